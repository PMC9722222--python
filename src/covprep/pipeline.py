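"""End-to-end ligand preparation: standardize -> warhead triage -> react.

Thin composition layer used by the command-line interface and by tests;
all stage logic lives in the stage modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .reactor import ReactionDefinition, load_reactions, react_compound
from .records import (
    CompoundRecord,
    DiscardRecord,
    PostReactedLigand,
    StandardizedCompound,
)
from .standardizer import DEFAULT_PH, DEFAULT_STEREO_CAP, standardize_pipeline
from .warheads import WarheadDefinition, detect_warheads, load_warhead_library, triage


@dataclass
class PrepareResult:
    ligands: List[PostReactedLigand] = field(default_factory=list)
    discards: List[DiscardRecord] = field(default_factory=list)
    #: parent_id -> "keep" / discard reason value
    fates: Dict[str, str] = field(default_factory=dict)


def prepare_library(
    records: Sequence[CompoundRecord],
    residue: str,
    warhead_library: Optional[Sequence[WarheadDefinition]] = None,
    reactions: Optional[Sequence[ReactionDefinition]] = None,
    stereo_cap: int = DEFAULT_STEREO_CAP,
    ph: float = DEFAULT_PH,
) -> PrepareResult:
    """Run raw compound records through the full preparation chain.

    Warhead detection and triage operate per parent compound (all
    enumerated stereoisomers share one constitution); the covalent
    reaction and link-atom annotation run per stereoisomer.
    """
    if warhead_library is None:
        warhead_library = load_warhead_library()
    if reactions is None:
        reactions = load_reactions(warhead_library=warhead_library)

    result = PrepareResult()
    survivors, std_discards = standardize_pipeline(records, cap=stereo_cap, ph=ph)
    for d in std_discards:
        result.discards.append(d)
        result.fates[d.parent_id] = d.reason.value

    by_parent: Dict[str, List[StandardizedCompound]] = {}
    for compound in survivors:
        by_parent.setdefault(compound.parent_id, []).append(compound)

    for parent_id, group in by_parent.items():
        matches = detect_warheads(group[0].mol, warhead_library, residue)
        verdict = triage(parent_id, matches)
        if isinstance(verdict, DiscardRecord):
            result.discards.append(verdict)
            result.fates[parent_id] = verdict.reason.value
            continue
        warhead_id = verdict
        produced = 0
        last_discard: Optional[DiscardRecord] = None
        for compound in group:
            reacted = react_compound(compound, warhead_id, reactions, residue)
            if isinstance(reacted, DiscardRecord):
                last_discard = reacted
                continue
            result.ligands.extend(reacted)
            produced += len(reacted)
        if produced:
            result.fates[parent_id] = "keep"
        else:
            discard = last_discard or DiscardRecord(parent_id, None)
            result.discards.append(discard)
            result.fates[parent_id] = discard.reason.value
    return result
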