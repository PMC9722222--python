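"""Residue-aware electrophilic warhead identification and triage.

The shipped library holds 68 warhead definitions, each a SMARTS pattern
annotated with the nucleophilic residues it can react with (Cys, Lys, Ser,
Tyr, Thr, Asp, Glu) and the reactions that consume it.  A compound is kept
for docking only when it carries exactly one warhead exactly once; anything
else (no warhead, several different warheads, the same warhead twice) is
discarded, because the reaction stage would otherwise be ambiguous.

Specificity is handled through optional ``parent_id`` links in the data
file: a match of a specific pattern (say, an epoxyketone) suppresses
overlapping matches of its declared generic parent (the plain epoxide), so
one functional group is never counted twice.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Union

from rdkit import Chem

from .records import SUPPORTED_RESIDUES, DiscardReason, DiscardRecord


class WarheadLibraryError(RuntimeError):
    """Fatal problem in the warhead data file."""


@dataclass
class WarheadDefinition:
    warhead_id: str
    name: str
    smarts: str
    residues: List[str]
    reaction_ids: List[str]
    parent_id: str = ""
    pattern: Chem.Mol = field(default=None, repr=False)


@dataclass
class WarheadMatch:
    warhead_id: str
    matched_atom_indices: List[tuple]  # 1-based atom index tuples

    @property
    def occurrence_count(self) -> int:
        return len(self.matched_atom_indices)


def default_library_path() -> str:
    return str(resources.files("covprep.data").joinpath("warheads.tsv"))


def load_warhead_library(path: Optional[str] = None) -> List[WarheadDefinition]:
    """Load and validate the warhead library (shipped default: 68 entries)."""
    if path is None:
        path = default_library_path()
    defs: List[WarheadDefinition] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            wid = row["warhead_id"].strip()
            if wid in seen:
                raise WarheadLibraryError(f"duplicate warhead_id: {wid}")
            seen[wid] = 1
            patt = Chem.MolFromSmarts(row["smarts"])
            if patt is None:
                raise WarheadLibraryError(f"invalid SMARTS for {wid}: {row['smarts']}")
            residues = [r for r in row["residues"].split(";") if r]
            if not residues:
                raise WarheadLibraryError(f"{wid}: empty residue list")
            for r in residues:
                if r not in SUPPORTED_RESIDUES:
                    raise WarheadLibraryError(f"{wid}: unsupported residue {r}")
            defs.append(
                WarheadDefinition(
                    warhead_id=wid,
                    name=row["name"],
                    smarts=row["smarts"],
                    residues=residues,
                    reaction_ids=[x for x in row["reaction_ids"].split(";") if x],
                    parent_id=row.get("parent_id", "").strip(),
                    pattern=patt,
                )
            )
    ids = {d.warhead_id for d in defs}
    for d in defs:
        if d.parent_id and d.parent_id not in ids:
            raise WarheadLibraryError(f"{d.warhead_id}: unknown parent {d.parent_id}")
    return defs


def detect_warheads(
    mol: Chem.Mol,
    library: Sequence[WarheadDefinition],
    residue: str,
) -> List[WarheadMatch]:
    """Match the library against ``mol`` for the selected residue.

    Only definitions reactive toward ``residue`` are considered.
    Symmetry-duplicate embeddings (same atom set) collapse to one
    occurrence, and matches of a generic parent that overlap a match of one
    of its specific children are suppressed.
    """
    if residue not in SUPPORTED_RESIDUES:
        raise ValueError(f"unsupported residue: {residue}")
    raw: Dict[str, List[frozenset]] = {}
    for d in library:
        if residue not in d.residues:
            continue
        matches = mol.GetSubstructMatches(d.pattern, uniquify=True)
        atom_sets: List[frozenset] = []
        for m in matches:
            s = frozenset(m)
            if s not in atom_sets:
                atom_sets.append(s)
        if atom_sets:
            raw[d.warhead_id] = atom_sets

    # suppress generic-parent matches overlapping a specific child's match
    by_id = {d.warhead_id: d for d in library}
    child_atoms: Dict[str, List[frozenset]] = {}
    for wid, sets in raw.items():
        parent = by_id[wid].parent_id
        while parent:
            child_atoms.setdefault(parent, []).extend(sets)
            parent = by_id[parent].parent_id if parent in by_id else ""
    out: List[WarheadMatch] = []
    for wid, sets in raw.items():
        suppressed = child_atoms.get(wid, [])
        kept = [s for s in sets if not any(s & c for c in suppressed)]
        if kept:
            out.append(
                WarheadMatch(
                    warhead_id=wid,
                    matched_atom_indices=[tuple(sorted(i + 1 for i in s)) for s in kept],
                )
            )
    out.sort(key=lambda m: m.warhead_id)
    return out


def triage(
    compound_id: str,
    matches: Sequence[WarheadMatch],
) -> Union[str, DiscardRecord]:
    """One-warhead rule: keep iff exactly one warhead matched exactly once.

    Returns the kept ``warhead_id`` or a :class:`DiscardRecord` with reason
    ``no_warhead``, ``multiple_warheads`` or ``repeated_warhead``.
    """
    if not matches:
        return DiscardRecord(compound_id, DiscardReason.NO_WARHEAD)
    if len(matches) > 1:
        return DiscardRecord(
            compound_id, DiscardReason.MULTIPLE_WARHEADS,
            ";".join(m.warhead_id for m in matches),
        )
    match = matches[0]
    if match.occurrence_count > 1:
        return DiscardRecord(
            compound_id, DiscardReason.REPEATED_WARHEAD,
            f"{match.warhead_id} x{match.occurrence_count}",
        )
    return match.warhead_id
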