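"""Core record types shared across the preparation pipeline.

The pipeline moves compounds through a sequence of states:

``CompoundRecord`` (raw input) -> ``StandardizedCompound`` (cleaned,
enumerated) -> ``PostReactedLigand`` (covalent adduct with a link atom).
Compounds that fall out at any stage become ``DiscardRecord``s, so that
every input identifier is accounted for exactly once at the end of a run.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from rdkit import Chem


class DiscardReason(str, enum.Enum):
    """Why a compound was dropped from the pipeline."""

    NONSTANDARD_ELEMENT = "nonstandard_element"
    ISOTOPE = "isotope"
    RADICAL = "radical"
    NULL_STRUCTURE = "null_structure"
    NO_WARHEAD = "no_warhead"
    MULTIPLE_WARHEADS = "multiple_warheads"
    REPEATED_WARHEAD = "repeated_warhead"
    AMBIGUOUS_LINK_ATOM = "ambiguous_link_atom"


@dataclass
class DiscardRecord:
    parent_id: str
    reason: DiscardReason
    detail: str = ""


@dataclass
class CompoundRecord:
    """One raw input ligand with identity, structure and passthrough fields."""

    compound_id: str
    smiles: str
    mol: Optional[Chem.Mol]
    properties: Dict[str, str] = field(default_factory=dict)


@dataclass
class StandardizedCompound:
    """A standardized, enumerated, pH-adjusted structure."""

    parent_id: str
    mol: Chem.Mol
    stereo_index: int = 1
    audit: List[str] = field(default_factory=list)
    original_smiles: str = ""
    properties: Dict[str, str] = field(default_factory=dict)


@dataclass
class PostReactedLigand:
    """A covalent adduct carrying its 1-based link-atom index."""

    parent_id: str
    stereo_index: int
    mol: Chem.Mol
    link_atom_index: int  # 1-based, valid for the written SDF atom block
    link_atom_element: str
    reaction_id: str
    original_smiles: str
    properties: Dict[str, str] = field(default_factory=dict)


ALLOWED_ELEMENTS = frozenset(
    ["H", "C", "O", "N", "S", "P", "B", "F", "Cl", "Br", "I"]
)

SUPPORTED_RESIDUES = ("Cys", "Lys", "Ser", "Tyr", "Thr", "Asp", "Glu")

#: nucleophile element contributed by each residue's side chain
RESIDUE_LINK_ELEMENT = {
    "Cys": "S",
    "Ser": "O",
    "Thr": "O",
    "Tyr": "O",
    "Lys": "N",
    "Asp": "O",
    "Glu": "O",
}
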