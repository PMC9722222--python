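"""In-silico covalent reaction and link-atom identification.

Each reaction is a SMIRKS transform that consumes one warhead and grafts on
the residue nucleophile (S for Cys, O for Ser/Thr/Tyr/Asp/Glu, N for Lys)
carrying a transient isotope label (mass 13).  After the transform, the
product that contains exactly one labelled atom defines the ligand link
atom; the label is cleared and the 1-based atom index is recorded so the
docking engine knows which atom forms the covalent bond.  Leaving groups
(halides, phenols of cleaved esters, ...) come out as separate fragments
and are dropped.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

from rdkit import Chem
from rdkit.Chem import AllChem

from . import io as cio
from .records import (
    RESIDUE_LINK_ELEMENT,
    SUPPORTED_RESIDUES,
    DiscardReason,
    DiscardRecord,
    PostReactedLigand,
    StandardizedCompound,
)
from .warheads import WarheadDefinition

log = logging.getLogger(__name__)

LINK_LABEL = 13  # transient isotope mass labelling the introduced nucleophile


class ReactionLibraryError(RuntimeError):
    """Fatal problem in the reaction data file."""


@dataclass
class ReactionDefinition:
    reaction_id: str
    warhead_id: str
    residue: str
    smirks: str
    link_atom_element: str
    rxn: AllChem.ChemicalReaction = field(default=None, repr=False)


def default_library_path() -> str:
    return str(resources.files("covprep.data").joinpath("reactions.tsv"))


def load_reactions(
    path: Optional[str] = None,
    warhead_library: Optional[Sequence[WarheadDefinition]] = None,
) -> List[ReactionDefinition]:
    """Load and validate the reaction library (shipped default: 98 entries).

    Every transform must compile, the link-atom element must match the
    residue mapping, and — when a warhead library is supplied — every
    reaction_id referenced by a warhead must resolve.
    """
    if path is None:
        path = default_library_path()
    defs: List[ReactionDefinition] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rid = row["reaction_id"].strip()
            if rid in seen:
                raise ReactionLibraryError(f"duplicate reaction_id: {rid}")
            seen[rid] = 1
            residue = row["residue"]
            if residue not in SUPPORTED_RESIDUES:
                raise ReactionLibraryError(f"{rid}: unsupported residue {residue}")
            element = row["link_atom_element"]
            if element != RESIDUE_LINK_ELEMENT[residue]:
                raise ReactionLibraryError(
                    f"{rid}: link atom {element} inconsistent with residue "
                    f"{residue} (expected {RESIDUE_LINK_ELEMENT[residue]})"
                )
            try:
                rxn = AllChem.ReactionFromSmarts(row["smirks"])
            except Exception as exc:
                raise ReactionLibraryError(f"{rid}: bad SMIRKS: {exc}") from exc
            defs.append(
                ReactionDefinition(rid, row["warhead_id"], residue,
                                   row["smirks"], element, rxn)
            )
    if not defs:
        raise ReactionLibraryError(f"empty reaction library: {path}")
    if warhead_library is not None:
        known = {d.reaction_id for d in defs}
        for wh in warhead_library:
            for rid in wh.reaction_ids:
                if rid not in known:
                    raise ReactionLibraryError(
                        f"warhead {wh.warhead_id} references unknown reaction {rid}"
                    )
    return defs


def apply_reaction(mol: Chem.Mol, rxn: ReactionDefinition) -> List[Chem.Mol]:
    """Apply the covalent transform; return unique labelled products.

    Products keep the transient isotope label on the introduced nucleophile.
    Leaving groups (fragments without a label) are removed.  Symmetric
    matches yielding the same product are deduplicated.
    """
    raw = rxn.rxn.RunReactants((mol,))
    products: List[Chem.Mol] = []
    smiles_seen = set()
    for ptuple in raw:
        for prod in ptuple:
            for frag in Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=False):
                if not any(a.GetIsotope() == LINK_LABEL for a in frag.GetAtoms()):
                    continue  # leaving group
                try:
                    Chem.SanitizeMol(frag)
                except Exception:
                    continue
                smi = Chem.MolToSmiles(frag)
                if smi not in smiles_seen:
                    smiles_seen.add(smi)
                    products.append(frag)
    return products


def locate_link_atom(mol: Chem.Mol) -> Tuple[Optional[int], Chem.Mol]:
    """Find the unique labelled atom; clear the label.

    Returns ``(index_1_based, cleaned_mol)``; index is ``None`` when the
    structure has zero or more than one labelled atom (ambiguous link atom —
    only records with one labelled atom are kept).
    """
    out = Chem.Mol(mol)
    labelled = [a.GetIdx() for a in out.GetAtoms() if a.GetIsotope() == LINK_LABEL]
    if len(labelled) != 1:
        return None, out
    out.GetAtomWithIdx(labelled[0]).SetIsotope(0)
    return labelled[0] + 1, out


def react_compound(
    compound: StandardizedCompound,
    warhead_id: str,
    reactions: Sequence[ReactionDefinition],
    residue: str,
) -> Union[List[PostReactedLigand], DiscardRecord]:
    """Apply the residue-specific reaction for ``warhead_id`` to one
    standardized stereoisomer and annotate the link atom.

    One post-reacted ligand is produced per compound; when the transform
    yields several distinct adducts (rare, symmetric warheads) the first in
    canonical-SMILES order is kept so the output stays deterministic.
    """
    candidates = [r for r in reactions
                  if r.warhead_id == warhead_id and r.residue == residue]
    if not candidates:
        return DiscardRecord(
            compound.parent_id, DiscardReason.AMBIGUOUS_LINK_ATOM,
            f"no {residue} reaction for warhead {warhead_id}",
        )
    rxn = candidates[0]
    products = apply_reaction(compound.mol, rxn)
    if not products:
        return DiscardRecord(
            compound.parent_id, DiscardReason.AMBIGUOUS_LINK_ATOM,
            f"transform {rxn.reaction_id} produced no product",
        )
    products.sort(key=Chem.MolToSmiles)
    link_idx, cleaned = locate_link_atom(products[0])
    if link_idx is None:
        return DiscardRecord(
            compound.parent_id, DiscardReason.AMBIGUOUS_LINK_ATOM,
            f"{rxn.reaction_id}: 0 or >1 labelled atoms",
        )
    elem = cleaned.GetAtomWithIdx(link_idx - 1).GetSymbol()
    return [
        PostReactedLigand(
            parent_id=compound.parent_id,
            stereo_index=compound.stereo_index,
            mol=cleaned,
            link_atom_index=link_idx,
            link_atom_element=elem,
            reaction_id=rxn.reaction_id,
            original_smiles=compound.original_smiles,
            properties=dict(compound.properties),
        )
    ]


def write_prepared_sdf(ligands: Sequence[PostReactedLigand], path: str) -> None:
    """Write the annotated pre-docking SDF.

    Atom numbering in the file matches ``link_atom_index`` (RDKit writes
    atoms in graph order, which is preserved from the reaction products).
    """
    rows = []
    for lig in ligands:
        props = dict(lig.properties)
        props[cio.PROP_LINK_ATOM] = lig.link_atom_index
        props[cio.PROP_COMPOUND_ID] = lig.parent_id
        props[cio.PROP_STEREO_INDEX] = lig.stereo_index
        props[cio.PROP_ORIGINAL_SMILES] = lig.original_smiles
        mol = Chem.Mol(lig.mol)
        mol.SetProp("_Name", f"{lig.parent_id}_{lig.stereo_index}")
        rows.append((mol, props))
    cio.write_sdf(rows, path)


def read_prepared_sdf(path: str) -> List[PostReactedLigand]:
    """Round-trip reader for SDFs produced by :func:`write_prepared_sdf`."""
    out: List[PostReactedLigand] = []
    for mol in Chem.SDMolSupplier(path, removeHs=False):
        if mol is None:
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        link = int(props.pop(cio.PROP_LINK_ATOM))
        out.append(
            PostReactedLigand(
                parent_id=props.pop(cio.PROP_COMPOUND_ID),
                stereo_index=int(props.pop(cio.PROP_STEREO_INDEX)),
                mol=mol,
                link_atom_index=link,
                link_atom_element=mol.GetAtomWithIdx(link - 1).GetSymbol(),
                reaction_id=props.pop("Reaction_ID", ""),
                original_smiles=props.pop(cio.PROP_ORIGINAL_SMILES, ""),
                properties=props,
            )
        )
    return out
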