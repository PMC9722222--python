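"""Reading ligand libraries and writing annotated SDF output.

Input formats: multi-record SDF (V2000, data fields preserved verbatim) and
whitespace-separated SMILES files (``SMILES<space>id``, one per line).
"""
from __future__ import annotations

import os
from typing import Dict, List, Tuple

from rdkit import Chem

from .records import CompoundRecord, DiscardReason, DiscardRecord

#: SDF property names written by the reactor stage
PROP_LINK_ATOM = "Link_Atom"
PROP_COMPOUND_ID = "Compound_ID"
PROP_STEREO_INDEX = "Stereo_Index"
PROP_ORIGINAL_SMILES = "Original_SMILES"

ID_FIELDS = ("compound_id", "Compound_ID", "ID", "id", "Name", "name")


class LibraryError(RuntimeError):
    """Fatal problem with an input library."""


def _auto_id(i: int) -> str:
    return "MOL%06d" % i


def read_library(path: str, fmt: str | None = None) -> Tuple[List[CompoundRecord], List[DiscardRecord]]:
    """Read an SDF or SMILES ligand library.

    Returns (records, discards).  Unparseable records become
    ``DiscardRecord(null_structure)``.  Raises :class:`LibraryError` if the
    file is missing or contains no parseable record at all.
    """
    if not os.path.exists(path):
        raise LibraryError(f"input file not found: {path}")
    if fmt is None:
        fmt = "smiles" if os.path.splitext(path)[1].lower() in (".smi", ".smiles", ".txt") else "sdf"
    if fmt == "sdf":
        records, discards = _read_sdf(path)
    elif fmt == "smiles":
        records, discards = _read_smiles(path)
    else:
        raise LibraryError(f"unknown format: {fmt}")
    if not records:
        raise LibraryError(
            f"no parseable records in {path} ({len(discards)} unparseable)"
        )
    seen: Dict[str, int] = {}
    for rec in records:
        if rec.compound_id in seen:
            raise LibraryError(f"duplicate compound_id: {rec.compound_id}")
        seen[rec.compound_id] = 1
    return records, discards


def _read_sdf(path: str) -> Tuple[List[CompoundRecord], List[DiscardRecord]]:
    records: List[CompoundRecord] = []
    discards: List[DiscardRecord] = []
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            discards.append(DiscardRecord(_auto_id(i), DiscardReason.NULL_STRUCTURE, "unparseable SDF record"))
            continue
        if mol.GetNumAtoms() == 0:
            discards.append(DiscardRecord(_auto_id(i), DiscardReason.NULL_STRUCTURE, "empty structure"))
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        cid = ""
        for f in ID_FIELDS:
            if f in props:
                cid = props[f]
                break
        if not cid and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        if not cid:
            cid = _auto_id(i)
        records.append(CompoundRecord(cid, Chem.MolToSmiles(mol), mol, props))
    return records, discards


def _read_smiles(path: str) -> Tuple[List[CompoundRecord], List[DiscardRecord]]:
    records: List[CompoundRecord] = []
    discards: List[DiscardRecord] = []
    with open(path) as fh:
        for i, line in enumerate((ln for ln in fh if ln.strip()), start=1):
            parts = line.split()
            smi = parts[0]
            cid = parts[1] if len(parts) > 1 else _auto_id(i)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                discards.append(DiscardRecord(cid, DiscardReason.NULL_STRUCTURE, f"bad SMILES: {smi}"))
                continue
            records.append(CompoundRecord(cid, smi, mol, {}))
    return records, discards


def write_sdf(mols_with_props, path: str) -> None:
    """Write ``(mol, {prop: value})`` pairs as a V2000 SDF."""
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for mol, props in mols_with_props:
            out = Chem.Mol(mol)
            for k, v in props.items():
                out.SetProp(k, str(v))
            writer.write(out)
    finally:
        writer.close()


def write_audit_csv(rows, path: str) -> None:
    """Audit trail: compound_id, stage, action, reason."""
    with open(path, "w") as fh:
        fh.write("compound_id,stage,action,reason\n")
        for cid, stage, action, reason in rows:
            fh.write(f"{cid},{stage},{action},{reason}\n")
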