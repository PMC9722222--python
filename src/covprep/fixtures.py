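"""Synthetic test data: toy ligand libraries and a toy protein.

Everything the pipeline needs for an engine-free end-to-end run is
generated here programmatically: a templated ligand library in which every
record has a known, manifest-declared fate (kept, or discarded for one
specific reason), a minimal Tripos mol2 "protein" — a capped cysteine
fragment whose SG atom serial and coordinates are documented — and
geometric pose fixtures for the distance filter.

Templated SMILES with seeded substituent randomization are used instead of
random molecular graphs so that warhead counts are guaranteed by
construction.
"""
from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from . import io as cio
from .gold_bridge import PoseResult
from .records import PostReactedLigand

#: substituents drawn for scaffold variation (always substitutable in a
#: parenthesized branch position)
_SUBSTITUENTS = ["F", "Cl", "C", "OC", "CC", "C(C)C", "Br", "CCC"]

#: templates per record class; {r} is the randomized substituent
_TEMPLATES = {
    "clean_active": ("C=CC(=O)Nc1ccc({r})cc1", "keep", 1),
    "decoy": ("ClCC(=O)Nc1ccc({r})cc1", "keep", 0),
    "salt": ("CC({r})C[NH3+].[Cl-]", "no_warhead", 0),
    "isotope": ("C=CC(=O)NC({r})[13CH3]", "isotope", 0),
    "multiwarhead": ("C=CC(=O)NCCCNC(=O)CCl", "multiple_warheads", 0),
    "repeated": ("C=CC(=O)NCCCNC(=O)C=C", "repeated_warhead", 0),
    "badelement": ("CC({r})[Si](C)(C)C", "nonstandard_element", 0),
}


@dataclass
class ManifestEntry:
    compound_id: str
    compound_class: str
    label: int
    expected_fate: str  # "keep" or a discard reason


def generate_toy_library(
    out_sdf: str,
    manifest_csv: str,
    n_clean_actives: int = 5,
    n_decoys: int = 5,
    n_salts: int = 1,
    n_isotopes: int = 1,
    n_multiwarhead: int = 1,
    n_repeated: int = 1,
    n_badelement: int = 1,
    seed: int = 7,
) -> List[ManifestEntry]:
    """Write an SDF + manifest whose records have declared pipeline fates."""
    rng = np.random.default_rng(seed)
    counts = [
        ("clean_active", n_clean_actives),
        ("decoy", n_decoys),
        ("salt", n_salts),
        ("isotope", n_isotopes),
        ("multiwarhead", n_multiwarhead),
        ("repeated", n_repeated),
        ("badelement", n_badelement),
    ]
    entries: List[ManifestEntry] = []
    rows = []
    serial = 0
    for cls, n in counts:
        template, fate, label = _TEMPLATES[cls]
        for _ in range(int(n)):
            serial += 1
            cid = f"TOY{serial:04d}"
            r = _SUBSTITUENTS[int(rng.integers(0, len(_SUBSTITUENTS)))]
            smi = template.format(r=r) if "{r}" in template else template
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                mol = Chem.MolFromSmiles(smi, sanitize=False)
                mol.UpdatePropertyCache(strict=False)
            mol.SetProp("_Name", cid)
            rows.append((mol, {
                "compound_id": cid,
                "class": cls,
                "activity": str(label),
            }))
            entries.append(ManifestEntry(cid, cls, label, fate))
    cio.write_sdf(rows, out_sdf)
    with open(manifest_csv, "w") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "class", "label", "expected_fate"])
        for e in entries:
            writer.writerow([e.compound_id, e.compound_class, e.label, e.expected_fate])
    return entries


def read_manifest(path: str) -> List[ManifestEntry]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(ManifestEntry(row["compound_id"], row["class"],
                                     int(row["label"]), row["expected_fate"]))
    return out


# ---------------------------------------------------------------------------
# toy protein
# ---------------------------------------------------------------------------

#: atom records of the capped-cysteine toy protein
#: (serial, name, x, y, z, sybyl type, subst_id, subst_name)
_PROTEIN_ATOMS = [
    (1, "N", -2.70, 1.20, 0.00, "N.am", 1, "CYS25"),
    (2, "CA", -2.00, 0.00, 0.00, "C.3", 1, "CYS25"),
    (3, "CB", -1.20, 0.00, 1.25, "C.3", 1, "CYS25"),
    (4, "SG", 0.00, 0.00, 0.00, "S.3", 1, "CYS25"),
    (5, "HG", 1.19, 0.00, 0.60, "H", 1, "CYS25"),
    (6, "C", -2.90, -1.20, 0.00, "C.2", 1, "CYS25"),
    (7, "O", -4.10, -1.20, 0.00, "O.2", 1, "CYS25"),
]
_PROTEIN_BONDS = [(1, 2, "1"), (2, 3, "1"), (3, 4, "1"), (4, 5, "1"),
                  (2, 6, "1"), (6, 7, "2")]

SG_SERIAL = 4
SG_COORDS = (0.0, 0.0, 0.0)


def toy_protein_mol2(path: str, chain: str = "A") -> Tuple[str, int]:
    """Write the toy protein; returns (path, SG atom serial)."""
    lines = ["@<TRIPOS>MOLECULE", "toy_cys_protein",
             f" {len(_PROTEIN_ATOMS)} {len(_PROTEIN_BONDS)} 1",
             "SMALL", "NO_CHARGES", "", "@<TRIPOS>ATOM"]
    for s, name, x, y, z, typ, sid, sname in _PROTEIN_ATOMS:
        lines.append(f"{s:7d} {name:<4s} {x:9.4f} {y:9.4f} {z:9.4f} "
                     f"{typ:<6s} {sid:3d} {sname:<8s} 0.0000")
    lines.append("@<TRIPOS>BOND")
    for i, (a, b, order) in enumerate(_PROTEIN_BONDS, start=1):
        lines.append(f"{i:6d} {a:5d} {b:5d} {order}")
    lines.append("@<TRIPOS>SUBSTRUCTURE")
    lines.append(f"     1 CYS25       1 RESIDUE           1 {chain} CYS     1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path, SG_SERIAL


# ---------------------------------------------------------------------------
# geometric pose fixtures
# ---------------------------------------------------------------------------

def pose_at_distance(distance: float, pose_index: int = 1,
                     ligand_id: str = "POSE") -> PoseResult:
    """A docked pose whose ligand link atom sits ``distance`` Å from SG.

    The ligand is a minimal thioether adduct (S-CH2-C(=O)-NH2) placed along
    the +x axis from the toy protein's SG position.
    """
    mol = Chem.MolFromSmiles("SCC(N)=O")
    mol = Chem.AddHs(mol)
    from rdkit.Chem import AllChem

    params = AllChem.ETKDGv3()
    params.randomSeed = 12345
    AllChem.EmbedMolecule(mol, params)
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    xyz -= xyz[0]  # link atom (S, index 0) to origin
    xyz += np.array(SG_COORDS) + np.array([distance, 0.0, 0.0])
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, Point3D(*xyz[i]))
    return PoseResult(ligand_id=ligand_id, pose_index=pose_index, mol=mol,
                      score=-distance, link_atom_index=1)
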