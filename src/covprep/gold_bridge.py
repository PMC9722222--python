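"""Covalent-docking orchestration around a GOLD-style engine.

Three steps mirror the helper-tool workflow:

* :func:`prepare` — one configuration file plus one single-record ligand
  SDF per input ligand, and a command manifest that partitions the jobs
  into balanced shards for parallel execution;
* :func:`run` — executes the commands through a *backend*.  The proprietary
  engine is optional: any object with ``dock(conf_path, ligand_path) ->
  [PoseResult]`` works, and a deterministic :class:`MockBackend` is shipped
  so the whole loop is testable offline;
* :func:`process` — fuses each docked pose with the protein by adding the
  single covalent bond between the configured link atoms.

The configuration dialect is deliberately isolated here: plain ``key =
value`` lines with a covalent block (``covalent = 1``, the protein and
ligand link-atom numbers) and the scoring-function keyword.  Users mapping
to a specific engine version can remap keys in one place (``CONF_KEYS``).
"""
from __future__ import annotations

import math
import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from . import io as cio
from .mol2 import Mol2Structure, ResidueSpec, find_protein_link_atom, read_mol2
from .reactor import read_prepared_sdf
from .records import PostReactedLigand

SCORING_FUNCTIONS = ("GoldScore", "ASP", "ChemScore", "PLP")
DEFAULT_DISTANCE_CUTOFF = 5.0  # Angstrom, noncovalent pose filter

CONF_KEYS = {
    "protein_file": "protein_datafile",
    "ligand_file": "ligand_data_file",
    "scoring_function": "gold_fitfunc_path",
    "n_poses": "ndocks",
    "covalent": "covalent",
    "protein_atom": "covalent_protein_atom_no",
    "ligand_atom": "covalent_ligand_atom_no",
    "output_dir": "directory",
}


class DockingError(RuntimeError):
    pass


@dataclass
class DockingConfig:
    protein_file: str
    residue_spec: ResidueSpec
    protein_link_atom_no: int
    scoring_function: str = "PLP"
    n_poses: int = 2
    n_shards: int = 1
    output_dir: str = "docking"

    def __post_init__(self):
        if self.scoring_function not in SCORING_FUNCTIONS:
            raise DockingError(
                f"unknown scoring function {self.scoring_function!r}; "
                f"choose one of {', '.join(SCORING_FUNCTIONS)}"
            )


@dataclass
class PoseResult:
    ligand_id: str
    pose_index: int
    mol: Chem.Mol  # 3D coordinates of the posed ligand
    score: float
    link_atom_index: int  # 1-based


@dataclass
class CovalentComplex:
    mol: Chem.Mol
    new_bond: Tuple[int, int]  # (protein atom no, ligand atom no), 1-based in merged mol
    ligand_id: str
    pose_index: int
    score: float


# ---------------------------------------------------------------------------
# prepare
# ---------------------------------------------------------------------------

def write_conf(path: str, config: DockingConfig, ligand_file: str,
               ligand_link_atom: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"{CONF_KEYS['protein_file']} = {config.protein_file}\n")
        fh.write(f"{CONF_KEYS['ligand_file']} = {ligand_file}\n")
        fh.write(f"{CONF_KEYS['scoring_function']} = {config.scoring_function}\n")
        fh.write(f"{CONF_KEYS['n_poses']} = {config.n_poses}\n")
        fh.write(f"{CONF_KEYS['covalent']} = 1\n")
        fh.write(f"{CONF_KEYS['protein_atom']} = {config.protein_link_atom_no}\n")
        fh.write(f"{CONF_KEYS['ligand_atom']} = {ligand_link_atom}\n")
        fh.write(f"{CONF_KEYS['output_dir']} = {config.output_dir}\n")


def read_conf(path: str) -> Dict[str, str]:
    """Parse an emitted conf back into its raw key/value mapping."""
    inv = {v: k for k, v in CONF_KEYS.items()}
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, value = (part.strip() for part in line.split("=", 1))
            out[inv.get(key, key)] = value
    return out


def shard_sizes(n_items: int, n_shards: int) -> List[int]:
    """Balanced partition: sizes differ by at most one."""
    if n_shards < 1:
        raise DockingError("n_shards must be >= 1")
    base, extra = divmod(n_items, n_shards)
    return [base + (1 if i < extra else 0) for i in range(n_shards)]


def prepare(
    ligands_sdf: str,
    config: DockingConfig,
) -> Tuple[List[str], List[str], List[str]]:
    """Emit per-ligand conf + SDF files and a sharded command manifest.

    Returns ``(conf_paths, ligand_paths, commands)`` with one command per
    shard.  Records without a ``Link_Atom`` property are skipped (logged as
    a discard in the shard manifest header).
    """
    try:
        ligands = read_prepared_sdf(ligands_sdf)
    except OSError as exc:
        raise DockingError(f"cannot read ligand SDF {ligands_sdf}: {exc}") from exc
    if not ligands:
        raise DockingError(f"no valid ligand records in {ligands_sdf}")
    os.makedirs(config.output_dir, exist_ok=True)
    conf_paths: List[str] = []
    ligand_paths: List[str] = []
    entries: List[Tuple[str, str]] = []
    for i, lig in enumerate(ligands):
        tag = f"{lig.parent_id}_{lig.stereo_index}_{i:04d}"
        lig_path = os.path.join(config.output_dir, f"ligand_{tag}.sdf")
        conf_path = os.path.join(config.output_dir, f"gold_{tag}.conf")
        props = dict(lig.properties)
        props[cio.PROP_LINK_ATOM] = lig.link_atom_index
        props[cio.PROP_COMPOUND_ID] = lig.parent_id
        props[cio.PROP_STEREO_INDEX] = lig.stereo_index
        props[cio.PROP_ORIGINAL_SMILES] = lig.original_smiles
        cio.write_sdf([(lig.mol, props)], lig_path)
        write_conf(conf_path, config, lig_path, lig.link_atom_index)
        conf_paths.append(conf_path)
        ligand_paths.append(lig_path)
        entries.append((conf_path, lig_path))

    sizes = shard_sizes(len(entries), config.n_shards)
    commands: List[str] = []
    start = 0
    for shard_no, size in enumerate(sizes):
        manifest = os.path.join(config.output_dir, f"shard_{shard_no:03d}.txt")
        with open(manifest, "w") as fh:
            for conf_path, lig_path in entries[start:start + size]:
                fh.write(f"{conf_path}\t{lig_path}\n")
        commands.append(f"covprep dock run-shard --manifest {manifest}")
        start += size
    with open(os.path.join(config.output_dir, "commands.txt"), "w") as fh:
        fh.write("\n".join(commands) + "\n")
    return conf_paths, ligand_paths, commands


# ---------------------------------------------------------------------------
# backends + run
# ---------------------------------------------------------------------------

class MockBackend:
    """Deterministic stand-in for the docking engine.

    For each requested pose the ligand is rigidly rotated and translated so
    its link atom lands at a seeded distance (1.6–2.4 Å) from the protein
    link atom; the score is the negative link-atom distance plus a small
    seeded noise term.  Fully reproducible for a fixed seed.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def _rng_for(self, ligand_id: str):
        mix = zlib.crc32(ligand_id.encode()) ^ self.seed
        return np.random.default_rng(mix % (2 ** 31))

    def dock(self, conf_path: str, ligand_path: str) -> List[PoseResult]:
        conf = read_conf(conf_path)
        protein = read_mol2(conf["protein_file"])
        target = np.array(protein.atom_by_serial(int(conf["protein_atom"])).coords)
        n_poses = int(conf["n_poses"])
        link_idx = int(conf["ligand_atom"])
        ligands = read_prepared_sdf(ligand_path)
        if not ligands:
            raise DockingError(f"backend: unreadable ligand file {ligand_path}")
        lig = ligands[0]
        ligand_id = f"{lig.parent_id}_{lig.stereo_index}"
        rng = self._rng_for(ligand_id)
        poses: List[PoseResult] = []
        for p in range(1, n_poses + 1):
            mol = Chem.Mol(lig.mol)
            conf3d = mol.GetConformer()
            xyz = np.array([list(conf3d.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
            center = xyz[link_idx - 1].copy()
            xyz -= center
            # random proper rotation
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            xyz = xyz @ rot.T
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(1.6, 2.4)
            xyz += target + direction * dist
            for i in range(mol.GetNumAtoms()):
                conf3d.SetAtomPosition(i, Point3D(*xyz[i]))
            score = -float(dist) + float(rng.normal(scale=0.1))
            poses.append(PoseResult(ligand_id, p, mol, score, link_idx))
        return poses


class GoldBackend:
    """Shells out to the external engine's ``gold_auto`` when installed."""

    def __init__(self, gold_auto: str = "gold_auto"):
        self.gold_auto = gold_auto

    def dock(self, conf_path: str, ligand_path: str) -> List[PoseResult]:
        import shutil
        import subprocess

        if shutil.which(self.gold_auto) is None:
            raise DockingError(
                f"docking engine executable {self.gold_auto!r} not on PATH; "
                "use the mock backend for engine-free runs"
            )
        subprocess.run([self.gold_auto, conf_path], check=True)
        conf = read_conf(conf_path)
        out_sdf = os.path.join(conf.get("output_dir", "."), "docked.sdf")
        poses: List[PoseResult] = []
        for p, mol in enumerate(Chem.SDMolSupplier(out_sdf, removeHs=False), start=1):
            if mol is None:
                continue
            score = float(mol.GetProp("Gold.Score")) if mol.HasProp("Gold.Score") else float("nan")
            poses.append(PoseResult(mol.GetProp("_Name"), p, mol, score,
                                    int(conf["ligand_atom"])))
        return poses


def run(commands: Sequence[str], backend) -> Tuple[List[PoseResult], List[str]]:
    """Execute shard commands through ``backend``.

    Returns ``(poses, failed_ligand_files)``; a backend failure on one
    ligand is recorded and the run continues.  Poses are order-normalized
    by (ligand_id, pose_index).
    """
    poses: List[PoseResult] = []
    failures: List[str] = []
    for command in commands:
        manifest = command.split("--manifest")[-1].strip()
        with open(manifest) as fh:
            for line in fh:
                if not line.strip():
                    continue
                conf_path, lig_path = line.rstrip("\n").split("\t")
                try:
                    poses.extend(backend.dock(conf_path, lig_path))
                except Exception:
                    failures.append(lig_path)
    poses.sort(key=lambda p: (p.ligand_id, p.pose_index))
    return poses, failures


# ---------------------------------------------------------------------------
# process: covalent complex assembly
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    "1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
    "3": Chem.BondType.TRIPLE, "am": Chem.BondType.SINGLE,
    "ar": Chem.BondType.AROMATIC, "du": Chem.BondType.SINGLE,
}


def mol2_to_rdkit(struct: Mol2Structure) -> Tuple[Chem.Mol, Dict[int, int]]:
    """Build an RDKit molecule from parsed mol2 records.

    Returns the molecule and a serial -> atom-index map.  Aromatic mol2
    bonds are kekulized by RDKit during sanitization; sanitization problems
    are tolerated (protein fragments routinely upset valence models).
    """
    rw = Chem.RWMol()
    serial_to_idx: Dict[int, int] = {}
    conf = Chem.Conformer(len(struct.atoms))
    for i, a in enumerate(struct.atoms):
        atom = Chem.Atom(a.element)
        atom.SetNoImplicit(True)
        idx = rw.AddAtom(atom)
        serial_to_idx[a.serial] = idx
        conf.SetAtomPosition(idx, Point3D(a.x, a.y, a.z))
    for b in struct.bonds:
        rw.AddBond(serial_to_idx[b.a1], serial_to_idx[b.a2],
                   _BOND_ORDER.get(b.order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    mol.AddConformer(conf, assignId=True)
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
    except Exception:
        pass
    return mol, serial_to_idx


def make_covalent_complex(
    pose: PoseResult,
    protein_mol: Chem.Mol,
    protein_atom_idx: int,
) -> CovalentComplex:
    """Fuse protein and posed ligand with one new single bond.

    A hydrogen attached to either endpoint is removed when the new bond
    would push it over valence; coordinates are never altered.
    """
    n_prot = protein_mol.GetNumAtoms()
    merged = Chem.RWMol(Chem.CombineMols(protein_mol, pose.mol))
    a1 = protein_atom_idx
    a2 = n_prot + pose.link_atom_index - 1
    merged.AddBond(a1, a2, Chem.BondType.SINGLE)

    # valence bookkeeping: drop one explicit H per endpoint when present
    to_remove = []
    for endpoint in (a1, a2):
        atom = merged.GetAtomWithIdx(endpoint)
        h_neighbors = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        if h_neighbors and _overfull(atom):
            to_remove.append(max(h_neighbors))
    for idx in sorted(to_remove, reverse=True):
        merged.RemoveAtom(idx)

    out = merged.GetMol()
    try:
        out.UpdatePropertyCache(strict=False)
    except Exception:
        pass
    # removing atoms shifts indices; recompute the bond endpoints
    shift1 = sum(1 for idx in to_remove if idx < a1)
    shift2 = sum(1 for idx in to_remove if idx < a2)
    return CovalentComplex(
        mol=out,
        new_bond=(a1 - shift1 + 1, a2 - shift2 + 1),
        ligand_id=pose.ligand_id,
        pose_index=pose.pose_index,
        score=pose.score,
    )


def _overfull(atom: Chem.Atom) -> bool:
    table = Chem.GetPeriodicTable()
    default = table.GetDefaultValence(atom.GetAtomicNum())
    if default <= 0:
        return False
    return atom.GetDegree() > default


def process(
    poses: Sequence[PoseResult],
    protein_mol2_path: str,
    config: DockingConfig,
    out_sdf: Optional[str] = None,
) -> List[CovalentComplex]:
    """Generate covalently bound protein–ligand complexes from poses."""
    struct = read_mol2(protein_mol2_path)
    protein_mol, serial_to_idx = mol2_to_rdkit(struct)
    prot_idx = serial_to_idx[config.protein_link_atom_no]
    complexes: List[CovalentComplex] = []
    for pose in poses:
        try:
            complexes.append(make_covalent_complex(pose, protein_mol, prot_idx))
        except Exception:
            continue
    if out_sdf is not None:
        rows = []
        for c in complexes:
            rows.append((c.mol, {
                "Ligand_ID": c.ligand_id,
                "Pose_Index": c.pose_index,
                "Score": f"{c.score:.4f}",
                "Covalent_Bond": f"{c.new_bond[0]}-{c.new_bond[1]}",
            }))
        cio.write_sdf(rows, out_sdf)
    return complexes


# ---------------------------------------------------------------------------
# classical (noncovalent) docking distance filter
# ---------------------------------------------------------------------------

def noncovalent_filter(
    poses: Sequence[PoseResult],
    protein_mol2_path: str,
    protein_link_atom_no: int,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> List[PoseResult]:
    """Keep poses whose reactive-atom pair lies within ``cutoff`` Å.

    This implements the classical-docking shortcut: exhaustive noncovalent
    poses are filtered on the distance between the protein nucleophile and
    the ligand's reactive (link) atom.
    """
    struct = read_mol2(protein_mol2_path)
    target = np.array(struct.atom_by_serial(protein_link_atom_no).coords)
    kept = []
    for pose in poses:
        pos = pose.mol.GetConformer().GetAtomPosition(pose.link_atom_index - 1)
        if math.dist(target, (pos.x, pos.y, pos.z)) <= cutoff:
            kept.append(pose)
    return kept
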