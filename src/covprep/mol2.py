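"""Minimal Tripos mol2 reading: ATOM / BOND / SUBSTRUCTURE records.

The docking orchestrator only needs atom serials, names, coordinates,
residue (substructure) assignment and bonds of an already-prepared protein,
so this parser deliberately covers just those record types.  Atom serial
numbers are taken verbatim as written (1-based).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


class Mol2Error(RuntimeError):
    pass


@dataclass
class Mol2Atom:
    serial: int
    name: str
    x: float
    y: float
    z: float
    atom_type: str
    subst_id: int
    subst_name: str
    charge: float

    @property
    def element(self) -> str:
        return self.atom_type.split(".")[0]

    @property
    def coords(self) -> Tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Mol2Bond:
    a1: int  # atom serials
    a2: int
    order: str


@dataclass
class Mol2Substructure:
    subst_id: int
    name: str
    root_atom: int
    chain: str = ""


@dataclass
class Mol2Structure:
    name: str
    atoms: List[Mol2Atom] = field(default_factory=list)
    bonds: List[Mol2Bond] = field(default_factory=list)
    substructures: List[Mol2Substructure] = field(default_factory=list)

    def atom_by_serial(self, serial: int) -> Mol2Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise Mol2Error(f"no atom with serial {serial}")


def read_mol2(path: str) -> Mol2Structure:
    struct = Mol2Structure(name="")
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("@<TRIPOS>"):
                section = line[len("@<TRIPOS>"):].strip()
                mol_lines = 0
                continue
            if not line.strip() or line.startswith("#"):
                continue
            if section == "MOLECULE":
                mol_lines += 1
                if mol_lines == 1:
                    struct.name = line.strip()
            elif section == "ATOM":
                f = line.split()
                struct.atoms.append(
                    Mol2Atom(
                        serial=int(f[0]), name=f[1],
                        x=float(f[2]), y=float(f[3]), z=float(f[4]),
                        atom_type=f[5],
                        subst_id=int(f[6]) if len(f) > 6 else 1,
                        subst_name=f[7] if len(f) > 7 else "",
                        charge=float(f[8]) if len(f) > 8 else 0.0,
                    )
                )
            elif section == "BOND":
                f = line.split()
                struct.bonds.append(Mol2Bond(int(f[1]), int(f[2]), f[3]))
            elif section == "SUBSTRUCTURE":
                f = line.split()
                struct.substructures.append(
                    Mol2Substructure(
                        subst_id=int(f[0]), name=f[1], root_atom=int(f[2]),
                        chain=f[5] if len(f) > 5 else "",
                    )
                )
    if not struct.atoms:
        raise Mol2Error(f"no TRIPOS ATOM records in {path}")
    return struct


@dataclass(frozen=True)
class ResidueSpec:
    """A protein residue atom, e.g. ``A:CYS:25:SG`` (chain optional)."""

    chain: str
    res_name: str
    res_number: int
    atom_name: str

    @classmethod
    def parse(cls, text: str) -> "ResidueSpec":
        parts = text.split(":")
        if len(parts) == 4:
            chain, rname, rnum, aname = parts
        elif len(parts) == 3:
            chain, (rname, rnum, aname) = "", parts
        else:
            raise ValueError(f"bad residue spec: {text!r} (want [CHAIN:]RES:NUM:ATOM)")
        return cls(chain, rname.upper(), int(rnum), aname.upper())

    def __str__(self) -> str:
        head = f"{self.chain}:" if self.chain else ""
        return f"{head}{self.res_name}:{self.res_number}:{self.atom_name}"


def find_protein_link_atom(mol2_path: str, spec: ResidueSpec | str) -> int:
    """Resolve a residue spec to the 1-based atom serial in the mol2.

    Raises :class:`Mol2Error` when the atom is absent or ambiguous (two
    chains matching an underspecified query, altloc duplicates, ...).
    """
    if isinstance(spec, str):
        spec = ResidueSpec.parse(spec)
    struct = read_mol2(mol2_path)
    chain_of: Dict[int, str] = {s.subst_id: s.chain for s in struct.substructures}
    target_subst = f"{spec.res_name}{spec.res_number}"
    candidates = []
    for atom in struct.atoms:
        if atom.subst_name.upper() != target_subst:
            continue
        if atom.name.upper() != spec.atom_name:
            continue
        if spec.chain:
            chain = chain_of.get(atom.subst_id, "")
            if chain and chain.upper() != spec.chain.upper():
                continue
        candidates.append(atom)
    if not candidates:
        raise Mol2Error(f"residue atom {spec} not found in {mol2_path}")
    if len(candidates) > 1:
        serials = ", ".join(str(a.serial) for a in candidates)
        raise Mol2Error(f"ambiguous residue spec {spec}: atom serials {serials}")
    return candidates[0].serial
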