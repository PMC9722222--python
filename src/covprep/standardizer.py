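"""Compound standardization: filtering, normalization, tautomer and
stereoisomer enumeration, and pH-7.4 microspecies assignment.

The pipeline applies, in order:

1. element/species filter (allowed elements, no isotopes, no radicals)
2. null-structure filter (heavy-atom molecular weight must be > 0)
3. largest-fragment selection (desalting)
4. normalization (mesomer standardization, neutralization, aromatization,
   wavy-bond clearing)
5. canonical tautomer
6. enumeration of undefined tetrahedral stereocenters (capped, default 1000)
7. major microspecies at pH 7.4 via a shipped SMARTS/pKa rule table

Every input compound ends up exactly once as either a set of surviving
stereoisomers (sharing the parent id) or a single discard record.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import (
    ALLOWED_ELEMENTS,
    CompoundRecord,
    DiscardReason,
    DiscardRecord,
    StandardizedCompound,
)

log = logging.getLogger(__name__)

DEFAULT_STEREO_CAP = 1000
DEFAULT_PH = 7.4

#: tautomer enumeration is abandoned above this many tautomers
_TAUTOMER_LIMIT = 1000


# ---------------------------------------------------------------------------
# stage 1: element / species filter
# ---------------------------------------------------------------------------

def element_and_species_filter(mol: Chem.Mol) -> Optional[DiscardReason]:
    """Return a discard reason if the structure contains a nonstandard
    element, an isotope label or a radical center; ``None`` if it passes."""
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return DiscardReason.NONSTANDARD_ELEMENT
    for atom in mol.GetAtoms():
        if atom.GetIsotope() != 0:
            return DiscardReason.ISOTOPE
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() != 0:
            return DiscardReason.RADICAL
    return None


def heavy_atom_mw(mol: Chem.Mol) -> float:
    return sum(a.GetMass() for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


# ---------------------------------------------------------------------------
# stage 3: largest fragment
# ---------------------------------------------------------------------------

def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Pick the fragment with the most heavy atoms.

    Ties are broken by larger molecular weight, then by canonical-SMILES
    lexicographic order (smallest string wins), so the choice is
    deterministic for any input.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(f: Chem.Mol):
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), _neg_lex(Chem.MolToSmiles(f)))

    return max(frags, key=key)


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smaller string."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# stage 4: normalization
# ---------------------------------------------------------------------------

_normalizer = rdMolStandardize.Normalizer()
_uncharger = rdMolStandardize.Uncharger()


def normalize(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Standardize mesomers (nitro, sulfone, sulfoxide, ...), neutralize,
    aromatize, and clear wavy/undefined double-bond stereo.

    The charge-separated nitro form ``[N+](=O)[O-]`` is the canonical
    output dialect.  Returns ``None`` when the structure cannot be
    sanitized after normalization.
    """
    try:
        out = _normalizer.normalize(mol)
        out = _uncharger.uncharge(out)
        Chem.SanitizeMol(out)
    except Exception:
        return None
    # wiggly bonds: explicit "unknown" single-bond wedging and crossed /
    # undefined double bonds are reduced to plain bonds
    for bond in out.GetBonds():
        if bond.GetBondDir() == Chem.BondDir.UNKNOWN:
            bond.SetBondDir(Chem.BondDir.NONE)
        if bond.GetStereo() == Chem.BondStereo.STEREOANY:
            bond.SetStereo(Chem.BondStereo.STEREONONE)
    Chem.SetAromaticity(out)
    return out


# ---------------------------------------------------------------------------
# stage 5: canonical tautomer
# ---------------------------------------------------------------------------

_tautomerizer = rdMolStandardize.TautomerEnumerator()
_tautomerizer.SetMaxTautomers(_TAUTOMER_LIMIT)


def canonical_tautomer(mol: Chem.Mol) -> Chem.Mol:
    """Deterministic canonical tautomer under a scoring scheme that prefers
    aromatic rings, then carbonyl over enol forms.  Idempotent.  If
    enumeration blows past the internal limit the input is returned
    unchanged with a warning."""
    try:
        return _tautomerizer.Canonicalize(mol)
    except Exception:
        log.warning("tautomer canonicalization failed; structure kept as-is")
        return mol


# ---------------------------------------------------------------------------
# stage 6: stereoisomer enumeration
# ---------------------------------------------------------------------------

def _undefined_tetrahedral_centers(mol: Chem.Mol) -> List[int]:
    """Atom indices of undefined tetrahedral stereocenters, ordered by
    canonical atom rank so that the enumeration order is reproducible."""
    si = Chem.FindPotentialStereo(mol)
    centers = [
        int(e.centeredOn)
        for e in si
        if e.type == Chem.StereoType.Atom_Tetrahedral
        and e.specified == Chem.StereoSpecified.Unspecified
    ]
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    centers.sort(key=lambda i: ranks[i])
    return centers


def count_undefined_stereocenters(mol: Chem.Mol) -> int:
    return len(_undefined_tetrahedral_centers(mol))


def enumerate_stereoisomers(mol: Chem.Mol, cap: int = DEFAULT_STEREO_CAP) -> List[Chem.Mol]:
    """Enumerate all ``2^k`` assignments of the k undefined tetrahedral
    centers, or the first ``cap`` of them in a deterministic depth-first
    order (centers visited in canonical rank order, CW before CCW).

    Defined centers are left untouched; every output shares the input's
    stereo-stripped constitution.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    centers = _undefined_tetrahedral_centers(mol)
    k = len(centers)
    if k == 0:
        return [Chem.Mol(mol)]
    n_out = min(2 ** k if k < 63 else cap, cap)
    out: List[Chem.Mol] = []
    tags = (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    for code in range(n_out):
        iso = Chem.Mol(mol)
        for bit, aidx in enumerate(centers):
            # most-significant bit = first center -> depth-first order
            choice = (code >> (k - 1 - bit)) & 1
            iso.GetAtomWithIdx(aidx).SetChiralTag(tags[choice])
        Chem.AssignStereochemistry(iso, cleanIt=True, force=True)
        out.append(iso)
    return out


# ---------------------------------------------------------------------------
# stage 7: major microspecies at pH 7.4
# ---------------------------------------------------------------------------

@dataclass
class ProtonationRule:
    rule_id: str
    name: str
    pattern: Chem.Mol
    site: int
    kind: str  # "acid" or "base"
    pka: float


def load_pka_rules(path: Optional[str] = None) -> List[ProtonationRule]:
    """Load the shipped SMARTS -> protonation rule table."""
    if path is None:
        src = resources.files("covprep.data").joinpath("pka_rules.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        patt = Chem.MolFromSmarts(row["smarts"])
        if patt is None:
            raise ValueError(f"bad SMARTS in pKa rule {row['rule_id']}")
        rules.append(
            ProtonationRule(
                row["rule_id"], row["name"], patt, int(row["site"]),
                row["kind"], float(row["pka"]),
            )
        )
    return rules


_PKA_RULES: Optional[List[ProtonationRule]] = None


def _pka_rules() -> List[ProtonationRule]:
    global _PKA_RULES
    if _PKA_RULES is None:
        _PKA_RULES = load_pka_rules()
    return _PKA_RULES


def major_microspecies(mol: Chem.Mol, ph: float = DEFAULT_PH,
                       rules: Optional[Sequence[ProtonationRule]] = None) -> Chem.Mol:
    """Apply the rule table: acids with pKa < pH are deprotonated, bases
    whose conjugate acid has pKa > pH are protonated; groups not covered by
    the table are untouched.  Idempotent (fired sites no longer match)."""
    if rules is None:
        rules = _pka_rules()
    out = Chem.RWMol(mol)
    actions: List[Tuple[int, int]] = []  # (atom idx, +1/-1)
    hit = set()
    for rule in rules:
        fire = (rule.kind == "acid" and rule.pka < ph) or (
            rule.kind == "base" and rule.pka > ph)
        if not fire:
            continue
        for match in out.GetSubstructMatches(rule.pattern):
            aidx = match[rule.site]
            if aidx not in hit:
                hit.add(aidx)
                actions.append((aidx, -1 if rule.kind == "acid" else +1))
    for aidx, delta in actions:
        atom = out.GetAtomWithIdx(aidx)
        h = atom.GetTotalNumHs()
        if delta < 0 and h == 0:
            continue
        atom.SetFormalCharge(atom.GetFormalCharge() + delta)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(h + delta)
    result = out.GetMol()
    Chem.SanitizeMol(result)
    return result


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def standardize_compound(
    record: CompoundRecord,
    cap: int = DEFAULT_STEREO_CAP,
    ph: float = DEFAULT_PH,
) -> Union[List[StandardizedCompound], DiscardRecord]:
    """Run a single compound through all standardization stages."""
    mol = record.mol
    if mol is None:
        return DiscardRecord(record.compound_id, DiscardReason.NULL_STRUCTURE)
    audit: List[str] = []

    reason = element_and_species_filter(mol)
    if reason is not None:
        return DiscardRecord(record.compound_id, reason)
    if heavy_atom_mw(mol) <= 0.0:
        return DiscardRecord(record.compound_id, DiscardReason.NULL_STRUCTURE)

    frag = largest_fragment(mol)
    if frag.GetNumAtoms() != mol.GetNumAtoms():
        audit.append("largest_fragment")
    if heavy_atom_mw(frag) <= 0.0:
        return DiscardRecord(record.compound_id, DiscardReason.NULL_STRUCTURE)

    norm = normalize(frag)
    if norm is None:
        return DiscardRecord(record.compound_id, DiscardReason.NULL_STRUCTURE,
                             "unfixable valence after normalization")
    audit.append("normalize")

    taut = canonical_tautomer(norm)
    audit.append("canonical_tautomer")

    isomers = enumerate_stereoisomers(taut, cap=cap)
    if len(isomers) > 1:
        audit.append(f"enumerate_stereoisomers:{len(isomers)}")

    out = []
    for i, iso in enumerate(isomers, start=1):
        final = major_microspecies(iso, ph=ph)
        out.append(
            StandardizedCompound(
                parent_id=record.compound_id,
                mol=final,
                stereo_index=i,
                audit=list(audit) + ["major_microspecies"],
                original_smiles=record.smiles,
                properties=dict(record.properties),
            )
        )
    return out


def standardize_pipeline(
    records: Iterable[CompoundRecord],
    cap: int = DEFAULT_STEREO_CAP,
    ph: float = DEFAULT_PH,
) -> Tuple[List[StandardizedCompound], List[DiscardRecord]]:
    """Standardize a library.  Count conservation holds:
    ``|input| == |distinct surviving parent ids| + |discards|``."""
    survivors: List[StandardizedCompound] = []
    discards: List[DiscardRecord] = []
    for record in records:
        result = standardize_compound(record, cap=cap, ph=ph)
        if isinstance(result, DiscardRecord):
            discards.append(result)
        else:
            survivors.extend(result)
    return survivors, discards
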