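"""3D embedding of post-reacted ligands.

The covalent reaction can create new stereocenters (e.g. the beta-carbon
of a Michael adduct).  Up to two such centers are enumerated (2^2 = 4
isomers); beyond that, only the first four assignments in the deterministic
enumeration order are embedded.  One conformer is generated per
stereoisomer with a distance-geometry embedder using experimental-torsion
preferences; the docking engine samples torsions itself, so a single input
conformer suffices.

Atom order is preserved through embedding, so the recorded link-atom index
stays valid in the 3D output.
"""
from __future__ import annotations

import logging
from typing import List

from rdkit import Chem
from rdkit.Chem import AllChem

from .records import DiscardReason, DiscardRecord, PostReactedLigand
from .standardizer import enumerate_stereoisomers

log = logging.getLogger(__name__)

DEFAULT_NEW_STEREOCENTER_CAP = 2
_EMBED_RETRIES = 5


def embed_3d(
    ligand: PostReactedLigand,
    max_new_stereocenters: int = DEFAULT_NEW_STEREOCENTER_CAP,
    seed: int = 0,
) -> List[PostReactedLigand]:
    """Embed one 2D ligand into 3D, enumerating reaction-born stereocenters.

    Returns up to ``2 ** max_new_stereocenters`` embedded copies; raises
    nothing — ligands whose embedding fails are reported via a
    ``DiscardRecord`` in the companion :func:`embed_library` API.
    """
    cap = 2 ** max_new_stereocenters
    isomers = enumerate_stereoisomers(ligand.mol, cap=max(cap, 1))
    if len(isomers) > cap:
        isomers = isomers[:cap]
    out: List[PostReactedLigand] = []
    for j, iso in enumerate(isomers):
        mol_h = Chem.AddHs(iso)
        params = AllChem.ETKDGv3()
        conf_id = -1
        for attempt in range(_EMBED_RETRIES):
            params.randomSeed = int(seed) + 1000 * attempt + j
            conf_id = AllChem.EmbedMolecule(mol_h, params)
            if conf_id == 0:
                break
        if conf_id != 0:
            continue
        mol3d = Chem.RemoveHs(mol_h)  # heavy-atom order preserved
        out.append(
            PostReactedLigand(
                parent_id=ligand.parent_id,
                stereo_index=ligand.stereo_index,
                mol=mol3d,
                link_atom_index=ligand.link_atom_index,
                link_atom_element=ligand.link_atom_element,
                reaction_id=ligand.reaction_id,
                original_smiles=ligand.original_smiles,
                properties=dict(ligand.properties),
            )
        )
    return out


def embed_library(
    ligands,
    max_new_stereocenters: int = DEFAULT_NEW_STEREOCENTER_CAP,
    seed: int = 0,
):
    """Embed a list of ligands; returns (embedded, discards)."""
    embedded: List[PostReactedLigand] = []
    discards: List[DiscardRecord] = []
    for lig in ligands:
        got = embed_3d(lig, max_new_stereocenters=max_new_stereocenters, seed=seed)
        if not got:
            discards.append(
                DiscardRecord(lig.parent_id, DiscardReason.NULL_STRUCTURE,
                              "3D embedding failed")
            )
        embedded.extend(got)
    return embedded, discards
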