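import csv
import os

import pytest
from rdkit import Chem, RDLogger

from covprep import fixtures as fx
from covprep import io as cio
from covprep.reactor import load_reactions
from covprep.warheads import load_warhead_library

RDLogger.DisableLog("rdApp.*")

HERE = os.path.dirname(__file__)


@pytest.fixture(scope="session")
def warhead_lib():
    return load_warhead_library()


@pytest.fixture(scope="session")
def reactions(warhead_lib):
    return load_reactions(warhead_library=warhead_lib)


@pytest.fixture(scope="session")
def warhead_examples():
    """warhead_id -> representative molecule bearing that warhead."""
    out = {}
    with open(os.path.join(HERE, "data", "warhead_examples.tsv")) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mol = Chem.MolFromSmiles(row["example_smiles"])
            assert mol is not None
            out[row["warhead_id"]] = mol
    return out


@pytest.fixture(scope="session")
def toy_library(tmp_path_factory):
    """The 15-record adversarial fixture library plus its manifest."""
    d = tmp_path_factory.mktemp("toylib")
    sdf = str(d / "toy_library.sdf")
    manifest = str(d / "manifest.csv")
    entries = fx.generate_toy_library(sdf, manifest, seed=7)
    return {"sdf": sdf, "manifest": manifest, "entries": entries}


@pytest.fixture(scope="session")
def toy_protein(tmp_path_factory):
    d = tmp_path_factory.mktemp("toyprot")
    path, sg_serial = fx.toy_protein_mol2(str(d / "toy_protein.mol2"))
    return {"path": path, "sg_serial": sg_serial}


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m
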