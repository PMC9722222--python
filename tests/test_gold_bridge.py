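"""mol2 parsing, conf emission, sharding, mock docking, complex assembly."""
import math
import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from covprep import fixtures as fx
from covprep import gold_bridge as gb
from covprep import io as cio
from covprep import pipeline, reactor, conformers
from covprep.mol2 import Mol2Error, ResidueSpec, find_protein_link_atom, read_mol2


class TestMol2:
    def test_parse_toy_protein(self, toy_protein):
        struct = read_mol2(toy_protein["path"])
        assert len(struct.atoms) == 7
        sg = struct.atom_by_serial(toy_protein["sg_serial"])
        assert sg.name == "SG" and sg.element == "S"
        assert sg.coords == fx.SG_COORDS

    def test_find_link_atom(self, toy_protein):
        assert find_protein_link_atom(toy_protein["path"], "A:CYS:25:SG") == \
            toy_protein["sg_serial"]

    def test_chain_optional(self, toy_protein):
        assert find_protein_link_atom(toy_protein["path"], "CYS:25:SG") == 4

    def test_wrong_residue_name_fatal(self, toy_protein):
        with pytest.raises(Mol2Error, match="not found"):
            find_protein_link_atom(toy_protein["path"], "A:SER:25:SG")

    def test_ambiguous_without_chain_fatal(self, tmp_path):
        # two chains each holding CYS25; the query omits the chain
        dup = tmp_path / "two_chains.mol2"
        dup.write_text(
            "@<TRIPOS>MOLECULE\ntwo_chains\n 4 0 2\nSMALL\nNO_CHARGES\n\n"
            "@<TRIPOS>ATOM\n"
            "      1 CB    0.0 0.0 0.0 C.3   1 CYS25 0.0\n"
            "      2 SG    1.8 0.0 0.0 S.3   1 CYS25 0.0\n"
            "      3 CB    9.0 0.0 0.0 C.3   2 CYS25 0.0\n"
            "      4 SG   10.8 0.0 0.0 S.3   2 CYS25 0.0\n"
            "@<TRIPOS>SUBSTRUCTURE\n"
            "     1 CYS25 1 RESIDUE 1 A CYS 1\n"
            "     2 CYS25 3 RESIDUE 1 B CYS 1\n")
        with pytest.raises(Mol2Error, match="ambiguous"):
            find_protein_link_atom(str(dup), "CYS:25:SG")
        # fully qualified specs resolve fine
        assert find_protein_link_atom(str(dup), "A:CYS:25:SG") == 2
        assert find_protein_link_atom(str(dup), "B:CYS:25:SG") == 4


class TestConfig:
    def test_exactly_four_scoring_functions(self):
        assert gb.SCORING_FUNCTIONS == ("GoldScore", "ASP", "ChemScore", "PLP")

    def test_unknown_scoring_function_rejected(self, toy_protein):
        with pytest.raises(gb.DockingError, match="scoring"):
            gb.DockingConfig(
                protein_file=toy_protein["path"],
                residue_spec=ResidueSpec.parse("A:CYS:25:SG"),
                protein_link_atom_no=4, scoring_function="Vina")

    def test_conf_round_trip(self, tmp_path, toy_protein):
        config = gb.DockingConfig(
            protein_file=toy_protein["path"],
            residue_spec=ResidueSpec.parse("A:CYS:25:SG"),
            protein_link_atom_no=4, scoring_function="ASP", n_poses=7,
            output_dir=str(tmp_path))
        conf_path = str(tmp_path / "lig.conf")
        gb.write_conf(conf_path, config, "lig.sdf", ligand_link_atom=5)
        back = gb.read_conf(conf_path)
        assert back["scoring_function"] == "ASP"
        assert int(back["n_poses"]) == 7
        assert int(back["protein_atom"]) == 4
        assert int(back["ligand_atom"]) == 5
        assert back["covalent"] == "1"
        assert back["protein_file"] == toy_protein["path"]


class TestSharding:
    def test_ten_into_four(self):
        assert gb.shard_sizes(10, 4) == [3, 3, 2, 2]

    @given(st.integers(0, 500), st.integers(1, 32))
    @settings(max_examples=100, deadline=None)
    def test_balanced_partition_property(self, n, k):
        sizes = gb.shard_sizes(n, k)
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        assert len(sizes) == k


@pytest.fixture(scope="module")
def docking_run(tmp_path_factory, toy_protein):
    """prepare -> run -> process on the fixture protein + toy actives."""
    d = tmp_path_factory.mktemp("dockrun")
    sdf = str(d / "lib.sdf")
    fx.generate_toy_library(sdf, str(d / "man.csv"), n_clean_actives=5,
                            n_decoys=5, n_salts=0, n_isotopes=0,
                            n_multiwarhead=0, n_repeated=0, n_badelement=0,
                            seed=7)
    records, _ = cio.read_library(sdf)
    prep = pipeline.prepare_library(records, "Cys")
    embedded, _ = conformers.embed_library(prep.ligands, seed=7)
    lig3d = str(d / "prepared3d.sdf")
    reactor.write_prepared_sdf(embedded, lig3d)
    config = gb.DockingConfig(
        protein_file=toy_protein["path"],
        residue_spec=ResidueSpec.parse("A:CYS:25:SG"),
        protein_link_atom_no=toy_protein["sg_serial"],
        scoring_function="PLP", n_poses=2, n_shards=4,
        output_dir=str(d / "dock"))
    confs, ligfiles, commands = gb.prepare(lig3d, config)
    poses, failures = gb.run(commands, gb.MockBackend(seed=7))
    complexes = gb.process(poses, toy_protein["path"], config,
                           out_sdf=str(d / "complexes.sdf"))
    return {"dir": d, "config": config, "confs": confs, "ligfiles": ligfiles,
            "commands": commands, "poses": poses, "failures": failures,
            "complexes": complexes, "lig3d": lig3d}


class TestPrepare:
    def test_one_conf_and_sdf_per_ligand(self, docking_run):
        assert len(docking_run["confs"]) == 10
        assert len(docking_run["ligfiles"]) == 10
        for path in docking_run["confs"] + docking_run["ligfiles"]:
            assert os.path.exists(path)

    def test_shard_manifests_partition_ligands(self, docking_run):
        seen = []
        for cmd in docking_run["commands"]:
            manifest = cmd.split("--manifest")[-1].strip()
            seen.append(sum(1 for ln in open(manifest) if ln.strip()))
        assert seen == [3, 3, 2, 2]

    def test_conf_contains_ligand_link_atom(self, docking_run):
        ligands = reactor.read_prepared_sdf(docking_run["lig3d"])
        for conf_path, lig in zip(docking_run["confs"], ligands):
            assert int(gb.read_conf(conf_path)["ligand_atom"]) == lig.link_atom_index

    def test_zero_valid_ligands_fatal(self, tmp_path, docking_run):
        empty = str(tmp_path / "none.sdf")
        open(empty, "w").close()
        with pytest.raises(gb.DockingError):
            gb.prepare(empty, docking_run["config"])


class TestRun:
    def test_pose_count_and_order(self, docking_run):
        poses = docking_run["poses"]
        assert len(poses) == 20  # 10 ligands x 2 poses
        keys = [(p.ligand_id, p.pose_index) for p in poses]
        assert keys == sorted(keys)
        assert docking_run["failures"] == []

    def test_seeded_reproducibility(self, docking_run):
        poses2, _ = gb.run(docking_run["commands"], gb.MockBackend(seed=7))
        for a, b in zip(docking_run["poses"], poses2):
            assert a.score == b.score
            ca, cb = a.mol.GetConformer(), b.mol.GetConformer()
            for i in range(a.mol.GetNumAtoms()):
                assert list(ca.GetAtomPosition(i)) == list(cb.GetAtomPosition(i))

    def test_corrupted_ligand_recorded_not_fatal(self, tmp_path, docking_run,
                                                 toy_protein):
        manifest = docking_run["commands"][0].split("--manifest")[-1].strip()
        entries = [ln.split("\t") for ln in open(manifest).read().splitlines()]
        bad = str(tmp_path / "corrupt.sdf")
        open(bad, "w").write("garbage\n")
        new_manifest = str(tmp_path / "shard.txt")
        with open(new_manifest, "w") as fh:
            fh.write(f"{entries[0][0]}\t{bad}\n")
            for conf, lig in entries[1:]:
                fh.write(f"{conf}\t{lig}\n")
        poses, failures = gb.run([f"x --manifest {new_manifest}"],
                                 gb.MockBackend(seed=7))
        assert failures == [bad]
        assert len(poses) == (len(entries) - 1) * 2

    def test_empty_command_list(self):
        poses, failures = gb.run([], gb.MockBackend(seed=0))
        assert poses == [] and failures == []


class TestProcess:
    def test_one_complex_per_pose(self, docking_run):
        assert len(docking_run["complexes"]) == len(docking_run["poses"]) == 20

    def test_exactly_one_added_bond(self, docking_run, toy_protein):
        protein_mol, _ = gb.mol2_to_rdkit(read_mol2(toy_protein["path"]))
        for c, pose in zip(docking_run["complexes"], docking_run["poses"]):
            # the thiol H of the protein SG is consumed by the new bond
            expected = (protein_mol.GetNumBonds() - 1) + pose.mol.GetNumBonds() + 1
            assert c.mol.GetNumBonds() == expected
            a1, a2 = c.new_bond
            bond = c.mol.GetBondBetweenAtoms(a1 - 1, a2 - 1)
            assert bond is not None
            assert {c.mol.GetAtomWithIdx(a1 - 1).GetSymbol(),
                    c.mol.GetAtomWithIdx(a2 - 1).GetSymbol()} == {"S"}

    def test_coordinates_unchanged(self, docking_run):
        pose = docking_run["poses"][0]
        c = docking_run["complexes"][0]
        lig_conf = pose.mol.GetConformer()
        merged_conf = c.mol.GetConformer()
        n_prot_heavy = c.mol.GetNumAtoms() - pose.mol.GetNumAtoms()
        for i in range(pose.mol.GetNumAtoms()):
            assert list(merged_conf.GetAtomPosition(n_prot_heavy + i)) == \
                pytest.approx(list(lig_conf.GetAtomPosition(i)))

    def test_thiol_hydrogen_removed_for_valence(self, docking_run, toy_protein):
        # protein SG carried an explicit HG; after bonding, S has 2 heavy
        # neighbours and no H left
        c = docking_run["complexes"][0]
        s_idx = c.new_bond[0] - 1
        atom = c.mol.GetAtomWithIdx(s_idx)
        assert atom.GetSymbol() == "S"
        assert atom.GetDegree() == 2
        assert all(n.GetAtomicNum() != 1 for n in atom.GetNeighbors())

    def test_empty_pose_list(self, toy_protein, docking_run):
        assert gb.process([], toy_protein["path"], docking_run["config"]) == []

    def test_output_sdf_carries_provenance(self, docking_run):
        path = str(docking_run["dir"] / "complexes.sdf")
        mols = [m for m in Chem.SDMolSupplier(path, removeHs=False, sanitize=False)]
        assert len(mols) == 20
        for m in mols:
            assert m.HasProp("Ligand_ID") and m.HasProp("Score")


class TestNoncovalentFilter:
    def test_distance_cutoff(self, toy_protein):
        near = fx.pose_at_distance(4.2)
        far = fx.pose_at_distance(6.1)
        kept = gb.noncovalent_filter([near, far], toy_protein["path"],
                                     toy_protein["sg_serial"], cutoff=5.0)
        assert kept == [near]

    def test_infinite_cutoff_is_identity(self, toy_protein):
        poses = [fx.pose_at_distance(d) for d in (1.0, 4.2, 6.1, 40.0)]
        kept = gb.noncovalent_filter(poses, toy_protein["path"],
                                     toy_protein["sg_serial"],
                                     cutoff=math.inf)
        assert kept == poses

    def test_default_cutoff_is_five_angstrom(self):
        assert gb.DEFAULT_DISTANCE_CUTOFF == 5.0

    def test_fixture_geometry_exact(self, toy_protein):
        pose = fx.pose_at_distance(4.2)
        pos = pose.mol.GetConformer().GetAtomPosition(pose.link_atom_index - 1)
        assert math.dist(fx.SG_COORDS, (pos.x, pos.y, pos.z)) == pytest.approx(4.2)
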