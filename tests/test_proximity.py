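import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from biaslens.core_io import Atom, Residue, StructureModel
from biaslens.proximity import (
    apply_transform,
    build_column_mapping,
    candidate_sites,
    kabsch_superpose,
    min_cluster_distance,
    superpose_models,
)
from biaslens.core_io import Alignment, SequenceRecord
from biaslens.synthetic import PlantedResidue, gen_structure, stream_rng


def _cloud(rng, n=20, spread=10.0):
    return rng.normal(0.0, spread, size=(n, 3))


class TestKabsch:
    def test_identity(self):
        rng = stream_rng(1, "kabsch")
        pts = _cloud(rng)
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_pure_translation_recovered(self):
        rng = stream_rng(2, "kabsch")
        pts = _cloud(rng)
        rot, trans, rmsd = kabsch_superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, [5.0, 0.0, 0.0], atol=1e-9)

    def test_rotation_with_noise_matches_scipy_oracle(self):
        rng = stream_rng(3, "kabsch")
        target = _cloud(rng, n=40)
        true_rot = Rotation.random(rng=123).as_matrix()
        noise = rng.normal(0.0, 0.1, size=target.shape)
        mobile = (target + noise) @ true_rot  # rotate noisy copy away
        rot, trans, rmsd = kabsch_superpose(mobile, target)
        # independent oracle: scipy's own least-squares superposition
        mob_c = mobile - mobile.mean(axis=0)
        tgt_c = target - target.mean(axis=0)
        oracle_rot, rssd = Rotation.align_vectors(tgt_c, mob_c)
        assert np.allclose(rot, oracle_rot.as_matrix(), atol=1e-6)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(target)), abs=1e-9)
        # mobile rows were right-multiplied by true_rot, i.e., each point was
        # rotated by true_rot.T; the fit must recover the inverse of that
        assert np.allclose(rot, true_rot, atol=0.05)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_superpose_models_moves_everything(self):
        coords = [(0.0, 0.0, 0.0), (8.0, 1.0, 0.5), (2.0, 9.0, 1.0), (1.0, 2.0, 7.0)]
        model = StructureModel(
            [
                Residue("A", n, "ALA", [Atom("CA", "C", *xyz)])
                for n, xyz in enumerate(coords, start=1)
            ],
            {"C1": [Atom("FE1", "FE", 4.0, 4.0, 4.0)]},
        )
        rot = Rotation.from_euler("xyz", [0.3, -0.2, 0.9]).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])

        def move(atom):
            x, y, z = rot @ atom.coord + shift
            return Atom(atom.name, atom.element, x, y, z)

        moved = StructureModel(
            [Residue(r.chain, r.number, r.name, [move(a) for a in r.atoms]) for r in model.residues],
            {k: [move(a) for a in v] for k, v in model.cluster_groups.items()},
        )
        pairs = [(("A", n), ("A", n)) for n in (1, 2, 3, 4)]
        fitted, rmsd = superpose_models(moved, model, pairs)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        for res_f, res_o in zip(fitted.residues, model.residues):
            assert np.allclose(res_f.atoms[0].coord, res_o.atoms[0].coord, atol=1e-6)


class TestMinClusterDistance:
    def test_coincident_atom_zero(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", 1.0, 2.0, 3.0)])
        cluster = [Atom("FE1", "FE", 1.0, 2.0, 3.0)]
        assert min_cluster_distance(res, cluster) == 0.0

    def test_three_four_five(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", 3.0, 4.0, 0.0)])
        cluster = [Atom("FE1", "FE", 0.0, 0.0, 0.0)]
        assert min_cluster_distance(res, cluster) == pytest.approx(5.0)

    def test_hydrogens_ignored(self):
        res = Residue(
            "A", 1, "ALA",
            [Atom("CA", "C", 3.0, 4.0, 0.0), Atom("H", "H", 0.1, 0.0, 0.0)],
        )
        cluster = [Atom("FE1", "FE", 0.0, 0.0, 0.0)]
        assert min_cluster_distance(res, cluster) == pytest.approx(5.0)

    def test_planted_distance(self):
        model, truth = gen_structure(
            [PlantedResidue(7, "LYS", "FS4B", 4.2)], {"FS4B": 4}, seed=6
        )
        res = model.get_residue("A", 7)
        d = min_cluster_distance(res, model.cluster_groups["FS4B"])
        assert d == pytest.approx(4.2, abs=1e-9)

    def test_empty_cluster_errors(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", 0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="empty"):
            min_cluster_distance(res, [])


def _profile(columns):
    return pd.DataFrame(
        [{"column": c, "res_a": "A", "res_b": "S", "pct_a": 50.0, "pct_b": 40.0,
          "pct_other": 10.0} for c in columns]
    )


class TestCandidateSites:
    @pytest.fixture
    def toy(self):
        planted = [
            PlantedResidue(10, "ALA", "H2Fe", 2.0),
            PlantedResidue(20, "ILE", "FS4A", 4.5),
            PlantedResidue(30, "MET", "FS4B", 4.9),
            PlantedResidue(40, "LYS", "FS4B", 6.5),
            PlantedResidue(50, "PHE", "FS2", 9.0),
            PlantedResidue(60, "VAL", "H2Fe", 11.0),
        ]
        model, truth = gen_structure(
            planted, {"H2Fe": 2, "FS4A": 4, "FS4B": 4, "FS2": 4}, seed=8
        )
        return model, truth

    def test_planted_within_cutoff_set(self, toy):
        model, truth = toy
        numbers = [r["number"] for r in truth["residues"]]
        mapping = {n: (n, None) for n in numbers}
        sites = candidate_sites(_profile(numbers), model, None, mapping, 5.0, "reference")
        assert [s.ref_number for s in sites] == [10, 20, 30]
        assert [s.region for s in sites] == ["H-cluster", "FS4A", "FS4B"]
        for site in sites:
            expected = next(
                r["distance"] for r in truth["residues"] if r["number"] == site.ref_number
            )
            assert site.min_distance == pytest.approx(expected, abs=1e-9)

    def test_cutoff_zero_normally_empty(self, toy):
        model, truth = toy
        numbers = [r["number"] for r in truth["residues"]]
        mapping = {n: (n, None) for n in numbers}
        assert candidate_sites(_profile(numbers), model, None, mapping, 0.0, "reference") == []

    def test_cutoff_monotonicity(self, toy):
        model, truth = toy
        numbers = [r["number"] for r in truth["residues"]]
        mapping = {n: (n, None) for n in numbers}
        small = candidate_sites(_profile(numbers), model, None, mapping, 4.0, "reference")
        large = candidate_sites(_profile(numbers), model, None, mapping, 5.0, "reference")
        assert {s.ref_number for s in small} <= {s.ref_number for s in large}

    def test_rigid_transform_invariance(self, toy):
        model, truth = toy
        rot = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        shift = np.array([3.0, -8.0, 2.0])

        def move(atom):
            x, y, z = rot @ atom.coord + shift
            return Atom(atom.name, atom.element, x, y, z)

        moved = StructureModel(
            [Residue(r.chain, r.number, r.name, [move(a) for a in r.atoms])
             for r in model.residues],
            {k: [move(a) for a in v] for k, v in model.cluster_groups.items()},
        )
        numbers = [r["number"] for r in truth["residues"]]
        mapping = {n: (n, None) for n in numbers}
        s1 = candidate_sites(_profile(numbers), model, None, mapping, 5.0, "reference")
        s2 = candidate_sites(_profile(numbers), moved, None, mapping, 5.0, "reference")
        assert [s.ref_number for s in s1] == [s.ref_number for s in s2]
        for a, b in zip(s1, s2):
            assert a.min_distance == pytest.approx(b.min_distance, abs=1e-8)

    def test_either_mode_takes_union_minimum(self, toy):
        model, truth = toy
        # model copy where residue 40 sits close to its cluster
        near, _ = gen_structure(
            [PlantedResidue(40, "LYS", "FS4B", 3.0)], {"FS4B": 4}, seed=8
        )
        mapping = {40: (40, 40)}
        ref_only = candidate_sites(_profile([40]), model, near, mapping, 5.0, "reference")
        either = candidate_sites(_profile([40]), model, near, mapping, 5.0, "either")
        assert ref_only == []
        assert [s.ref_number for s in either] == [40]

    def test_unmapped_column_skipped(self, toy):
        model, truth = toy
        sites = candidate_sites(_profile([999]), model, None, {999: (None, None)}, 5.0, "reference")
        assert sites == []

    def test_no_clusters_errors(self):
        bare = StructureModel(
            [Residue("A", 1, "ALA", [Atom("CA", "C", 0.0, 0.0, 0.0)])], {}
        )
        with pytest.raises(ValueError, match="cluster"):
            candidate_sites(_profile([1]), bare, None, {1: (1, None)}, 5.0, "reference")


def test_build_column_mapping_follows_gaps():
    aln = Alignment(
        [SequenceRecord("ref", "AC-DE"), SequenceRecord("mod", "-CQDE")]
    )
    mapping = build_column_mapping(aln, "ref", "mod", ref_offset=10, model_offset=0)
    assert mapping[1] == (11, None)
    assert mapping[2] == (12, 1)
    assert mapping[3] == (None, 2)
    assert mapping[5] == (14, 4)
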