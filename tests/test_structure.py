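import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from flavimine.structure import (
    detect_heme_his_pairs,
    detect_tm_segments,
    kabsch_superpose,
    motif_pocket_distance,
    read_pdb,
)
from flavimine.synthetic import (
    SimConfig,
    simulate_structure,
    tm_test_sequence,
    write_structure,
)


def _pdb_line(serial, name, resname, chain, resseq, xyz, occ=1.0, altloc=" ",
              record="ATOM"):
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          "
        f"{name[0]:>2s}"
    )


class TestReadPdb:
    def test_first_model_only(self, tmp_path):
        lines = [
            "MODEL        1",
            _pdb_line(1, "CA", "ALA", "A", 1, (1, 2, 3)),
            "ENDMDL",
            "MODEL        2",
            _pdb_line(2, "CA", "ALA", "A", 1, (9, 9, 9)),
            "ENDMDL",
            "END",
        ]
        path = tmp_path / "two_model.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        np.testing.assert_allclose(model.chains["A"][0].coord("CA"), [1, 2, 3])

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "SER", "A", 1, (0, 0, 0), occ=0.6, altloc="A"),
            _pdb_line(2, "CA", "SER", "A", 1, (5, 5, 5), occ=0.4, altloc="B"),
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        np.testing.assert_allclose(model.chains["A"][0].coord("CA"), [0, 0, 0])

    def test_fmn_ligand_kept_separately(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0)),
            _pdb_line(2, "C1", "FMN", "A", 90, (3, 4, 0), record="HETATM"),
            "END",
        ]
        path = tmp_path / "ligand.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        assert [lig.name for _c, lig in model.ligands] == ["FMN"]
        assert len(model.chains["A"]) == 1

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            read_pdb(path)


class TestDetectTmSegments:
    def test_single_hydrophobic_stretch(self):
        seq = "D" * 20 + "I" * 19 + "D" * 20
        segments = detect_tm_segments(seq)
        assert len(segments) == 1
        assert segments[0].mean_hydropathy == pytest.approx(4.5)

    def test_polar_sequence_has_no_segments(self):
        assert detect_tm_segments("D" * 60) == []

    def test_too_short_sequence_empty(self):
        assert detect_tm_segments("I" * 10) == []

    @pytest.mark.parametrize("n_helices", [1, 3, 6])
    def test_planted_topology_recovered(self, n_helices):
        seq = tm_test_sequence(n_helices=n_helices, seed=n_helices)
        assert len(detect_tm_segments(seq)) == n_helices

    def test_segments_at_least_window_long(self):
        seq = tm_test_sequence(n_helices=4, seed=0)
        for seg in detect_tm_segments(seq):
            assert seg.end - seg.start + 1 >= 19


def _toy_structure(planted, chains=None):
    cfg = SimConfig(
        structure_chains=chains or {"A": "A" * 60},
        planted_his=planted,
    )
    st, truth = simulate_structure(cfg)
    return st, truth


def _as_model(st, tmp_path, name="toy.pdb"):
    path = tmp_path / name
    write_structure(st, path)
    return read_pdb(path)


class TestDetectHemeHisPairs:
    def test_planted_pair_at_42A_found(self, tmp_path):
        st, _ = _toy_structure(
            [("A", 10, (0.0, 0.0, 0.0)), ("A", 40, (0.0, 0.0, 4.2))]
        )
        model = _as_model(st, tmp_path)
        pairs = detect_heme_his_pairs(model)
        assert len(pairs) == 1
        assert pairs[0].inter_atom_distance == pytest.approx(4.2, abs=1e-3)
        assert pairs[0].same_chain

    def test_pair_at_10A_rejected_at_default_cutoff(self, tmp_path):
        st, _ = _toy_structure(
            [("A", 10, (0.0, 0.0, 0.0)), ("A", 40, (0.0, 0.0, 10.0))]
        )
        assert detect_heme_his_pairs(_as_model(st, tmp_path)) == []

    def test_adjacent_his_excluded_by_sequence_separation(self, tmp_path):
        st, _ = _toy_structure(
            [("A", 10, (0.0, 0.0, 0.0)), ("A", 12, (0.0, 0.0, 4.0))]
        )
        assert detect_heme_his_pairs(_as_model(st, tmp_path)) == []

    def test_cross_chain_dimer_site(self, tmp_path):
        st, _ = _toy_structure(
            [("A", 10, (0.0, 0.0, 0.0)), ("B", 10, (0.0, 0.0, 4.5))],
            chains={"A": "A" * 30, "B": "A" * 30},
        )
        pairs = detect_heme_his_pairs(_as_model(st, tmp_path))
        assert len(pairs) == 1
        assert not pairs[0].same_chain
        assert pairs[0].sequence_separation is None

    def test_fewer_than_two_his_empty(self, tmp_path):
        st, _ = _toy_structure([("A", 10, (0.0, 0.0, 0.0))])
        assert detect_heme_his_pairs(_as_model(st, tmp_path)) == []

    def test_invariant_under_rigid_motion(self, tmp_path):
        st, _ = _toy_structure(
            [("A", 10, (1.0, 2.0, 3.0)), ("A", 45, (1.0, 2.0, 7.2))]
        )
        model = _as_model(st, tmp_path)
        baseline = detect_heme_his_pairs(model)
        rng = np.random.default_rng(0)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = model.transformed(rot, rng.normal(scale=20.0, size=3))
            pairs = detect_heme_his_pairs(moved)
            assert len(pairs) == len(baseline) == 1
            assert pairs[0].inter_atom_distance == pytest.approx(
                baseline[0].inter_atom_distance, abs=1e-6
            )


def quaternion_grid_oracle(a, b, n_coarse=600, seed=0):
    """Brute-force rigid superposition: coarse random-rotation search
    refined by Nelder-Mead over the rotation vector."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum(((rot @ a0.T).T - b0) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = min(
        (Rotation.random(rng=rng).as_rotvec() for _ in range(n_coarse)),
        key=rmsd_of,
    )
    result = minimize(rmsd_of, best, method="Nelder-Mead",
                      options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return float(result.fun)


class TestKabsch:
    def _random_points(self, seed, n=30):
        return np.random.default_rng(seed).normal(size=(n, 3))

    def test_exact_rigid_motion_gives_zero_rmsd(self):
        a = self._random_points(1)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = (rot90 @ a.T).T + np.array([5.0, 0.0, 0.0])
        rotation, translation, rmsd = kabsch_superpose(a, b)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(rotation, rot90, atol=1e-9)

    def test_identity_on_self(self):
        a = self._random_points(2)
        rotation, translation, rmsd = kabsch_superpose(a, a)
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(translation, 0.0, atol=1e-9)
        assert rmsd <= 1e-12

    def test_symmetry(self):
        a, b = self._random_points(3), self._random_points(4)
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-9
        )

    def test_proper_rotation_enforced(self):
        a = self._random_points(5)
        b = a.copy()
        b[:, 0] *= -1  # reflection cannot be matched by a proper rotation
        rotation, _t, rmsd = kabsch_superpose(a, b)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(6)
        a, b = self._random_points(7), self._random_points(8)
        base = kabsch_superpose(a, b)[2]
        rot = Rotation.random(rng=rng).as_matrix()
        moved = (rot @ a.T).T + rng.normal(scale=10.0, size=3)
        assert kabsch_superpose(moved, b)[2] == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_agreement_with_brute_force_oracle_on_noisy_cases(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            a = rng.normal(size=(50, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            b = (rot @ a.T).T + rng.normal(size=3) + rng.normal(scale=0.1, size=(50, 3))
            rmsd = kabsch_superpose(a, b)[2]
            oracle = quaternion_grid_oracle(a, b, seed=trial)
            assert rmsd == pytest.approx(oracle, abs=1e-3)
            assert rmsd <= oracle + 1e-9  # Kabsch is the optimum

    def test_noisy_rmsd_matches_small_noise_expectation(self):
        # isotropic sigma=0.1 noise on n=50 points: rmsd ~ sigma*sqrt(3 - 7/n)
        rng = np.random.default_rng(10)
        sigma, n = 0.1, 50
        rmsds = []
        for _ in range(20):
            a = rng.normal(size=(n, 3))
            b = a + rng.normal(scale=sigma, size=(n, 3))
            rmsds.append(kabsch_superpose(a, b)[2])
        expected = sigma * np.sqrt(3 - 7 / n)
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.1)


class TestMotifPocketDistance:
    def test_three_four_five_triangle(self, tmp_path):
        st, _ = _toy_structure([("A", 5, (0.0, 0.0, 0.0))])
        model = _as_model(st, tmp_path)
        # planted His NE2 at origin serves as the "motif" atom is absent;
        # use CA-based pocket: place pocket residues around a known centroid
        res = model.chains["A"]
        motif_ca = res[4].coord("CA")  # His CA at NE2 + (2,0,0) = (2,0,0)
        pocket = [("A", res[20].number), ("A", res[21].number)]
        centroid = (res[20].coord("CA") + res[21].coord("CA")) / 2
        dist, _prox = motif_pocket_distance(model, "A", res[4].number,
                                            pocket_residues=pocket)
        assert dist == pytest.approx(float(np.linalg.norm(motif_ca - centroid)), abs=1e-3)

    def test_ligand_centroid_distance(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "SER", "A", 1, (0, 0, 0)),
            _pdb_line(2, "OG", "SER", "A", 1, (0, 0, 0)),
            _pdb_line(3, "C1", "FMN", "B", 900, (3, 4, 0), record="HETATM"),
            "END",
        ]
        path = tmp_path / "fmn.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        dist, proximal = motif_pocket_distance(model, "A", 1, ligand_name="FMN")
        assert dist == pytest.approx(5.0, abs=1e-6)
        assert proximal

    def test_proximal_flag_depends_on_cutoff(self, tmp_path):
        lines = [
            _pdb_line(1, "OG", "SER", "A", 1, (0, 0, 0)),
            _pdb_line(2, "C1", "FMN", "B", 900, (12, 0, 0), record="HETATM"),
            "END",
        ]
        path = tmp_path / "far.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        assert motif_pocket_distance(model, "A", 1, ligand_name="FMN",
                                     proximal_cutoff=15.0)[1]
        assert not motif_pocket_distance(model, "A", 1, ligand_name="FMN",
                                         proximal_cutoff=10.0)[1]

    def test_missing_pocket_residues_listed(self, tmp_path):
        st, _ = _toy_structure([("A", 5, (0.0, 0.0, 0.0))])
        model = _as_model(st, tmp_path)
        with pytest.raises(ValueError, match="B/99"):
            motif_pocket_distance(model, "A", 5, pocket_residues=[("B", 99)])
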