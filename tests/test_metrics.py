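"""Overlap matrices, RWSIP, RMSF correlations, distance observables."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conformetrics as cm
from conformetrics.metrics import DEFAULT_N_PCS, summarize
from conformetrics.pca import PCAResults


def _pc_model(components, eigenvalues, n_residues, keys=None):
    """Assemble a PCAResults directly from a (k, 3N) orthonormal row set."""
    components = np.asarray(components, float)
    eigenvalues = np.asarray(eigenvalues, float)
    if keys is None:
        keys = tuple(("A", i + 1, "") for i in range(n_residues))
    return PCAResults(np.zeros((n_residues, 3)), eigenvalues, components,
                      keys, total_variance=float(eigenvalues.sum()))


def _random_orthonormal(rng, dim, k):
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return q.T


def _random_model(rng, n_residues=4, k=3):
    comps = _random_orthonormal(rng, 3 * n_residues, k)
    evals = np.sort(rng.uniform(0.1, 5.0, size=k))[::-1]
    return _pc_model(comps, evals, n_residues)


def rwsip_bruteforce(a, b, n):
    """Independent double-loop evaluation of the eigenvalue-weighted
    subspace inner product."""
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += (a.eigenvalues[i] * b.eigenvalues[j]
                    * float(a.components[i] @ b.components[j]) ** 2)
    den = sum(a.eigenvalues[i] * b.eigenvalues[i] for i in range(n))
    return np.sqrt(num / den)


class TestOverlapMatrix:
    def test_self_is_identity(self, rng):
        m = _random_model(rng, k=4)
        np.testing.assert_allclose(cm.overlap_matrix(m, m, k=4), np.eye(4),
                                   atol=1e-10)

    def test_orthogonal_subspaces_zero(self, rng):
        basis = _random_orthonormal(rng, 12, 4)
        a = _pc_model(basis[:2], [2.0, 1.0], 4)
        b = _pc_model(basis[2:], [2.0, 1.0], 4)
        np.testing.assert_allclose(cm.overlap_matrix(a, b, k=2), 0.0, atol=1e-12)

    def test_hand_built_two_vector_sets(self):
        """2-vector sets in 6-D: matches directly computed dot products."""
        u1 = np.array([1.0, 0, 0, 0, 0, 0])
        u2 = np.array([0, 1.0, 0, 0, 0, 0])
        s = 1 / np.sqrt(2)
        v1 = np.array([s, s, 0, 0, 0, 0])
        v2 = np.array([0, 0, 1.0, 0, 0, 0])
        a = _pc_model([u1, u2], [2.0, 1.0], 2)
        b = _pc_model([v1, v2], [3.0, 0.5], 2)
        expected = np.array([[s, 0.0], [s, 0.0]])
        np.testing.assert_allclose(cm.overlap_matrix(a, b, k=2), expected,
                                   atol=1e-12)

    def test_row_sum_of_squares_bounded(self, rng):
        a = _random_model(rng, n_residues=5, k=4)
        b = _random_model(rng, n_residues=5, k=4)
        mat = cm.overlap_matrix(a, b, k=4)
        assert np.all(mat <= 1.0 + 1e-12)
        assert np.all(mat.sum(axis=1) ** 0 * (mat ** 2).sum(axis=1) <= 1 + 1e-12)


class TestRWSIP:
    def test_identical_sets_give_one(self, rng):
        """Self-comparison of any PC set evaluates to exactly 1 — the
        reference value of the experimental-vs-experimental column."""
        m = _random_model(rng, k=DEFAULT_N_PCS)
        assert cm.rwsip(m, m, n=4) == pytest.approx(1.0, abs=1e-14)

    def test_orthogonal_sets_give_zero(self, rng):
        basis = _random_orthonormal(rng, 24, 8)
        a = _pc_model(basis[:4], [4.0, 3.0, 2.0, 1.0], 8)
        b = _pc_model(basis[4:], [4.0, 3.0, 2.0, 1.0], 8)
        assert cm.rwsip(a, b, n=4) == pytest.approx(0.0, abs=1e-14)

    def test_against_bruteforce_oracle(self, rng):
        for _ in range(50):
            a = _random_model(rng, n_residues=5, k=3)
            b = _random_model(rng, n_residues=5, k=3)
            assert cm.rwsip(a, b, n=3) == pytest.approx(
                rwsip_bruteforce(a, b, 3), abs=1e-12)

    def test_symmetry_and_bounds_random_instances(self, rng):
        for _ in range(200):
            a = _random_model(rng, n_residues=4, k=3)
            b = _random_model(rng, n_residues=4, k=3)
            r_ab = cm.rwsip(a, b, n=3)
            assert r_ab == pytest.approx(cm.rwsip(b, a, n=3), abs=1e-12)
            assert 0.0 <= r_ab <= 1.0 + 1e-12

    def test_n1_reduces_to_overlap_entry(self, rng):
        a = _random_model(rng, k=2)
        b = _random_model(rng, k=2)
        assert cm.rwsip(a, b, n=1) == pytest.approx(
            cm.overlap_matrix(a, b, k=1)[0, 0], abs=1e-12)

    def test_invariant_under_joint_rotation(self, rng):
        from scipy.stats import ortho_group
        a = _random_model(rng, n_residues=4, k=3)
        b = _random_model(rng, n_residues=4, k=3)
        q = ortho_group.rvs(12, random_state=3)
        a2 = dataclasses.replace(a, components=a.components @ q.T)
        b2 = dataclasses.replace(b, components=b.components @ q.T)
        assert cm.rwsip(a2, b2, n=3) == pytest.approx(cm.rwsip(a, b, n=3),
                                                      abs=1e-10)

    def test_too_few_components_raises(self, rng):
        a = _random_model(rng, k=2)
        with pytest.raises(ValueError):
            cm.rwsip(a, a, n=4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bound_property(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_model(rng, n_residues=3, k=2)
        b = _random_model(rng, n_residues=3, k=2)
        r = cm.rwsip(a, b, n=2)
        assert 0.0 <= r <= 1.0 + 1e-12


class TestRmsfPearson:
    def test_self_correlation_one(self, rng):
        p = rng.uniform(0.5, 2.0, size=20)
        mat = cm.rmsf_pearson([p, p])
        np.testing.assert_allclose(mat.values, 1.0, atol=1e-12)

    def test_negation_about_mean(self, rng):
        p = rng.uniform(0.5, 2.0, size=20)
        q = 2 * p.mean() - p
        mat = cm.rmsf_pearson([p, q])
        assert mat.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        p = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        q = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # hand: r = cov/ (sp sq) with population moments
        cov = np.mean((p - 3.0) * (q - 3.2))
        r_hand = cov / (p.std() * q.std())
        mat = cm.rmsf_pearson([p, q], labels=["p", "q"])
        assert mat.loc["p", "q"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        mat = cm.rmsf_pearson([np.ones(5), np.arange(5.0)])
        assert np.isnan(mat.iloc[0, 1])

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            cm.rmsf_pearson([np.ones(5), np.ones(6)])


class TestDistances:
    def test_pair_distance_same_residue_zero(self, helix30):
        ens = cm.build_ensemble([helix30])
        d = cm.pair_distance(ens, ("A", 5, ""), ("A", 5, ""))
        np.testing.assert_allclose(d.values, 0.0)

    def test_pair_distance_known_geometry(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0], [10.0, 0, 0]]])
        keys = (("A", 1, ""), ("A", 2, ""), ("A", 3, ""))
        ens = cm.Ensemble(["x"], keys, coords)
        assert cm.pair_distance(ens, ("A", 1, ""), ("A", 2, "")).values[0] \
            == pytest.approx(5.0)

    def test_superposition_independence(self, helix30):
        from scipy.spatial.transform import Rotation
        ens = cm.build_ensemble([helix30] * 3)
        rot = Rotation.from_euler("z", 1.1).as_matrix()
        moved = cm.Ensemble(ens.labels, ens.residue_keys,
                            ens.coords @ rot.T + 7.0)
        a = cm.pair_distance(ens, ("A", 1, ""), ("A", 20, "")).values
        b = cm.pair_distance(moved, ("A", 1, ""), ("A", 20, "")).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_missing_residue_raises(self, helix30):
        ens = cm.build_ensemble([helix30])
        with pytest.raises(cm.SelectionError):
            cm.pair_distance(ens, ("A", 1, ""), ("B", 999, ""))

    def test_com_single_residue_ranges_reduce_to_pair(self, helix30):
        ens = cm.build_ensemble([helix30, helix30])
        a = cm.com_distance(ens, [("A", 3, 3)], [("A", 17, 17)]).values
        b = cm.pair_distance(ens, ("A", 3, ""), ("A", 17, "")).values
        np.testing.assert_allclose(a, b)

    def test_com_identical_selections_zero(self, helix30):
        ens = cm.build_ensemble([helix30])
        d = cm.com_distance(ens, [("A", 1, 10)], [("A", 1, 10)])
        np.testing.assert_allclose(d.values, 0.0)

    def test_com_two_segment_selection(self, helix30):
        ens = cm.build_ensemble([helix30])
        d = cm.com_distance(ens, [("A", 1, 5), ("A", 8, 10)], [("A", 20, 30)])
        idx_a = list(range(0, 5)) + list(range(7, 10))
        idx_b = list(range(19, 30))
        expected = np.linalg.norm(ens.coords[0][idx_a].mean(0)
                                  - ens.coords[0][idx_b].mean(0))
        assert d.values[0] == pytest.approx(expected)

    def test_empty_selection_raises(self, helix30):
        ens = cm.build_ensemble([helix30])
        with pytest.raises(cm.SelectionError):
            cm.com_distance(ens, [("Z", 1, 5)], [("A", 1, 5)])


class TestSummarize:
    def _two_state(self, helix30):
        bend = np.zeros((30, 3))
        bend[15:, 0] = 6.0
        closed = helix30.with_coords(helix30.coords + bend, label="closed")
        ens = cm.two_state_ensemble(helix30, closed, noise=0.05,
                                    n_conformers=60, seed=0)
        return closed, ens

    def test_min_rmsd_zero_when_target_in_ensemble(self, helix30):
        ens = cm.build_ensemble([helix30] * 2)
        rep = summarize({"e": ens}, targets={"self": helix30})
        assert rep.min_rmsd_to_target.min_rmsd.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_min_rmsd_tracks_generator_noise(self, helix30):
        closed, ens = self._two_state(helix30)
        rep = summarize({"two-state": ens}, targets={"closed": closed})
        # min RMSD to the closed state ~ jitter scale, far below the
        # open/closed separation
        val = rep.min_rmsd_to_target.min_rmsd.iloc[0]
        assert val < 3 * 0.05
        assert val < 0.2

    def test_closest_approach_single_conformer(self, helix30):
        ens = cm.build_ensemble([helix30])
        rep = summarize({"e": ens}, observables={
            "tip": {"pair": (("A", 1, ""), ("A", 30, ""))}})
        row = rep.distance_summary.iloc[0]
        assert row.closest == row.farthest

    def test_report_notes_missing_inputs(self, helix30):
        ens = cm.build_ensemble([helix30])
        rep = summarize({"e": ens}, observables={
            "bad": {"pair": (("Q", 1, ""), ("A", 2, ""))}})
        assert rep.distance_summary is None
        assert any("bad" in n for n in rep.notes)

    def test_rwsip_table_symmetric_unit_diagonal(self, helix30, two_domain60):
        anm = cm.AnisotropicNetworkModel(helix30).fit(n_modes=4)
        e1, _ = cm.gaussian_ensemble(helix30, anm.modes, anm.eigenvalues,
                                     n_conformers=80, seed=0)
        e2, _ = cm.gaussian_ensemble(helix30, anm.modes, anm.eigenvalues,
                                     n_conformers=80, seed=1)
        models = {"a": cm.compute_pcs(e1, 4), "b": cm.compute_pcs(e2, 4)}
        rep = summarize({"a": e1, "b": e2}, models, n_pcs=4)
        tab = rep.rwsip_table
        np.testing.assert_allclose(np.diag(tab.values), 1.0, atol=1e-10)
        np.testing.assert_allclose(tab.values, tab.values.T, atol=1e-12)

    def test_json_roundtrip(self, helix30, tmp_path):
        ens = cm.build_ensemble([helix30] * 2)
        rep = summarize({"e": ens}, targets={"self": helix30})
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        data = json.loads(path.read_text())
        assert "min_rmsd_to_target" in data
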