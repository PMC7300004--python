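import numpy as np
import pytest

from leadtime.timeline import (
    DiffMatrix,
    Timeline,
    bootstrap_leave_one_lead,
    diff_matrix_average_of_onsets,
    diff_matrix_trial_by_trial,
    mds_reconstruct,
    rank_conjunction,
)


def complete_matrix(true_onsets, areas, jitter=0.0, rng=None):
    t = np.asarray(true_onsets, dtype=float)
    delta = t[:, None] - t[None, :]
    if jitter and rng is not None:
        noise = rng.normal(0, jitter, delta.shape)
        delta = delta + (noise - noise.T) / 2.0
        np.fill_diagonal(delta, 0.0)
    return DiffMatrix(areas=list(areas), delta=delta, sigma=np.ones_like(delta),
                      counts=np.ones_like(delta))


class TestDiffMatrixAverage:
    def test_hand_example(self):
        onsets = {
            "a1": np.array([0.010, 0.020]), "a2": np.array([0.015, 0.015]),
            "a3": np.array([0.012, 0.018]),
            "b1": np.array([0.030, 0.040]), "b2": np.array([0.035, 0.035]),
            "b3": np.array([0.032, 0.038]),
        }
        amap = {k: ("A" if k.startswith("a") else "B") for k in onsets}
        m = diff_matrix_average_of_onsets(onsets, amap)
        ia, ib = m.areas.index("A"), m.areas.index("B")
        assert m.delta[ia, ib] == pytest.approx(-0.020)
        assert np.all(m.sigma == 1.0)

    def test_antisymmetry_exact(self, rng):
        onsets = {f"l{i}": rng.normal(0, 0.05, 30) for i in range(9)}
        amap = {f"l{i}": f"A{i % 3}" for i in range(9)}
        m = diff_matrix_average_of_onsets(onsets, amap)
        assert np.allclose(m.delta + m.delta.T, 0.0, atol=1e-15)
        assert np.allclose(np.diag(m.delta), 0.0)

    def test_single_area_zero_matrix(self, rng):
        onsets = {f"l{i}": rng.normal(0, 0.05, 10) for i in range(3)}
        m = diff_matrix_average_of_onsets(onsets, {f"l{i}": "A" for i in range(3)})
        assert m.areas == ["A"]
        assert m.delta.shape == (1, 1) and m.delta[0, 0] == 0.0

    def test_small_areas_excluded(self, rng):
        onsets = {f"l{i}": rng.normal(0, 0.05, 10) for i in range(5)}
        amap = {"l0": "A", "l1": "A", "l2": "A", "l3": "B", "l4": "B"}
        m = diff_matrix_average_of_onsets(onsets, amap)
        assert m.areas == ["A"]

    def test_nan_onsets_ignored(self):
        onsets = {
            "a1": np.array([0.01, np.nan]), "a2": np.array([0.01, np.nan]),
            "a3": np.array([0.01, np.nan]),
            "b1": np.array([0.03, 0.03]), "b2": np.array([0.03, 0.03]),
            "b3": np.array([0.03, 0.03]),
        }
        amap = {k: k[0].upper() for k in onsets}
        m = diff_matrix_average_of_onsets(onsets, amap)
        assert m.delta[m.areas.index("A"), m.areas.index("B")] == pytest.approx(-0.02)

    def test_no_qualifying_area_rejected(self, rng):
        with pytest.raises(ValueError, match="minimum lead count"):
            diff_matrix_average_of_onsets({"l0": rng.normal(size=5)}, {"l0": "A"})


class TestDiffMatrixTrialwise:
    def _leads(self, shift=0.015, n=20):
        base = np.linspace(-0.3, -0.1, n)
        onsets = {}
        amap = {}
        for i in range(3):
            onsets[f"a{i}"] = base + 0.001 * i
            amap[f"a{i}"] = "A"
        for i in range(3):
            onsets[f"b{i}"] = base - shift + 0.001 * i
            amap[f"b{i}"] = "B"
        return onsets, amap

    def test_constant_shift_recovered_with_small_sigma(self):
        onsets, amap = self._leads(shift=0.015)
        m = diff_matrix_trial_by_trial(onsets, amap)
        ia, ib = m.areas.index("A"), m.areas.index("B")
        assert m.delta[ia, ib] == pytest.approx(0.015, abs=0.002)
        assert m.sigma[ia, ib] < 0.005

    def test_never_corecorded_pair_missing(self):
        onsets, amap = self._leads()
        subj = {k: ("S1" if k.startswith("a") else "S2") for k in onsets}
        m = diff_matrix_trial_by_trial(onsets, amap, subject_map=subj)
        ia, ib = m.areas.index("A"), m.areas.index("B")
        assert np.isnan(m.delta[ia, ib])

    def test_undetected_trial_contributes_nothing(self):
        onsets, amap = self._leads()
        for k in onsets:
            onsets[k] = onsets[k].copy()
        onsets["a0"][0] = np.nan  # this trial drops out of every a0 pair
        m1 = diff_matrix_trial_by_trial(onsets, amap)
        assert np.isfinite(m1.delta).all()

    def test_antisymmetric(self):
        onsets, amap = self._leads()
        m = diff_matrix_trial_by_trial(onsets, amap)
        assert np.allclose(np.where(np.isfinite(m.delta), m.delta + m.delta.T, 0), 0, atol=1e-15)


class TestBootstrap:
    def test_one_matrix_per_lead(self, rng):
        onsets = {f"l{i}": rng.normal(0, 0.02, 15) for i in range(8)}
        amap = {f"l{i}": f"A{i % 2}" for i in range(8)}
        boots = bootstrap_leave_one_lead(onsets, amap, "average")
        assert len(boots) == 8

    def test_identical_leads_identical_matrices(self):
        onsets = {f"l{i}": np.full(10, -0.2) for i in range(6)}
        amap = {f"l{i}": f"A{i % 2}" for i in range(6)}
        boots = bootstrap_leave_one_lead(onsets, amap, "average")
        for b in boots[1:]:
            assert np.allclose(b.delta, boots[0].delta)

    def test_three_lead_area_drops_when_its_lead_removed(self, rng):
        onsets = {f"a{i}": rng.normal(0, 0.02, 15) for i in range(3)}
        onsets.update({f"b{i}": rng.normal(0, 0.02, 15) for i in range(4)})
        amap = {k: k[0].upper() for k in onsets}
        boots = bootstrap_leave_one_lead(onsets, amap, "average")
        assert boots[0].areas == ["B"]  # a0 left out -> A below threshold
        assert boots[-1].areas == ["A", "B"]

    def test_needs_two_leads(self, rng):
        with pytest.raises(ValueError, match="2 leads"):
            bootstrap_leave_one_lead({"l0": rng.normal(size=5)}, {"l0": "A"}, "average")

    def test_unknown_method(self, rng):
        onsets = {f"l{i}": rng.normal(size=5) for i in range(2)}
        with pytest.raises(ValueError, match="method"):
            bootstrap_leave_one_lead(onsets, {"l0": "A", "l1": "A"}, "weird")


class TestMds:
    def test_exact_fixed_point_any_seed(self):
        areas = [f"A{i:02d}" for i in range(8)]
        true = np.linspace(-0.06, 0.0, 8)
        m = complete_matrix(true, areas)
        for seed in range(10):
            tl = mds_reconstruct(m, seed=seed)
            c = np.array([tl.coords[a] for a in areas])
            rec = c[:, None] - c[None, :]
            assert np.abs(rec - m.delta).max() < 1e-3  # within 1 ms

    def test_two_area_forced_geometry(self):
        m = DiffMatrix(areas=["X", "Y"], delta=np.array([[0.0, 0.020], [-0.020, 0.0]]),
                       sigma=np.ones((2, 2)), counts=np.ones((2, 2)))
        tl = mds_reconstruct(m, reference="X", seed=3)
        assert tl.coords["X"] == 0.0
        assert tl.coords["Y"] == pytest.approx(-0.020, abs=1e-6)

    def test_rank_recovery_with_jitter(self, rng):
        areas = [f"A{i}" for i in range(6)]
        true = np.arange(6) * 0.012 - 0.2
        hits = 0
        for seed in range(100):
            m = complete_matrix(true, areas, jitter=0.005, rng=rng)
            tl = mds_reconstruct(m, seed=seed)
            hits += tl.rank_order() == areas
        assert hits >= 95

    def test_translation_invariance(self, rng):
        areas = [f"A{i}" for i in range(5)]
        t0 = rng.normal(0, 0.05, 5)
        m1 = complete_matrix(t0, areas)
        m2 = complete_matrix(t0 + 0.42, areas)
        assert np.allclose(m1.delta, m2.delta)
        tl1 = mds_reconstruct(m1, seed=7)
        tl2 = mds_reconstruct(m2, seed=7)
        for a in areas:
            assert tl1.coords[a] == pytest.approx(tl2.coords[a], abs=1e-9)

    def test_residual_not_inflated(self, rng):
        areas = [f"A{i}" for i in range(6)]
        for seed in range(20):
            m = complete_matrix(rng.normal(0, 0.03, 6), areas, jitter=0.01, rng=rng)
            r = np.random.default_rng(seed)
            T0 = r.uniform(-0.1, 0.1, 6)
            init_residual = np.abs((T0[:, None] - T0[None, :]) - m.delta).mean()
            tl = mds_reconstruct(m, seed=seed)
            c = np.array([tl.coords[a] for a in areas])
            final_residual = np.abs((c[:, None] - c[None, :]) - m.delta).mean()
            assert final_residual <= init_residual + 1e-12

    def test_disconnected_matrix_lists_components(self):
        delta = np.full((4, 4), np.nan)
        np.fill_diagonal(delta, 0.0)
        delta[0, 1] = 0.01
        delta[1, 0] = -0.01
        delta[2, 3] = 0.02
        delta[3, 2] = -0.02
        m = DiffMatrix(areas=list("ABCD"), delta=delta, sigma=np.ones((4, 4)),
                       counts=np.ones((4, 4)))
        with pytest.raises(ValueError, match="disconnected"):
            mds_reconstruct(m)

    def test_reference_default_ba4(self):
        areas = ["BA4", "PFt", "PMd"]
        m = complete_matrix([-0.01, -0.02, -0.03], areas)
        tl = mds_reconstruct(m, seed=0)
        assert tl.reference == "BA4" and tl.coords["BA4"] == 0.0

    def test_convergence_metadata(self):
        m = complete_matrix([-0.01, -0.03], ["A", "B"])
        tl = mds_reconstruct(m, seed=0)
        assert tl.converged and tl.iterations <= 1000

    def test_beta_validation(self):
        m = complete_matrix([-0.01, -0.03], ["A", "B"])
        with pytest.raises(ValueError, match="beta"):
            mds_reconstruct(m, beta=1.5)


def _timelines_from_ranks(rank_lists, areas):
    out = []
    for ranks in rank_lists:
        coords = {a: 0.01 * r for a, r in zip(areas, ranks)}
        out.append(Timeline(coords=coords, reference=areas[0], iterations=1, converged=True))
    return out


class TestRankConjunction:
    def test_identical_ranks_score_zero(self):
        areas = ["A", "B", "C"]
        tls = _timelines_from_ranks([[1, 2, 3]] * 4, areas)
        conj = rank_conjunction({"m": tls}, n_null=50)
        assert all(conj.score[a] == 0.0 for a in areas)

    def test_pair_example_c_two(self):
        areas = ["A", "B", "C"]
        tls = _timelines_from_ranks([[1, 2, 3], [3, 2, 1]], areas)
        conj = rank_conjunction({"m": tls}, n_null=10)
        assert conj.score["A"] == pytest.approx(2.0)  # ranks {1, 3}
        assert conj.score["B"] == pytest.approx(0.0)

    def test_null_calibration(self):
        areas = [f"A{i}" for i in range(5)]
        rng = np.random.default_rng(0)
        sig = total = 0
        for rep in range(30):
            rank_lists = [list(rng.permutation(5) + 1) for _ in range(12)]
            tls = _timelines_from_ranks(rank_lists, areas)
            conj = rank_conjunction({"m": tls}, n_null=100, rng=rng)
            sig += sum(conj.significant.values())
            total += len(areas)
        assert sig / total < 0.12  # fully random ranks: about alpha

    def test_consensus_order_sorted_by_mean_rank(self):
        areas = ["A", "B", "C"]
        tls = _timelines_from_ranks([[2, 1, 3], [2, 1, 3]], areas)
        conj = rank_conjunction({"m": tls}, n_null=10)
        assert conj.consensus_order() == ["B", "A", "C"]

    def test_fewer_than_two_points_rejected(self):
        areas = ["A", "B"]
        tls = _timelines_from_ranks([[1, 2]], areas)
        with pytest.raises(ValueError, match="2 pooled rank"):
            rank_conjunction({"m": tls}, n_null=10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no timelines"):
            rank_conjunction({}, n_null=10)


class TestDiffMatrixValidation:
    def test_asymmetric_rejected(self):
        delta = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="antisymmetric"):
            DiffMatrix(areas=["A", "B"], delta=delta, sigma=np.ones((2, 2)),
                       counts=np.ones((2, 2)))

    def test_nonzero_diagonal_rejected(self):
        delta = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DiffMatrix(areas=["A", "B"], delta=delta, sigma=np.ones((2, 2)),
                       counts=np.ones((2, 2)))

    def test_nonpositive_sigma_rejected(self):
        delta = np.zeros((2, 2))
        with pytest.raises(ValueError, match="sigma"):
            DiffMatrix(areas=["A", "B"], delta=delta, sigma=np.zeros((2, 2)),
                       counts=np.ones((2, 2)))
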