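import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_ar1
from laketempo.pattern import (
    BASE_CLASSES,
    TemporalIndicators,
    base_class,
    classify_cluster_profile,
    cluster_series,
    compute_indicators,
    detect_anomalies,
    detect_breakpoints,
    mann_kendall,
    refine_classes,
)
from oracles import exhaustive_breakpoints, mk_all_pairs, ward_merge_order


class TestBreakpoints:
    def test_planted_shift_localized(self, rng):
        hits = 0
        for _ in range(50):
            z = np.concatenate([np.zeros(17), np.full(17, 3.0)]) + rng.normal(0, 0.2, 34)
            z = (z - z.mean()) / z.std()
            bps = detect_breakpoints(z)
            hits += len(bps) == 1 and abs(bps[0] - 17) <= 1
        assert hits >= 47

    def test_constant_series_no_breaks(self):
        assert detect_breakpoints(np.zeros(34)) == []

    def test_staircase_two_breaks(self, rng):
        z = np.concatenate([np.zeros(11), np.full(11, 3.0), np.full(12, 6.0)])
        z = z + rng.normal(0, 0.2, 34)
        z = (z - z.mean()) / z.std()
        bps = detect_breakpoints(z)
        assert len(bps) == 2
        assert abs(bps[0] - 11) <= 1 and abs(bps[1] - 22) <= 1

    def test_too_short_series_no_breaks_testable(self):
        assert detect_breakpoints(np.array([0.0, 1.0, 2.0]), min_seg_frac=0.5) == []

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(25):
            z = rng.normal(size=34)
            if rng.random() < 0.5:
                z[17:] += rng.uniform(1.0, 3.0)
            assert detect_breakpoints(z, max_breaks=2) == exhaustive_breakpoints(z)

    def test_minimum_segment_length_respected(self, rng):
        for _ in range(20):
            z = rng.normal(size=34)
            z[17:] += 2.0
            bps = detect_breakpoints(z)
            bounds = [0] + bps + [34]
            assert all(b - a >= 6 for a, b in zip(bounds[:-1], bounds[1:]))


class TestAnomalies:
    def test_quiet_series_empty(self):
        assert detect_anomalies(np.full(34, 0.5)) == []

    def test_single_extreme_year(self):
        z = np.zeros(34)
        z[11] = 2.0
        assert detect_anomalies(z) == [12]

    def test_boundary_is_strict(self):
        z = np.zeros(34)
        z[5] = 1.0
        z[6] = -1.0
        assert detect_anomalies(z) == []
        z[7] = 1.0000001
        assert detect_anomalies(z) == [8]


class TestMannKendall:
    def test_perfect_monotone(self):
        S, tau, p, trend = mann_kendall(np.arange(1.0, 11.0))
        assert tau == pytest.approx(1.0)
        assert trend == "increasing"

    def test_constant_no_trend(self):
        S, tau, p, trend = mann_kendall(np.full(10, 2.0))
        assert S == 0 and trend == "none" and p == 1.0

    def test_hand_enumerated_example(self):
        S, tau, p, trend = mann_kendall(np.array([3.0, 1.0, 2.0, 5.0, 4.0]))
        assert S == 4
        assert tau == pytest.approx(0.4)

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(50):
            n = rng.integers(5, 50)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            S, tau, p, _ = mann_kendall(x)
            S_o, tau_o = mk_all_pairs(x)
            assert S == S_o
            assert tau == pytest.approx(tau_o, abs=1e-12)

    def test_agrees_with_scipy_kendalltau(self, rng):
        """Independent cross-check of tau against scipy's implementation."""
        for _ in range(20):
            x = rng.normal(size=30)
            _, tau, _, _ = mann_kendall(x)
            tau_scipy = stats.kendalltau(np.arange(30), x).statistic
            assert tau == pytest.approx(tau_scipy, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall(np.array([1.0, 2.0, 3.0]))


class TestClusterSeries:
    def test_singletons_at_k_equals_n(self, rng):
        z = rng.normal(size=(5, 34))
        model = cluster_series(z, [f"L{i}" for i in range(5)], k=5)
        assert sorted(model.labels.values()) == [1, 2, 3, 4, 5]

    def test_recovers_two_planted_archetypes(self, rng):
        up = np.linspace(-1.5, 1.5, 34)
        flat = np.zeros(34)
        z = np.vstack(
            [up + rng.normal(0, 0.2, 34) for _ in range(20)]
            + [flat + rng.normal(0, 0.2, 34) for _ in range(20)]
        )
        ids = [f"L{i}" for i in range(40)]
        model = cluster_series(z, ids, k=2)
        labels = np.array([model.labels[i] for i in ids])
        # adjusted Rand index 1 <=> the 20/20 split is exact
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_order_matches_bruteforce_ward(self, rng):
        pts = rng.normal(size=(6, 4))
        model = cluster_series(pts, [f"L{i}" for i in range(6)], k=1)
        # replay scipy's linkage into member sets
        sets = {i: frozenset([i]) for i in range(6)}
        scipy_merges = []
        for step, (a, b, _, _) in enumerate(model.linkage_matrix):
            merged = sets[int(a)] | sets[int(b)]
            sets[6 + step] = merged
            scipy_merges.append(merged)
        assert scipy_merges == ward_merge_order(pts)

    def test_linkage_heights_nondecreasing(self, rng):
        z = rng.normal(size=(12, 34))
        model = cluster_series(z, [f"L{i}" for i in range(12)], k=3)
        heights = model.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_permutation_equivariance(self, rng):
        z = rng.normal(size=(10, 34))
        ids = [f"L{i}" for i in range(10)]
        model = cluster_series(z, ids, k=3)
        perm = rng.permutation(10)
        model_p = cluster_series(z[perm], [ids[i] for i in perm], k=3)
        # same partition of lake ids, regardless of row order
        def partition(m):
            groups = {}
            for lake, c in m.labels.items():
                groups.setdefault(c, set()).add(lake)
            return {frozenset(g) for g in groups.values()}
        assert partition(model) == partition(model_p)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_series(rng.normal(size=(3, 34)), ["a", "b", "c"], k=4)


def _ind(lake="L", breaks=(), anoms=(), trend="none"):
    return TemporalIndicators(lake, list(breaks), list(anoms), 0, 0.0, 1.0, trend)


class TestBaseClass:
    @pytest.mark.parametrize(
        "breaks,anoms,trend,expected",
        [
            ((), (2012,), "none", "abrupt_temporary"),
            ((1998,), (), "none", "abrupt_persistent"),
            ((1998,), (2012,), "none", "abrupt_mixed"),
            ((), (), "increasing", "monotonic_increasing"),
            ((), (), "decreasing", "monotonic_decreasing"),
            ((), (), "none", "no_pattern"),
        ],
    )
    def test_six_definitions(self, breaks, anoms, trend, expected):
        assert base_class(_ind(breaks=breaks, anoms=anoms, trend=trend)) == expected

    def test_total_function_onto_six_classes(self):
        seen = set()
        for breaks in ((), (5,)):
            for anoms in ((), (9,)):
                for trend in ("none", "increasing", "decreasing"):
                    cls = base_class(_ind(breaks=breaks, anoms=anoms, trend=trend))
                    assert cls in BASE_CLASSES
                    seen.add(cls)
        assert seen == set(BASE_CLASSES)


class TestClusterProfileClassification:
    def test_step_profile(self, rng):
        P = np.concatenate([np.full(17, -1.0), np.full(17, 1.0)]) + rng.normal(0, 0.1, 34)
        cls, peak = classify_cluster_profile(P)
        assert cls == "abrupt_persistent" and abs(peak - 17) <= 1

    def test_impulse_profile(self, rng):
        P = rng.normal(0, 0.15, 34)
        P[27] += 2.5
        cls, peak = classify_cluster_profile(P)
        assert cls == "abrupt_temporary" and peak == 28

    def test_ramp_profile(self, rng):
        P = np.linspace(-1.5, 1.5, 34) + rng.normal(0, 0.15, 34)
        cls, peak = classify_cluster_profile(P)
        assert cls == "monotonic_increasing" and peak is None

    def test_flat_profile(self, rng):
        cls, peak = classify_cluster_profile(rng.normal(0, 0.2, 34))
        assert cls == "no_pattern" and peak is None

    def test_step_plus_impulse_profile(self, rng):
        P = np.concatenate([np.full(17, -1.0), np.full(17, 1.0)]) + rng.normal(0, 0.1, 34)
        P[8] += 2.5
        cls, peak = classify_cluster_profile(P)
        assert cls == "abrupt_mixed" and abs(peak - 17) <= 1


class TestRefineClasses:
    def _model_and_z(self, profiles, per_cluster=4, noise=0.1, seed=0):
        """Build lakes around given cluster profiles; returns (model, z)."""
        g = np.random.default_rng(seed)
        z, ids = {}, []
        labels = {}
        for c, P in enumerate(profiles, start=1):
            for i in range(per_cluster):
                lid = f"c{c}_l{i}"
                z[lid] = P + g.normal(0, noise, P.size)
                labels[lid] = c
                ids.append(lid)
        from laketempo.pattern import ClusterModel

        model = ClusterModel(k=len(profiles), labels=labels, linkage_matrix=np.empty((0, 4)))
        return model, z

    def test_same_year_different_magnitude_merged(self):
        step = np.concatenate([np.full(17, 0.0), np.full(17, 1.0)])
        big_step = np.concatenate([np.full(17, 0.0), np.full(17, 3.0)])
        model, z = self._model_and_z([step - step.mean(), big_step - big_step.mean()])
        classes, registry = refine_classes(model, z)
        assert len(set(classes.values())) == 1
        assert registry.iloc[0]["base_class"] == "abrupt_persistent"

    def test_distinct_peak_years_stay_separate(self):
        def spike(year):
            P = np.zeros(34)
            P[year - 1] = 2.5
            return P

        model, z = self._model_and_z([spike(8), spike(17), spike(28)])
        classes, registry = refine_classes(model, z)
        assert len(set(classes.values())) == 3
        assert set(registry["base_class"]) == {"abrupt_temporary"}

    def test_trend_clusters_merge_by_class_alone(self):
        ramp = np.linspace(-1.5, 1.5, 34)
        model, z = self._model_and_z([ramp, 2.0 * ramp])
        classes, _ = refine_classes(model, z)
        assert len(set(classes.values())) == 1

    def test_every_lake_classified_exactly_once(self, rng):
        profiles = [np.zeros(34), np.linspace(-1, 1, 34)]
        model, z = self._model_and_z(profiles)
        classes, registry = refine_classes(model, z)
        assert set(classes) == set(z)
        assert registry["n_lakes"].sum() == len(z)

    def test_deterministic(self):
        ramp = np.linspace(-1.5, 1.5, 34)
        model, z = self._model_and_z([ramp, np.zeros(34)])
        assert refine_classes(model, z)[0] == refine_classes(model, z)[0]


class TestComputeIndicators:
    def test_fields_consistent(self, rng):
        z = make_ar1(34, 0.4, rng)
        ind = compute_indicators("L", z)
        assert abs(ind.mk_tau) <= 1.0
        if ind.trend != "none":
            assert ind.mk_p < 0.05
            assert np.sign(ind.mk_tau) == (1 if ind.trend == "increasing" else -1)
        assert set(ind.anomaly_years) == set(detect_anomalies(z))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_breakpoint_segments_respect_minimum(self, seed):
        z = np.random.default_rng(seed).normal(size=34)
        ind = compute_indicators("L", z)
        bounds = [0] + ind.breakpoint_years + [34]
        assert all(b - a >= 6 for a, b in zip(bounds[:-1], bounds[1:]))
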