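"""Information statistics against closed forms and the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import laminfo as L
from laminfo.infotheory import (
    DegenerateBinningWarning,
    TransmissionSpec,
    _substream,
    condition_mi_series,
    signal_mi_series,
    transmission_series,
)

import _oracle as oracle


labels_strategy = st.lists(st.integers(0, 4), min_size=5, max_size=60)


class TestDiscretize:
    def test_equal_counts_on_1_to_10(self):
        labels = L.discretize_uniform_count(np.arange(1, 11), 5)
        assert np.bincount(labels, minlength=5).tolist() == [2, 2, 2, 2, 2]

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(47)
        a = L.discretize_uniform_count(x, 5)
        b = L.discretize_uniform_count(np.exp(x), 5)
        assert np.array_equal(a, b)

    def test_constant_samples_flagged_single_bin(self):
        with pytest.warns(DegenerateBinningWarning):
            labels = L.discretize_uniform_count(np.full(20, 3.0), 5)
        assert set(labels) == {0}

    def test_occupancies_differ_by_at_most_one(self, rng):
        x = rng.standard_normal(53)
        labels = L.discretize_uniform_count(x, 5)
        counts = np.bincount(labels, minlength=5)
        assert counts.max() - counts.min() <= 1


class TestEntropy:
    def test_uniform_five_bins(self):
        labels = np.repeat(np.arange(5), 10)
        assert L.entropy(labels) == pytest.approx(math.log2(5), abs=1e-12)

    def test_deterministic_and_fair_coin(self):
        assert L.entropy(np.zeros(10)) == 0.0
        assert L.entropy(np.array([0, 1] * 25)) == pytest.approx(1.0, abs=1e-12)

    @given(labels_strategy)
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_and_bounds(self, labels):
        h = L.entropy(np.array(labels))
        assert h == pytest.approx(oracle.entropy(labels), abs=1e-12)
        assert -1e-12 <= h <= math.log2(5) + 1e-12


class TestMutualInformation:
    def test_perfect_copy_is_one_bit(self):
        x = np.array([0, 1] * 30)
        assert L.mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_product_joint_is_zero(self):
        # empirical joint counts [[25, 25], [25, 25]]
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile([0, 1], 50)
        assert L.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_skewed_joint_matches_direct_formula(self):
        # joint counts [[40, 10], [10, 40]]
        x = np.repeat([0, 1], 50)
        y = np.concatenate([np.repeat([0, 1], [40, 10]), np.repeat([0, 1], [10, 40])])
        expected = oracle.mutual_information(list(x), list(y))
        assert L.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.mutual_information(np.arange(4), np.arange(5))

    @given(labels_strategy, st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_oracle_symmetry_nonnegativity(self, labels, rnd):
        x = np.array(labels)
        y = np.array([rnd.randint(0, 2) for _ in labels])
        mi = L.mutual_information(x, y)
        assert mi == pytest.approx(oracle.mutual_information(list(x), list(y)), abs=1e-12)
        assert mi == pytest.approx(L.mutual_information(y, x), abs=1e-12)
        assert mi >= -1e-12
        assert L.mutual_information(x, x) == pytest.approx(L.entropy(x), abs=1e-12)


class TestSpecificInformation:
    def test_independent_signal_gives_zero(self):
        x = np.array([0, 1] * 20)
        s = np.zeros(40)
        for xv in (0, 1):
            assert L.specific_information(xv, s, x) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_copy_gives_one_bit_each(self):
        x = np.array([0, 1] * 20)
        for xv in (0, 1):
            assert L.specific_information(xv, x, x) == pytest.approx(1.0, abs=1e-12)

    def test_unobserved_value_rejected(self):
        with pytest.raises(ValueError):
            L.specific_information(7, np.arange(4), np.array([0, 1, 0, 1]))

    @given(labels_strategy, st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_decomposition_recovers_mi(self, labels, rnd):
        x = np.array([rnd.randint(0, 1) for _ in labels])
        s = np.array(labels)
        uniq, counts = np.unique(x, return_counts=True)
        total = sum(
            (c / len(x)) * L.specific_information(xv, s, x)
            for xv, c in zip(uniq, counts)
        )
        assert total == pytest.approx(L.mutual_information(x, s), abs=1e-12)
        for xv in uniq:
            assert L.specific_information(xv, s, x) == pytest.approx(
                oracle.specific_information(xv, list(s), list(x)), abs=1e-12
            )


class TestMinimumInformation:
    def test_idempotence(self, rng):
        x = rng.integers(0, 2, 60)
        s = rng.integers(0, 5, 60)
        assert L.minimum_information(x, s, s) == pytest.approx(
            L.mutual_information(x, s), abs=1e-12
        )

    def test_independent_second_source_gives_zero(self):
        x = np.array([0, 1] * 20)
        assert L.minimum_information(x, x, np.zeros(40)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_copy_bounds_the_min(self, rng):
        x = rng.integers(0, 2, 200)
        noisy = np.where(rng.random(200) < 0.3, rng.integers(0, 2, 200), x)
        imin = L.minimum_information(x, x, noisy)
        expected = oracle.minimum_information(list(x), list(x), list(noisy))
        assert imin == pytest.approx(expected, abs=1e-12)
        assert imin <= L.mutual_information(x, noisy) + 1e-12

    @given(labels_strategy, st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_oracle_and_upper_bounds(self, labels, rnd):
        x = np.array([rnd.randint(0, 1) for _ in labels])
        s1 = np.array(labels)
        s2 = np.array([rnd.randint(0, 3) for _ in labels])
        imin = L.minimum_information(x, s1, s2)
        assert imin == pytest.approx(
            oracle.minimum_information(list(x), list(s1), list(s2)), abs=1e-12
        )
        assert imin >= -1e-12
        assert imin <= L.mutual_information(x, s1) + 1e-12
        assert imin <= L.mutual_information(x, s2) + 1e-12


class TestInformationTransmission:
    def _spec(self, x, yp, zp, zf, t=1):
        n = len(x)
        y = np.zeros((n, 2))
        z = np.zeros((n, 2))
        y[:, 0] = yp
        z[:, 0] = zp
        z[:, 1] = zf
        return TransmissionSpec(x=np.asarray(x), y=y, z=z, lag_samples=1, n_bins=5)

    def test_copy_chain_transmits_one_bit(self):
        # X balanced binary; Y_past = X; Z_future = Y_past; Z_past crossed
        # with X so the empirical joint factorizes exactly
        x = np.array([0, 1] * 50)
        zp = np.tile(np.arange(5.0), 20)
        it = L.information_transmission(self._spec(x, x.astype(float), zp, x.astype(float)), 1)
        expected = oracle.transmission(
            list(x),
            list(L.discretize_uniform_count(x.astype(float), 5)),
            list(L.discretize_uniform_count(zp, 5)),
            list(L.discretize_uniform_count(x.astype(float), 5)),
        )
        assert it == pytest.approx(expected, abs=1e-12)
        assert it == pytest.approx(1.0, abs=1e-9)

    def test_fully_informative_past_transmits_nothing(self):
        x = np.array([0, 1] * 50)
        xf = x.astype(float)
        it = L.information_transmission(self._spec(x, xf, xf, xf), 1)
        assert it == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = 60
            x = rng.integers(0, 2, n)
            yp = rng.standard_normal(n)
            zp = rng.standard_normal(n)
            zf = rng.standard_normal(n) + x
            it = L.information_transmission(self._spec(x, yp, zp, zf), 1)
            expected = oracle.transmission(
                list(x),
                list(L.discretize_uniform_count(yp, 5)),
                list(L.discretize_uniform_count(zp, 5)),
                list(L.discretize_uniform_count(zf, 5)),
            )
            assert it == pytest.approx(expected, abs=1e-12)

    def test_missing_samples_excluded_per_timepoint(self, rng):
        x = np.array([0, 1] * 30)
        y = rng.standard_normal((60, 3))
        z = rng.standard_normal((60, 3))
        z[:58, 2] = np.nan   # too few usable trials left at t=2
        spec = TransmissionSpec(x=x, y=y, z=z, lag_samples=1, n_bins=5)
        assert np.isfinite(L.information_transmission(spec, 1))
        assert math.isnan(L.information_transmission(spec, 2))


class TestMcSignificance:
    def test_addone_p_bounds(self, rng):
        x = np.array([0, 1] * 100)
        res = L.mc_significance(
            lambda xx, s: L.mutual_information(xx, s), x, x.copy(),
            n_shuffle=500, seed=1,
        )
        assert res.p == pytest.approx(1.0 / 501.0, abs=1e-12)
        anti = L.mc_significance(
            lambda xx, s: -L.mutual_information(xx, s), x, x.copy(),
            n_shuffle=200, seed=1,
        )
        assert anti.p == 1.0

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            L.mc_significance(lambda x, s: 0.0, np.arange(4), np.arange(4), n_shuffle=10)

    def test_type_one_error_calibrated(self, rng):
        """Independent pairs: rejection rate compatible with alpha."""
        n_rep, n, alpha = 200, 120, 0.05
        hits = 0
        for k in range(n_rep):
            x = L.discretize_uniform_count(rng.standard_normal(n), 5)
            y = L.discretize_uniform_count(rng.standard_normal(n), 5)
            res = L.mc_significance(
                lambda xx, s: L.mutual_information(xx, s), x, y,
                n_shuffle=200, alpha=alpha, seed=k,
            )
            hits += res.p <= alpha
        rate = hits / n_rep
        # 99.9% binomial interval around 0.05 for 200 repeats
        assert 0.0 <= rate <= 0.05 + 3.3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestPersistenceAndConsensus:
    def test_runs_filtered_by_duration(self):
        times = np.arange(100.0)
        p = np.ones(100)
        p[10:22] = 0.01           # 12 ms run
        p[40:48] = 0.01           # 8 ms run
        p[60:75] = 0.01           # 15 ms run
        ivals = L.persistent_intervals(p, times, alpha=0.05, min_duration_ms=10)
        assert ivals == [(10.0, 21.0), (60.0, 74.0)]

    def test_single_short_run_dropped(self):
        times = np.arange(30.0)
        p = np.ones(30)
        p[5:13] = 0.01
        assert L.persistent_intervals(p, times, min_duration_ms=10) == []

    def test_consensus_strict_inequality(self):
        sig = np.zeros((5, 3), dtype=bool)
        sig[:4, 0] = True         # 0.8 > 0.75 -> in
        sig[:3, 1] = True         # 0.6 -> out
        mask = L.sessionwise_consensus(sig, 0.75)
        assert mask.tolist() == [True, False, False]
        sig34 = np.ones((4, 1), dtype=bool)
        sig34[0, 0] = False       # 3 of 4 = 0.75, not > 0.75
        assert not L.sessionwise_consensus(sig34, 0.75)[0]
        assert L.sessionwise_consensus(np.ones((3, 4), bool), 0.75).all()

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            L.sessionwise_consensus(np.zeros((0, 5), dtype=bool))


class TestSeriesDrivers:
    def test_vectorized_null_matches_per_timepoint_independence(self, rng):
        """Substreams are counter-keyed: results don't depend on order."""
        x = rng.integers(0, 2, 80)
        z = rng.standard_normal((80, 30))
        times = np.arange(30.0)
        a = condition_mi_series(x, z, times, np.array([5, 10]), n_shuffle=200, seed=3)
        b = condition_mi_series(x, z, times, np.array([10]), n_shuffle=200, seed=3)
        i = 1  # index of t=10 in a
        assert a.p[i] == b.p[0]
        assert a.statistic[i] == b.statistic[0]

    def test_transmission_series_null_is_calibrated_for_unrelated_source(self, rng):
        """Y independent of everything: significance at ~alpha rate."""
        n, T = 150, 40
        x = rng.integers(0, 2, n)
        z = rng.standard_normal((n, T)) + 0.8 * x[:, None]
        y = rng.standard_normal((n, T))
        ts = transmission_series(
            x, y, z, np.arange(float(T)), np.arange(12, T), n_shuffle=300, seed=9
        )
        rate = np.nanmean(ts.p <= 0.05)
        assert rate <= 0.2      # small-sample guard: well below certain detection

    def test_signal_mi_series_detects_shared_component(self, rng):
        n, T = 120, 20
        shared = rng.standard_normal((n, T))
        y = shared + 0.3 * rng.standard_normal((n, T))
        z = shared + 0.3 * rng.standard_normal((n, T))
        ts = signal_mi_series(y, z, np.arange(float(T)), np.arange(T), n_shuffle=200, seed=4)
        assert (ts.p <= 0.05).mean() > 0.9
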