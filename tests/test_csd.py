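"""CSD operator, laminar alignment, compartments, attention difference."""

import numpy as np
import pytest

import laminfo as L
from laminfo.csd import CSDStack, compartment_rows, compartment_series
from laminfo.synth import component_maps, csd_to_lfp


def make_stack(csd, boundary=None):
    return CSDStack(
        csd=csd, spacing=0.1, conductivity=0.4, sample_rate=1000.0,
        array_onset_index=0, boundary_channel=boundary,
    )


class TestComputeCsd:
    def test_affine_profile_annihilated_exactly(self):
        depths = np.arange(8)
        lfp = (2.0 + 3.0 * depths)[:, None] * np.ones((1, 10))
        out = L.compute_csd(lfp, spacing=0.1, conductivity=0.4)
        assert np.all(out == 0.0)

    def test_hand_evaluated_three_channel_value(self):
        # x = [0, 1, 0] mV, z = 0.1 mm, sigma = 0.4 S/m
        lfp = np.array([[0.0], [1.0], [0.0]])
        out = L.compute_csd(lfp, spacing=0.1, conductivity=0.4)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(-0.4 * (0.0 + 0.0 - 2.0) / 0.01)
        assert out[0, 0] == pytest.approx(80.0)

    def test_quadratic_profile_gives_constant(self):
        d = np.arange(10, dtype=float)
        lfp = (d**2)[:, None] * np.ones((1, 5))
        out = L.compute_csd(lfp, spacing=1.0, conductivity=0.4)
        assert np.allclose(out, -0.4 * 2.0)

    def test_linear_in_input(self, rng):
        a = rng.standard_normal((6, 9))
        b = rng.standard_normal((6, 9))
        z, s = 0.1, 0.4
        assert np.allclose(
            L.compute_csd(2 * a + 3 * b, z, s),
            2 * L.compute_csd(a, z, s) + 3 * L.compute_csd(b, z, s),
        )

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            L.compute_csd(np.zeros((2, 5)), 0.1, 0.4)


class TestRoundTrip:
    def test_zero_csd_gives_zero_lfp(self):
        assert np.all(csd_to_lfp(np.zeros((5, 7)), 0.1, 0.4) == 0.0)

    def test_impulse_round_trip(self):
        csd = np.zeros((9, 4))
        csd[4, 2] = 3.5
        lfp = csd_to_lfp(csd, 0.1, 0.4)
        back = L.compute_csd(lfp, 0.1, 0.4)
        assert np.abs(back - csd).max() < 1e-9 * np.abs(csd).max()

    def test_random_smooth_csd_round_trip(self, rng):
        csd = rng.standard_normal((20, 30))
        lfp = csd_to_lfp(csd, 0.1, 0.4)
        back = L.compute_csd(lfp, 0.1, 0.4)
        rel = np.abs(back - csd).max() / np.abs(csd).max()
        assert rel < 1e-9

    def test_generator_truth_round_trip(self, small_config):
        maps = component_maps(small_config)
        latent = maps["granular"] + maps["extragranular"]
        lfp = csd_to_lfp(latent, small_config.spacing, small_config.conductivity)
        back = L.compute_csd(lfp, small_config.spacing, small_config.conductivity)
        rel = np.abs(back - latent).max() / np.abs(latent).max()
        assert rel < 1e-9


class TestAlignment:
    def test_recovers_generator_boundary(self, default_session):
        cfg, (rec, trials, truth) = default_session
        lfp = L.baseline_correct(rec.lfp, rec.times_ms)
        csd = L.compute_csd(lfp, rec.spacing, cfg.conductivity)
        avg = csd[trials["correct"].to_numpy(bool)].mean(axis=0)
        boundary = L.align_to_granular_sink(avg, rec.times_ms)
        # the generator's L4 sink centre must fall inside the assigned L4 span
        sink_centre = truth.boundary_channel - 2
        assert boundary - 4 <= sink_centre <= boundary

    def test_translation_equivariance(self, default_session):
        cfg, (rec, trials, truth) = default_session
        lfp = L.baseline_correct(rec.lfp, rec.times_ms)
        csd = L.compute_csd(lfp, rec.spacing, cfg.conductivity)
        avg = csd[trials["correct"].to_numpy(bool)].mean(axis=0)
        b0 = L.align_to_granular_sink(avg, rec.times_ms)
        shifted = np.roll(avg, 3, axis=0)
        shifted[:3] = avg[:3]     # rolled-in rows replaced by quiet channels
        b1 = L.align_to_granular_sink(shifted, rec.times_ms)
        assert b1 == b0 + 3

    def test_pure_noise_raises(self, rng):
        noise = 0.1 * rng.standard_normal((20, 400))
        times = np.arange(-300.0, 100.0)
        with pytest.raises(RuntimeError):
            L.align_to_granular_sink(noise, times)


class TestCompartments:
    def test_unit_csd_gives_unit_series(self):
        stack = make_stack(np.ones((3, 30, 50)), boundary=16)
        series = compartment_series(stack)
        for name in ("L2/3", "L4", "L5/6"):
            assert np.all(series[name] == 1.0)

    def test_sites_disjoint_and_cover_fifteen(self):
        spans = compartment_rows(16, 30)
        rows = np.concatenate(list(spans.values()))
        assert len(rows) == 15
        assert len(set(rows.tolist())) == 15
        assert set(np.diff(np.sort(rows))) == {1}

    def test_sink_confined_to_l23_stays_in_l23(self, small_config):
        maps = component_maps(small_config)
        eg = maps["extragranular"]
        stack = make_stack(np.clip(eg, None, 0.0)[None], boundary=16)
        series = compartment_series(stack)
        t_peak = np.argmin(eg.min(axis=0))
        assert series["L2/3"][0, t_peak] < 0
        assert abs(series["L4"][0, t_peak]) < 0.2 * abs(series["L2/3"][0, t_peak])

    def test_insufficient_span_rejected(self):
        stack = make_stack(np.zeros((1, 30, 5)), boundary=5)
        with pytest.raises(ValueError):
            compartment_series(stack)


class TestAttentionDifference:
    def test_label_swap_negates_difference(self, rng):
        csd = rng.standard_normal((40, 10, 20))
        stack = make_stack(csd)
        sel = np.arange(40) < 20
        a = L.attention_csd_difference(stack, sel)
        b = L.attention_csd_difference(stack, ~sel)
        assert np.allclose(a.difference, -b.difference)
        assert np.array_equal(a.significant, b.significant)

    def test_null_calibration_at_alpha(self, rng):
        csd = rng.standard_normal((60, 12, 40))
        stack = make_stack(csd)
        sel = rng.permutation(60) < 30
        res = L.attention_csd_difference(stack, sel, alpha=0.05)
        rate = res.significant.mean()
        assert 0.02 < rate < 0.09

    def test_generator_effect_lands_in_extragranular_depths(self, default_session):
        cfg, (rec, trials, truth) = default_session
        lfp = L.baseline_correct(rec.lfp, rec.times_ms)
        csd = L.compute_csd(lfp, rec.spacing, cfg.conductivity)
        stack = make_stack(csd, boundary=truth.boundary_channel)
        res = L.attention_csd_difference(stack, trials["target_in_rf"].to_numpy(bool))
        cell = np.unravel_index(np.nanargmax(np.abs(res.difference)), res.difference.shape)
        times = rec.times_ms
        spans = compartment_rows(truth.boundary_channel, csd.shape[1])
        extragranular = set(spans["L2/3"].tolist()) | set(spans["L5/6"].tolist())
        assert cell[0] in extragranular
        assert times[cell[1]] > 100.0

    def test_single_condition_rejected(self, rng):
        stack = make_stack(rng.standard_normal((8, 5, 6)))
        with pytest.raises(ValueError):
            L.attention_csd_difference(stack, np.ones(8, dtype=bool))
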