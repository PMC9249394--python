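"""Tuning curves, consistency test, Gaussian fields, speed score, SI."""

import numpy as np
import pytest

from hippo2p.behavior import make_track
from hippo2p.tuning import (
    consistency_test,
    fit_gaussian_field,
    lap_time_shuffle,
    spatial_information,
    spatial_tuning_curves,
    speed_score,
)


@pytest.fixture(scope="module")
def track72():
    return make_track()


def _fake_session(track, n_laps=10, frames_per_lap=144, rng=None):
    """Uniform constant-speed laps: every bin visited twice per lap.

    Positions are offset by half a sample step so none lands exactly on a
    bin edge (floor would then be float-ambiguous and occupancy uneven).
    """
    n = n_laps * frames_per_lap
    step = track.midline_circumference_cm / frames_per_lap
    pos = np.mod(
        step / 2.0
        + np.linspace(0, n_laps * track.midline_circumference_cm, n, endpoint=False),
        track.midline_circumference_cm,
    )
    lap_id = np.repeat(np.arange(n_laps), frames_per_lap)
    moving = np.ones(n, dtype=bool)
    return pos, lap_id, moving


class TestSpatialTuningCurves:
    def test_constant_activity_flat_curve(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        act = np.ones(pos.size)
        curves, mean_curve = spatial_tuning_curves(act, pos, moving, lap_id, track72)
        assert np.allclose(mean_curve, mean_curve[0])

    def test_single_bin_activity(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        bins = track72.bin_index(pos)
        act = (bins == 10).astype(float)
        _, mean_curve = spatial_tuning_curves(act, pos, moving, lap_id, track72)
        assert mean_curve[10] > 0
        assert np.nansum(mean_curve[np.arange(72) != 10]) == 0

    def test_matches_bruteforce_double_loop(self, track72):
        rng = np.random.default_rng(0)
        pos, lap_id, moving = _fake_session(track72, n_laps=5)
        moving = rng.random(pos.size) > 0.2
        act = rng.exponential(1.0, pos.size)
        curves, _ = spatial_tuning_curves(act, pos, moving, lap_id, track72)
        bins = track72.bin_index(pos)
        for lap in range(5):
            for b in [0, 13, 40, 71]:
                sel = (lap_id == lap) & moving & (bins == b)
                if sel.any():
                    assert curves[lap, b] == pytest.approx(
                        act[sel].sum() / sel.sum()
                    )
                else:
                    assert np.isnan(curves[lap, b])

    def test_all_zero_cell_valid(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        curves, mean_curve = spatial_tuning_curves(
            np.zeros(pos.size), pos, moving, lap_id, track72
        )
        assert np.nansum(mean_curve) == 0


class TestConsistency:
    def test_identical_sharp_bumps_consistent(self):
        rng = np.random.default_rng(0)
        curve = np.zeros(72)
        curve[30:36] = [1, 3, 8, 8, 3, 1]
        curves = np.tile(curve, (12, 1)) + rng.normal(0, 0.05, (12, 72))
        real, shuf, ks_p, d, consistent = consistency_test(curves, seed=1)
        assert consistent
        assert np.mean(real) > 0.9
        assert d > 0.5 and ks_p < 0.01

    def test_iid_noise_distributions_centered_identically(self):
        """On white-noise curves the real and shuffled split-correlation
        distributions coincide in location on average across sessions
        (within-session, split dependence makes the gate anti-conservative
        — the false-positive guarantee belongs to the full classifier,
        tested at session level)."""
        diffs = []
        fp = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            curves = rng.exponential(1.0, (20, 72))
            real, shuf, _, d, consistent = consistency_test(curves, seed=seed)
            diffs.append(np.nanmean(real) - np.nanmean(shuf))
            fp += consistent
        assert abs(np.mean(diffs)) < 0.03
        assert fp / 20 < 0.5

    def test_too_few_laps_rejected(self):
        with pytest.raises(ValueError):
            consistency_test(np.ones((5, 72)))

    def test_permutation_preserves_lap_mass(self):
        """The shuffle null must conserve each lap's total activity."""
        rng = np.random.default_rng(2)
        curves = rng.exponential(1.0, (8, 72))
        shifts = rng.integers(1, 72, size=8)
        col = np.arange(72)
        rolled = curves[
            np.arange(8)[:, None], (col[None, :] - shifts[:, None]) % 72
        ]
        assert np.allclose(rolled.sum(axis=1), curves.sum(axis=1))


class TestGaussianField:
    def test_noiseless_gaussian_closed_form(self, track72):
        x = (np.arange(72) + 0.5) * track72.bin_length_cm
        c_true = 12.0
        curve = 0.2 + 1.5 * np.exp(-(((x - 30.0) / c_true) ** 2))
        params, adj_r2, fwhm, ok, _ = fit_gaussian_field(curve, track72)
        assert fwhm == pytest.approx(2 * c_true * np.sqrt(np.log(2)), rel=1e-3)
        assert fwhm == pytest.approx(19.98, abs=0.02)
        assert adj_r2 > 0.999
        assert ok

    def test_flat_curve_fails_amplitude_criteria(self, track72):
        params, adj_r2, fwhm, ok, _ = fit_gaussian_field(np.ones(72), track72)
        assert not ok

    def test_wide_field_fails_upper_bound(self, track72):
        x = (np.arange(72) + 0.5) * track72.bin_length_cm
        c_wide = 35.0 / (2 * np.sqrt(np.log(2)))  # FWHM 35 cm > 30.6
        curve = 0.1 + 1.0 * np.exp(-(((x - 30.0) / c_wide) ** 2))
        *_, ok, _ = fit_gaussian_field(curve, track72)
        assert not ok

    def test_narrow_field_fails_lower_bound(self, track72):
        x = (np.arange(72) + 0.5) * track72.bin_length_cm
        c_narrow = 2.0 / (2 * np.sqrt(np.log(2)))  # FWHM 2 cm < 2.5
        curve = 0.1 + 1.0 * np.exp(-(((x - 30.0) / c_narrow) ** 2))
        *_, ok, _ = fit_gaussian_field(curve, track72)
        assert not ok

    def test_wraparound_field_recovered(self, track72):
        """A field straddling the origin must fit after recentering."""
        x = (np.arange(72) + 0.5) * track72.bin_length_cm
        circ = track72.midline_circumference_cm
        d = np.minimum(np.abs(x - 1.0), circ - np.abs(x - 1.0))
        curve = 0.1 + 1.0 * np.exp(-((d / 10.0) ** 2))
        params, _, fwhm, ok, _ = fit_gaussian_field(curve, track72)
        assert ok
        assert params[2] == pytest.approx(1.0, abs=1.0) or params[2] == pytest.approx(
            circ + 1.0 - circ, abs=1.0
        )


class TestSpeedScore:
    def test_perfect_positive(self):
        rng = np.random.default_rng(0)
        speed = rng.uniform(0, 200, 2000)
        score, shuf, is_sc, sign = speed_score(speed.copy(), speed, seed=1)
        assert score == pytest.approx(1.0)
        assert is_sc and sign == "+"

    def test_perfect_negative(self):
        rng = np.random.default_rng(0)
        speed = rng.uniform(0, 200, 2000)
        score, _, is_sc, sign = speed_score(-speed, speed, seed=1)
        assert score == pytest.approx(-1.0)
        assert is_sc and sign == "-"

    def test_independent_noise_rarely_passes(self):
        rng = np.random.default_rng(42)
        n_pass = 0
        n_rep = 100
        for k in range(n_rep):
            speed = rng.uniform(0, 200, 1000)
            dff = rng.normal(0, 1, 1000)
            *_, is_sc, _ = speed_score(dff, speed, seed=k)
            n_pass += is_sc
        # two one-sided 1% gates -> ~2% expected
        assert n_pass / n_rep <= 0.08

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            speed_score(np.ones(100), np.random.default_rng(0).uniform(0, 1, 100))


class TestSpatialInformation:
    def test_uniform_rate_zero_information(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        si = spatial_information(np.ones(pos.size), pos, moving, track72)
        assert si == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_log2_72(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        bins = track72.bin_index(pos)
        rates = (bins == 7).astype(float)
        si = spatial_information(rates, pos, moving, track72)
        assert si == pytest.approx(np.log2(72), rel=1e-6)

    def test_two_bins_log2_36(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        bins = track72.bin_index(pos)
        rates = ((bins == 7) | (bins == 40)).astype(float)
        si = spatial_information(rates, pos, moving, track72)
        assert si == pytest.approx(np.log2(36), rel=1e-6)

    def test_scale_invariance(self, track72):
        rng = np.random.default_rng(0)
        pos, lap_id, moving = _fake_session(track72)
        rates = rng.exponential(1.0, pos.size)
        si1 = spatial_information(rates, pos, moving, track72)
        si2 = spatial_information(7.3 * rates, pos, moving, track72)
        assert si1 == pytest.approx(si2, rel=1e-9)

    def test_zero_rate_undefined(self, track72):
        pos, lap_id, moving = _fake_session(track72)
        with pytest.raises(ValueError):
            spatial_information(np.zeros(pos.size), pos, moving, track72)


class TestLapTimeShuffle:
    def test_preserves_per_lap_content(self):
        rng = np.random.default_rng(0)
        act = rng.exponential(1.0, 300)
        lap_id = np.repeat(np.arange(3), 100)
        sh = lap_time_shuffle(act, lap_id, seed=1)
        for k in range(3):
            assert sorted(sh[lap_id == k]) == pytest.approx(
                sorted(act[lap_id == k])
            )
        assert not np.allclose(sh, act)
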