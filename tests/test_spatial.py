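"""Tug-of-war cell simulator and kymograph metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_kymograph
from para2cycle.spatial import (
    InsufficientSpanError,
    SpatialConfig,
    asymmetry_index,
    measure_period,
    measure_transit,
    simulate_cell,
)


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SpatialConfig(length_um=-1.0)
        with pytest.raises(ValueError):
            SpatialConfig(n_sites=10)
        with pytest.raises(ValueError):
            SpatialConfig(focus_positions=(1.5,))
        with pytest.raises(ValueError):
            SpatialConfig(focus_stimulation=0.5)
        with pytest.raises(ValueError):
            SpatialConfig(d_cyto_um2_s=-1.0)

    def test_step_size_guard(self):
        from para2cycle.spatial import StepSizeError

        with pytest.raises(StepSizeError):
            simulate_cell(SpatialConfig(dt_s=5.0, t_end_s=10.0))


class TestSimulateCell:
    def test_default_regime_oscillates_and_conserves(self, pde_default_run):
        kymo = pde_default_run
        total = kymo.total_copies
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6
        period = measure_period(kymo)
        assert period.oscillatory
        assert 60.0 < period.period_s < 600.0

    def test_focus_knockout_removes_oscillation(self):
        kymo = simulate_cell(SpatialConfig(focus_stimulation=1.0, t_end_s=2000.0))
        period = measure_period(kymo)
        assert not period.oscillatory
        # bound density settles: late spatial pattern stops changing
        late = kymo.density[-100:]
        assert np.std(late - late.mean(axis=0), axis=0).max() < 0.1 * late.mean()

    def test_detection_statistic_monotone_in_focus_stimulation(self):
        peaks = []
        for stim in (1.0, 5.0, 20.0, 100.0, 300.0):
            kymo = simulate_cell(SpatialConfig(focus_stimulation=stim, t_end_s=2000.0))
            peaks.append(measure_period(kymo).peak_correlation)
        assert all(b >= a - 0.02 for a, b in zip(peaks, peaks[1:]))

    def test_time_average_symmetric_about_midcell(self):
        """Midcell focus, symmetric model: the time-averaged bound density
        is left/right symmetric within 3 SE over 10 seeded runs."""
        asyms = []
        for seed in range(10):
            kymo = simulate_cell(
                SpatialConfig(init="uniform", seed=seed, t_end_s=1500.0)
            )
            left, right = kymo.halves()
            sel = kymo.t > 300.0  # discard the initial transient
            total = (left + right)[sel]
            asyms.append(float(np.mean((left[sel] - right[sel]) / total)))
        asyms = np.array(asyms)
        se = asyms.std(ddof=1) / np.sqrt(len(asyms))
        assert abs(asyms.mean()) < 3 * max(se, 1e-12)

    def test_ssa_conserves_mass_exactly_and_is_reproducible(self):
        cfg = SpatialConfig(
            engine="ssa", d_cyto_um2_s=0.05, n_sites=50, total_copies=1200,
            capacity_copies=2400, t_end_s=40.0, record_every_s=10.0, seed=5,
        )
        a = simulate_cell(cfg)
        assert np.all(a.total_copies == a.total_copies[0])
        b = simulate_cell(cfg)
        assert np.array_equal(a.density, b.density)

    def test_ssa_ensemble_matches_pde(self):
        """Half-cell bound masses: mean of SSA runs at 5000 copies within
        3 SE of the deterministic solution."""
        base = dict(
            d_cyto_um2_s=0.05, n_sites=50, total_copies=5000, capacity_copies=10000,
            t_end_s=30.0, record_every_s=10.0, focus_mode="fixed", init="left",
        )
        pde = simulate_cell(SpatialConfig(engine="pde", **base))
        runs = [simulate_cell(SpatialConfig(engine="ssa", seed=s, **base)) for s in range(12)]
        for side in (0, 1):
            ssa_half = np.array([r.halves()[side] for r in runs])
            pde_half = pde.halves()[side]
            mean = ssa_half.mean(axis=0)
            se = ssa_half.std(axis=0, ddof=1) / np.sqrt(len(runs))
            z = (mean[1:] - pde_half[1:]) / np.maximum(se[1:], 1e-9)
            assert np.all(np.abs(z) < 3.0)


class TestMeasurePeriod:
    def test_square_wave_period_recovered(self):
        t = np.arange(0, 3000, 2.0)
        dens = np.zeros((len(t), 60))
        phase = (t % 300) < 150
        dens[phase, :30] = 1.0
        dens[~phase, 30:] = 1.0
        kymo = make_kymograph(t, dens)
        res = measure_period(kymo)
        assert res.oscillatory
        assert res.period_s == pytest.approx(300.0, abs=4.0)

    def test_noisy_sinusoid_period(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 2400, 2.0)
        x = np.linspace(0, 1, 50)
        wave = 1 + np.outer(np.sin(2 * np.pi * t / 240.0), (x - 0.5))
        kymo = make_kymograph(t, wave + rng.normal(0, 0.05, wave.shape).clip(-0.9, None))
        res = measure_period(kymo)
        assert res.oscillatory
        assert res.period_s == pytest.approx(240.0, abs=10.0)

    def test_agrees_with_periodogram_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            period = float(rng.uniform(120, 600))
            t = np.arange(0, 6 * period, 2.0)
            x = np.linspace(0, 1, 40)
            dens = 1 + 0.8 * np.outer(np.sin(2 * np.pi * t / period), x - 0.5)
            dens += rng.normal(0, 0.03, dens.shape)
            kymo = make_kymograph(t, dens.clip(0, None))
            res = measure_period(kymo, seed=1)
            # periodogram oracle on the same half-difference signal
            left, right = kymo.halves()
            sig = (left - right) - (left - right).mean()
            freqs = np.fft.rfftfreq(len(sig), d=2.0)[1:]
            power = np.abs(np.fft.rfft(sig))[1:] ** 2
            oracle = 1.0 / freqs[np.argmax(power)]
            assert res.oscillatory
            assert res.period_s == pytest.approx(oracle, rel=0.2)

    def test_flat_kymograph_not_oscillatory(self):
        t = np.arange(0, 1000, 2.0)
        kymo = make_kymograph(t, np.ones((len(t), 50)))
        assert not measure_period(kymo).oscillatory

    def test_short_span_raises(self):
        t = np.arange(0, 500, 2.0)
        x = np.linspace(0, 1, 50)
        dens = 1 + np.outer(np.sin(2 * np.pi * t / 400.0), x - 0.5)
        with pytest.raises(InsufficientSpanError):
            measure_period(make_kymograph(t, dens))


class TestMeasureTransit:
    def test_instantaneous_switch_transits_in_one_frame(self):
        t = np.arange(0, 3000, 2.0)
        dens = np.zeros((len(t), 60))
        phase = (t % 300) < 150
        dens[phase, :5] = 1.0
        dens[~phase, 55:] = 1.0
        transit, n = measure_transit(make_kymograph(t, dens))
        assert n > 5
        assert transit <= 4.0  # about one frame interval

    def test_translating_gaussian_transit_is_half_length_over_speed(self):
        speed = 0.01  # um/s, L = 2 um -> transit = 0.5 * L / speed = 100 s
        t = np.arange(0, 2000, 1.0)
        x = (np.arange(100) + 0.5) * 0.02
        phase = (speed * t) % 3.6  # bounce between the poles
        centers = 0.1 + np.where(phase < 1.8, phase, 3.6 - phase)
        dens = np.exp(-0.5 * ((x[None, :] - centers[:, None]) / 0.08) ** 2)
        transit, n = measure_transit(make_kymograph(t, dens))
        assert n >= 3
        assert transit == pytest.approx(0.5 * 2.0 / speed, rel=0.1)

    def test_agrees_with_manual_crossing_extraction(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            speed = float(rng.uniform(0.005, 0.03))
            t = np.arange(0, 6000, 1.0)
            x = (np.arange(80) + 0.5) * 0.025
            phase = (speed * t) % 3.6
            centers = 0.1 + np.where(phase < 1.8, phase, 3.6 - phase)
            dens = np.exp(-0.5 * ((x[None, :] - centers[:, None]) / 0.06) ** 2)
            kymo = make_kymograph(t, dens)
            transit, n = measure_transit(kymo)
            # oracle: upward 25% -> 75% centroid crossings listed directly
            c = kymo.centroid_um() / 2.0
            t_lo = t[np.nonzero((c[:-1] < 0.25) & (c[1:] >= 0.25))[0]]
            t_hi = t[np.nonzero((c[:-1] < 0.75) & (c[1:] >= 0.75))[0]]
            events = [hi - lo for lo in t_lo for hi in t_hi if 0 < hi - lo < 1.5 / speed]
            assert events
            assert transit == pytest.approx(np.mean(events), rel=0.05)

    def test_non_oscillatory_returns_nothing(self):
        t = np.arange(0, 500, 2.0)
        kymo = make_kymograph(t, np.ones((len(t), 50)))
        transit, n = measure_transit(kymo)
        assert transit is None and n == 0


class TestAsymmetryIndex:
    def test_all_left_is_plus_one(self):
        t = np.arange(0, 10, 1.0)
        dens = np.zeros((len(t), 40))
        dens[:, :20] = 1.0
        assert asymmetry_index(make_kymograph(t, dens), 5.0) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        t = np.arange(0, 10, 1.0)
        assert asymmetry_index(make_kymograph(t, np.ones((len(t), 40))), 5.0) == pytest.approx(0.0)

    def test_zero_bound_mass_undefined(self):
        t = np.arange(0, 10, 1.0)
        assert np.isnan(asymmetry_index(make_kymograph(t, np.zeros((len(t), 40))), 5.0))

    def test_alternates_sign_with_measured_period(self, pde_default_run):
        kymo = pde_default_run
        period = measure_period(kymo).period_s
        sel = kymo.t > 400.0
        a_t = np.array([asymmetry_index(kymo, tt) for tt in kymo.t[sel][:-200]])
        half = int(round(period / 2.0 / np.median(np.diff(kymo.t))))
        a_shift = np.array([
            asymmetry_index(kymo, tt + period / 2.0) for tt in kymo.t[sel][:-200]
        ])
        # half a period later the gradient points the other way
        assert np.corrcoef(a_t, a_shift)[0, 1] < -0.5

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_for_arbitrary_densities(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 20, 1.0)
        dens = rng.uniform(0, 5, size=(len(t), 50))
        val = asymmetry_index(make_kymograph(t, dens), 10.0)
        assert -1.0 <= val <= 1.0
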