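"""Forward models of the in-vitro assays (synthetic-data generators)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from para2cycle.assays import (
    FrapParams,
    HillParams,
    MeltParams,
    gen_atpase,
    gen_carpet_timecourse,
    gen_emsa,
    gen_frap,
    gen_mant_kinetics,
    gen_thermal_melt,
    gen_trp_switch,
)
from para2cycle.inference import fit_single_exponential, fit_two_phase_decay


def _generators(rates):
    return {
        "mant": lambda noise, seed: gen_mant_kinetics(rates, "binding", noise_sigma=noise, seed=seed),
        "trp": lambda noise, seed: gen_trp_switch(rates, "ATP", noise_sigma=noise, seed=seed),
        "emsa": lambda noise, seed: gen_emsa(HillParams.preset("wt-atp"), noise_sigma=noise, seed=seed),
        "carpet": lambda noise, seed: gen_carpet_timecourse(rates, noise_sigma=noise, seed=seed),
        "frap": lambda noise, seed: gen_frap(FrapParams.preset("low-density"), noise_sigma=noise, seed=seed),
        "atpase": lambda noise, seed: gen_atpase(rates, "basal", t_points=np.linspace(0, 1800, 7), noise_sigma=noise, seed=seed),
        "melt": lambda noise, seed: gen_thermal_melt(MeltParams.preset("apo"), noise_sigma=noise, seed=seed),
    }


@pytest.mark.parametrize("name", ["mant", "trp", "emsa", "carpet", "frap", "atpase", "melt"])
def test_generators_reproducible_and_seeded(rates, name):
    """Noiseless output is bit-identical; with noise, same seed agrees and
    different seeds differ."""
    gen = _generators(rates)[name]
    a, b = gen(0.0, 1), gen(0.0, 2)
    assert np.array_equal(a.y, b.y)  # noiseless: seed-independent
    c, d, e = gen(0.05, 7), gen(0.05, 7), gen(0.05, 8)
    assert np.array_equal(c.y, d.y)
    assert not np.array_equal(c.y, e.y)


class TestMantKinetics:
    def test_binding_kobs_in_measured_band(self, rates):
        # 25 uM MANT-ATP on 2.5 uM ParA2: observed rate 0.09-0.13 /s
        tr = gen_mant_kinetics(rates, "binding")
        fit = fit_single_exponential(tr, "rise")
        assert fit.converged
        assert 0.09 <= fit["kobs"] <= 0.13

    def test_kobs_linear_in_substrate(self, rates):
        # pseudo-first-order pipeline: kobs vs [MANT-ATP] is a line
        concs = np.array([6.25, 12.5, 25.0, 50.0])
        kobs = []
        for c in concs:
            tr = gen_mant_kinetics(rates, "binding", parA2_uM=c / 10.0, mant_uM=c)
            kobs.append(fit_single_exponential(tr, "rise")["kobs"])
        slope, intercept = np.polyfit(concs, kobs, 1)
        resid = np.array(kobs) - (slope * concs + intercept)
        r2 = 1 - resid @ resid / np.sum((kobs - np.mean(kobs)) ** 2)
        assert r2 > 0.99

    def test_chase_slow_phase_in_measured_band(self, rates):
        # MANT-ATP chase: multiphasic decay with slow phase 0.015-0.02 /s
        tr = gen_mant_kinetics(rates, "dissociation", mant_uM=5.0)
        fit = fit_two_phase_decay(tr)
        assert fit.model == "two_phase_decay"
        assert 0.015 <= fit["k_slow"] <= 0.02

    def test_adp_chase_faster_than_atp_chase(self, rates):
        atp = gen_mant_kinetics(rates, "dissociation", mant_uM=5.0, nucleotide="ATP")
        adp = gen_mant_kinetics(rates, "dissociation", mant_uM=5.0, nucleotide="ADP")
        # compare times to lose half the initial signal
        t_half = lambda tr: tr.x[np.argmax(tr.y <= 0.5 * tr.y[0])]
        assert t_half(adp) < t_half(atp) / 2

    def test_flat_when_binding_disabled(self, rates):
        dead = rates.replace(k1=0.0, k6_adp_to_atp=0, k6_adp_to_adp=0, k6_atp_to_atp=0)
        tr = gen_mant_kinetics(dead, "binding", noise_sigma=0.0)
        assert np.allclose(tr.y, tr.y[0])

    def test_substoichiometric_substrate_flagged(self, rates):
        tr = gen_mant_kinetics(rates, "binding", parA2_uM=10.0, mant_uM=25.0)
        assert "pseudo_first_order_violated" in tr.meta["flags"]

    def test_exchange_round_trips_through_pseudo_first_order(self, rates):
        # ADP->ATP exchange series: fitted slope recovers k6_adp_to_atp
        from para2cycle.inference import pseudo_first_order

        pts = []
        for p, m in [(0.625, 15.625), (1.25, 31.25), (2.5, 62.5)]:
            tr = gen_mant_kinetics(rates, "exchange", parA2_uM=p, mant_uM=m,
                                   nucleotide="ATP", from_nucleotide="ADP")
            pts.append((m, fit_single_exponential(tr, "rise")["kobs"]))
        line = pseudo_first_order(pts)
        assert line["kon"] == pytest.approx(rates.k6_adp_to_atp, rel=0.05)


class TestTrpSwitch:
    def test_atp_rise_rate_and_plateau(self, rates):
        tr = gen_trp_switch(rates, "ATP")
        fit = fit_single_exponential(tr, "rise", exclude_lag=True)
        assert 0.015 <= fit["kobs"] <= 0.018
        assert tr.y[-1] - tr.y[0] == pytest.approx(0.05, rel=0.05)

    def test_dna_accelerates_and_more_than_doubles_plateau(self, rates):
        atp = gen_trp_switch(rates, "ATP")
        dna = gen_trp_switch(rates, "ATP+DNA")
        fit = fit_single_exponential(dna, "rise", exclude_lag=True)
        assert 0.03 <= fit["kobs"] <= 0.07
        assert (dna.y[-1] - dna.y[0]) > 2 * (atp.y[-1] - atp.y[0])

    def test_parb2_leaves_rates_unchanged(self, rates):
        k_plain = fit_single_exponential(gen_trp_switch(rates, "ATP"), "rise", exclude_lag=True)["kobs"]
        k_parb = fit_single_exponential(gen_trp_switch(rates, "ATP+ParB2"), "rise", exclude_lag=True)["kobs"]
        assert k_parb == pytest.approx(k_plain, rel=0.15)

    @pytest.mark.parametrize("condition", ["no-Mg", "no-ATP", "ADP", "ATPgS"])
    def test_controls_monotone_non_increasing(self, rates, condition):
        tr = gen_trp_switch(rates, condition)
        assert np.all(np.diff(tr.y) <= 1e-12)


class TestEmsa:
    def test_midpoint_is_half_plateau(self):
        p = HillParams.preset("wt-atp")
        tr = gen_emsa(p, protein_concs_nM=np.array([10, 20, 46.0, 100, 300, 600, 1200]))
        assert tr.y[2] == pytest.approx(0.5 * p.plateau, rel=1e-9)

    def test_non_cooperative_limit_is_hyperbola(self):
        c = np.geomspace(10, 1000, 8)
        tr = gen_emsa(HillParams(kd_nM=100.0, n=1.0), protein_concs_nM=c)
        assert np.allclose(tr.y, c / (100.0 + c))

    def test_adp_condition_cannot_reach_full_binding(self):
        # KD 378 nM sampled only to 1.2 uM: partial binding
        tr = gen_emsa(HillParams.preset("wt-adp"), protein_concs_nM=np.geomspace(10, 1200, 8))
        assert tr.y.max() < 0.95 * HillParams.preset("wt-adp").plateau

    def test_clipping_is_counted_never_silent(self):
        tr = gen_emsa(HillParams.preset("wt-atp"), noise_sigma=0.3, seed=5)
        assert tr.meta["clipped_points"] > 0
        assert np.all((tr.y >= 0) & (tr.y <= 1))

    def test_unidentifiable_titration_warns(self):
        with pytest.warns(UserWarning, match="below KD"):
            tr = gen_emsa(HillParams(kd_nM=5000.0, n=2.0), protein_concs_nM=np.geomspace(1, 10, 6))
        assert "unidentifiable_titration" in tr.meta["flags"]

    def test_hill_params_invariants(self):
        with pytest.raises(ValueError):
            HillParams(kd_nM=-1.0)
        with pytest.raises(ValueError):
            HillParams(kd_nM=10, n=0.5)


class TestCarpet:
    def test_atp_association_and_wash_rates(self, rates):
        # binding at 0.05 /s and wash at 0.1 /s for 1 uM ParA2 with ATP
        tr = gen_carpet_timecourse(rates, protein_conc_uM=1.0)
        pre = tr.x < tr.condition["t_switch_s"]
        assoc = fit_single_exponential(
            tr.replace(x=tr.x[pre], y=tr.y[pre], assay="carpet_assoc"), "rise"
        )
        assert assoc["kobs"] == pytest.approx(0.05, rel=0.01)
        wash = tr.replace(x=tr.x[~pre], y=tr.y[~pre], assay="carpet_wash")
        two = fit_two_phase_decay(wash)
        assert two["k_fast"] == pytest.approx(0.10, rel=0.02)

    def test_adp_gives_negligible_binding(self, rates):
        atp = gen_carpet_timecourse(rates, condition="ATP")
        adp = gen_carpet_timecourse(rates, condition="ADP")
        assert adp.y.max() < 0.05 * atp.y.max()

    def test_atpgs_slows_binding_and_dissociation(self, rates):
        tr = gen_carpet_timecourse(rates, condition="ATPgS")
        assert tr.meta["assoc_rate_s"] == pytest.approx(0.02, rel=0.01)
        assert tr.meta["wash_fast_s"] == pytest.approx(rates.k_minus3)

    def test_atp_start_mode_lags_a_minute(self, rates):
        tr = gen_carpet_timecourse(rates, mode="atp-start")
        assert np.all(tr.y[tr.x < 60.0] == 0.0)
        assert tr.y[-100] > 0  # but it does rise eventually

    def test_bad_switch_time_rejected(self, rates):
        with pytest.raises(ValueError):
            gen_carpet_timecourse(rates, t_switch=-5.0)


class TestFrap:
    def test_recovery_shape_and_asymptote(self):
        p = FrapParams.preset("low-density")
        tr = gen_frap(p)
        assert tr.y[0] == pytest.approx(0.0, abs=1e-9)
        assert tr.y[-1] == pytest.approx(1 - p.fraction_immobile, rel=0.02)

    def test_fully_immobile_curve_is_flat_zero(self):
        tr = gen_frap(FrapParams(0.0, 0.0, 1.0, 2.3, 121.0))
        assert np.allclose(tr.y, 0.0)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau_fast"):
            FrapParams(0.5, 0.3, 0.2, 100.0, 10.0)
        with pytest.raises(ValueError, match="sum"):
            FrapParams(0.8, 0.5, 0.2, 1.0, 10.0)


class TestAtpase:
    def test_stimulation_ratios_in_linear_regime(self, rates):
        t = np.linspace(0, 600, 5)  # early: little substrate depletion
        basal = gen_atpase(rates, "basal", t_points=t).y[-1]
        dna = gen_atpase(rates, "DNA", t_points=t).y[-1]
        both = gen_atpase(rates, "both", t_points=t).y[-1]
        assert dna / basal == pytest.approx(rates.stim_dna, rel=0.1)
        assert both / basal == pytest.approx(rates.stim_both, rel=0.1)

    def test_saturating_atp_gives_linear_time_course(self, rates):
        t = np.linspace(0, 1800, 10)
        tr = gen_atpase(rates, "basal", atp_uM=1e5, t_points=t)
        fitline = np.polyval(np.polyfit(t, tr.y, 1), t)
        assert np.max(np.abs(tr.y - fitline)) < 0.01 * tr.y[-1]

    def test_steady_state_series_saturates_by_substrate_depletion(self, rates):
        concs = np.array([0.5, 1.5, 5.0, 15.0, 40.0])
        tr = gen_atpase(rates, "both", parA2_uM=concs)
        gains = np.diff(tr.y) / np.diff(concs)
        assert gains[-1] < 0.2 * gains[0]  # flattening toward 100%
        assert tr.y.max() <= 100.0

    def test_k124e_is_dead(self):
        from para2cycle import preset_rates

        tr = gen_atpase(preset_rates("k124e"), "both", t_points=np.linspace(0, 1800, 6))
        assert np.allclose(tr.y, 0.0)


class TestMelt:
    @pytest.mark.parametrize("preset,tm", [("apo", 44.0), ("atp", 53.0)])
    def test_midpoint_sits_at_tm(self, preset, tm):
        p = MeltParams.preset(preset)
        tr = gen_thermal_melt(p)
        mid = 0.5 * (p.theta_folded + p.theta_unfolded)
        t_cross = np.interp(mid, tr.y, tr.x)  # theta monotone increasing
        assert t_cross == pytest.approx(tm, abs=0.2)

    def test_equal_baselines_make_flat_trace(self):
        p = MeltParams(tm_C=44.0, theta_folded=-5.0, theta_unfolded=-5.0)
        tr = gen_thermal_melt(p)
        assert np.allclose(tr.y, -5.0)

    def test_tm_outside_grid_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            tr = gen_thermal_melt(MeltParams(tm_C=80.0))
        assert "tm_outside_grid" in tr.meta["flags"]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    kd=st.floats(5.0, 2000.0),
    n=st.floats(1.0, 6.0),
    plateau=st.floats(0.3, 1.0),
)
def test_emsa_midpoint_property(kd, n, plateau):
    """f(KD) = plateau/2 for any valid Hill parameters."""
    concs = np.sort(np.append(np.geomspace(1.0, 5000.0, 7), kd))
    tr = gen_emsa(HillParams(kd_nM=kd, n=n, plateau=plateau), protein_concs_nM=concs)
    i = int(np.argmin(np.abs(tr.x - kd)))
    assert tr.y[i] == pytest.approx(0.5 * plateau, rel=1e-6)
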