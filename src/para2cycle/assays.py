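"""Forward models of the in-vitro assays: the synthetic-data generators.

Each generator emulates the statistical structure of one instrument
readout — kinetic shape, sampling grid and iid Gaussian noise (sigma given
as a fraction of the trace's dynamic range, default 0.02) — and returns a
:class:`~para2cycle.trace.Trace`.  With ``noise_sigma = 0`` every generator
is bit-reproducible; fraction-type outputs are clipped to [0, 1] and the
number of clipped points is recorded in the trace metadata, never silent.

Generators whose readout is driven by the ATPase cycle (MANT nucleotide
kinetics, tryptophan switch, radiolabel ATPase) integrate the assembled
reaction scheme; titration- and relaxation-shaped assays (EMSA, FRAP,
thermal melt) use their standard closed forms; the DNA-carpet flow assay
uses a reduced piecewise kinetic model parameterized by the rate set,
because the flowcell continuously exchanges the solution phase, which a
closed well-mixed scheme cannot represent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rates import RateSet, monomer_to_dimer
from .scheme import AssayCondition, ReactionScheme, assemble_scheme
from .simulate import initial_state, integrate
from .trace import Trace

__all__ = [
    "HillParams",
    "MeltParams",
    "FrapParams",
    "gen_mant_kinetics",
    "gen_trp_switch",
    "gen_emsa",
    "gen_carpet_timecourse",
    "gen_frap",
    "gen_atpase",
    "gen_thermal_melt",
    "stopped_flow_grid",
    "assay_params",
]

#: mg DNA per ml -> uM of 30 bp binding sites (650 g/mol/bp average)
_SITES_PER_MG_ML = 1e6 / 650.0 / 30.0

#: fold-slowdown of carpet loading with the non-hydrolysable ATP analogue
ATPGS_K3_FACTOR = 0.4

#: photobleaching drift in control tryptophan traces, fraction per second
TRP_BLEACH_PER_S = 2e-4

#: fixed cooperative nucleation delay in carpet ATP-start mode (s)
CARPET_NUCLEATION_DELAY_S = 10.0


def assay_params(group: str, name: str) -> dict:
    """Load a named assay parameter preset (emsa / frap / melt tables)."""
    from .io import read_toml
    from .rates import PRESET_DIR

    tables = read_toml(PRESET_DIR / f"{group}.toml")
    if name not in tables:
        raise KeyError(f"no {group} preset named {name!r}; have {sorted(tables)}")
    return tables[name]


# ----------------------------------------------------------------------
# parameter containers with their invariants


@dataclass(frozen=True)
class HillParams:
    """Cooperative binding isotherm f = plateau * c^n / (KD^n + c^n)."""

    kd_nM: float
    n: float = 1.0
    plateau: float = 1.0

    def __post_init__(self):
        if not self.kd_nM > 0:
            raise ValueError("KD must be positive")
        if self.n < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if not 0 < self.plateau <= 1:
            raise ValueError("plateau must be in (0, 1]")

    @classmethod
    def preset(cls, name: str) -> "HillParams":
        return cls(**assay_params("emsa", name))


@dataclass(frozen=True)
class MeltParams:
    """Two-state thermal unfolding monitored by ellipticity at 220 nm."""

    tm_C: float
    slope_C: float = 1.5
    theta_folded: float = -10.0
    theta_unfolded: float = -2.0

    def __post_init__(self):
        if self.slope_C <= 0:
            raise ValueError("cooperativity slope must be positive")

    @classmethod
    def preset(cls, name: str) -> "MeltParams":
        return cls(**assay_params("melt", name))


@dataclass(frozen=True)
class FrapParams:
    """Double-exponential photobleaching recovery parameters."""

    fraction_fast: float
    fraction_slow: float
    fraction_immobile: float
    tau_fast_s: float
    tau_slow_s: float

    def __post_init__(self):
        fracs = (self.fraction_fast, self.fraction_slow, self.fraction_immobile)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must each lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("fractions must sum to <= 1")
        if not self.tau_fast_s < self.tau_slow_s:
            raise ValueError("tau_fast must be smaller than tau_slow")
        if self.tau_fast_s <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def preset(cls, name: str) -> "FrapParams":
        return cls(**assay_params("frap", name))


# ----------------------------------------------------------------------
# noise and grids


def _apply_noise(y: np.ndarray, sigma_frac: float, rng, clip01: bool = False):
    """Add iid Gaussian noise scaled to the dynamic range; report clipping."""
    if sigma_frac == 0:
        return y.copy(), 0.0, 0
    span = float(np.ptp(y)) or 1.0
    sigma = sigma_frac * span
    noisy = y + rng.normal(0.0, sigma, size=y.shape)
    clipped = 0
    if clip01:
        clipped = int(np.sum((noisy < 0) | (noisy > 1)))
        noisy = np.clip(noisy, 0.0, 1.0)
    return noisy, sigma, clipped


def stopped_flow_grid(t_end: float) -> np.ndarray:
    """Stopped-flow sampling: 0.01 s steps to 30 s, then 0.1 s steps."""
    if t_end <= 30.0:
        return np.arange(0.0, t_end + 1e-9, 0.01)
    fast = np.arange(0.0, 30.0, 0.01)
    slow = np.arange(30.0, t_end + 1e-9, 0.1)
    return np.concatenate([fast, slow])


def _drop_reactions(scheme: ReactionScheme, prefixes: tuple) -> ReactionScheme:
    keep = [r for r in scheme.reactions if not r.name.startswith(prefixes)]
    return ReactionScheme(keep, scheme.rates, scheme.condition)


def _bound_label_signal(traj, total_monomer_uM: float) -> np.ndarray:
    """Relative MANT fluorescence: bound labelled nucleotide per ParA2 site."""
    bound = sum(
        2.0 * traj.conc(sp) for sp in ("D_ATP_M", "Dstar_ATP_M", "D_ADP_M", "B_M")
    )
    return bound / total_monomer_uM


# ----------------------------------------------------------------------
# stopped-flow MANT nucleotide kinetics


def gen_mant_kinetics(
    rates: RateSet,
    protocol: str,
    parA2_uM: float = 2.5,
    mant_uM: float = 25.0,
    nucleotide: str = "ATP",
    from_nucleotide: str = "ADP",
    chase_uM: float = 1000.0,
    preincubation_s: float = 180.0,
    t_end: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Stopped-flow MANT-nucleotide fluorescence time course.

    Protocols
    ---------
    ``binding``
        Apo ParA2 rapidly mixed with MANT-AXP at ``mant_uM`` (default 25 uM,
        10-fold over protein for pseudo-first-order conditions); fluorescence
        rises as the labelled nucleotide loads.
    ``dissociation``
        ParA2 pre-incubated with MANT-AXP, chased with ``chase_uM`` (1 mM)
        unlabelled nucleotide; fluorescence decays as the label releases.
        The effective-exchange channel is disabled here: at saturating chase
        the readout is release-limited, and keeping both representations
        would double-count the same flux.
    ``exchange``
        Dimers pre-loaded with unlabelled ``from_nucleotide`` mixed with
        MANT-``nucleotide``; the label enters through the one-step effective
        exchange reactions (k6) only, matching how exchange constants are
        measured (they are not the composition of release and rebinding).

    If the labelled substrate is not in >= 10-fold excess over ParA2 the
    trace is generated anyway but flagged ``pseudo_first_order_violated``
    (downstream kobs analysis will be biased).
    """
    if protocol not in ("binding", "dissociation", "exchange"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if nucleotide not in ("ATP", "ADP"):
        raise ValueError("nucleotide must be 'ATP' or 'ADP'")
    rng = np.random.default_rng(seed)
    dimers = monomer_to_dimer(parA2_uM)
    flags = []
    if protocol in ("binding", "exchange") and mant_uM < 10.0 * parA2_uM:
        flags.append("pseudo_first_order_violated")

    if protocol == "binding":
        t_end = 30.0 if t_end is None else t_end
        cond = AssayCondition(nucleotide="none", mant=nucleotide)
        sch = assemble_scheme(rates, cond)
        init = initial_state(D=dimers, **{f"MANT_{nucleotide}": mant_uM})
        traj = integrate(sch, init, stopped_flow_grid(t_end))
    elif protocol == "dissociation":
        t_end = 200.0 if t_end is None else t_end
        cond = AssayCondition(nucleotide=nucleotide, mant=nucleotide)
        sch = _drop_reactions(assemble_scheme(rates, cond), ("exchange_",))
        pre = integrate(
            sch, initial_state(D=dimers, **{f"MANT_{nucleotide}": mant_uM}),
            np.linspace(0.0, preincubation_s, 50),
        )
        init = dict(zip(pre.species, pre.y[-1]))
        init[nucleotide] = init.get(nucleotide, 0.0) + chase_uM
        traj = integrate(sch, init, stopped_flow_grid(t_end))
    else:  # exchange
        t_end = 200.0 if t_end is None else t_end
        unlabeled_uM = mant_uM / 5.0  # protocol: MANT at 5x the cold nucleotide
        cond = AssayCondition(nucleotide=from_nucleotide, mant=nucleotide)
        sch = _drop_reactions(
            assemble_scheme(rates, cond),
            ("bind_", "release_", "star_release_", "remodel", "hydrolyse_"),
        )
        loaded = "D_ATP" if from_nucleotide == "ATP" else "D_ADP"
        init = initial_state(
            **{
                loaded: dimers,
                from_nucleotide: max(unlabeled_uM - 2.0 * dimers, 0.0),
                f"MANT_{nucleotide}": mant_uM,
            }
        )
        traj = integrate(sch, init, stopped_flow_grid(t_end))

    y = _bound_label_signal(traj, parA2_uM)
    y, sigma_abs, _ = _apply_noise(y, noise_sigma, rng)
    return Trace(
        assay="mant",
        x=traj.t,
        y=y,
        ylabel="rel_fluorescence",
        condition={
            "protocol": protocol,
            "nucleotide": nucleotide,
            "parA2_uM": parA2_uM,
            "mant_uM": mant_uM,
            "from_nucleotide": from_nucleotide if protocol == "exchange" else None,
        },
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"flags": flags, "sigma_abs": sigma_abs},
    )


# ----------------------------------------------------------------------
# tryptophan conformational-switch kinetics

_TRP_CONDITIONS = {
    "ATP": dict(nucleotide="ATP"),
    "ATP+DNA": dict(nucleotide="ATP", dna=True),
    "ATP+ParB2": dict(nucleotide="ATP", parb2=True),
    "ATP+DNA+ParB2": dict(nucleotide="ATP", dna=True, parb2=True),
    "ADP": dict(nucleotide="ADP"),
    "ATPgS": dict(nucleotide="ATPgS"),
    "ATPgS+DNA": dict(nucleotide="ATPgS", dna=True),
    "no-Mg": dict(nucleotide="ATP", mg=False),
    "no-ATP": dict(nucleotide="none"),
}


def gen_trp_switch(
    rates: RateSet,
    condition: str,
    parA2_uM: float = 0.6,
    nucleotide_uM: float = 1000.0,
    dna_mg_ml: float = 0.1,
    t_end: float = 200.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Intrinsic tryptophan fluorescence time course after rapid mixing.

    The remodeled ParA2*-ATP state raises intrinsic fluorescence by 5% of
    baseline and the DNA-bound state by 13% (slightly dampened by ParB2);
    the ATPgS-remodeled state is spectroscopically silent except for a
    small DNA-bound increment.  Control conditions without a rising signal
    (no ATP, no Mg2+, ADP, ATPgS without DNA) carry a linear photobleaching
    drift instead.
    """
    if condition not in _TRP_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; have {sorted(_TRP_CONDITIONS)}")
    rng = np.random.default_rng(seed)
    ckw = _TRP_CONDITIONS[condition]
    cond = AssayCondition(**ckw)
    sch = assemble_scheme(rates, cond)
    dimers = monomer_to_dimer(parA2_uM)
    init_kw = {"D": dimers}
    if cond.nucleotide in ("ATP", "ATPgS"):
        init_kw["ATP"] = nucleotide_uM
    elif cond.nucleotide == "ADP":
        init_kw["ADP"] = nucleotide_uM
    if cond.dna:
        init_kw["sites"] = dna_mg_ml * _SITES_PER_MG_ML
    if cond.parb2:
        init_kw["ParB2"] = parA2_uM
    t_grid = stopped_flow_grid(t_end)
    traj = integrate(sch, initial_state(**init_kw), t_grid)

    # The printed percentages (+5% remodeled, +13% DNA-bound, slightly
    # dampened by ParB2, +3% for ATPgS on DNA) are plateau values of the
    # assay; the arbitrary-unit instrument weight is calibrated so the
    # signal-carrying species reaches that increment at its steady state.
    baseline = 1.0
    is_atp = cond.nucleotide == "ATP" and cond.mg
    if cond.dna and is_atp:
        carrier, target = traj.conc("B"), (0.115 if cond.parb2 else 0.13)
    elif cond.dna and cond.nucleotide == "ATPgS":
        carrier, target = traj.conc("B"), 0.03
    elif is_atp:
        carrier, target = traj.conc("Dstar_ATP"), 0.05
    else:
        carrier, target = np.zeros_like(t_grid), 0.0
    plateau_conc = carrier[-1]
    weight = target / plateau_conc if plateau_conc > 0 else 0.0
    y = baseline + weight * carrier
    rising = np.ptp(y) > 1e-6
    if not rising:  # photobleaching dominates the flat controls
        y = y - baseline * TRP_BLEACH_PER_S * t_grid
    y, sigma_abs, _ = _apply_noise(y, noise_sigma, rng)
    return Trace(
        assay="trp",
        x=t_grid,
        y=y,
        ylabel="rel_fluorescence",
        condition={"condition": condition, "parA2_uM": parA2_uM},
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"sigma_abs": sigma_abs, "bleach_applied": bool(not rising)},
    )


# ----------------------------------------------------------------------
# EMSA titration


def gen_emsa(
    params: HillParams,
    protein_concs_nM: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Fraction of labelled 69 bp DNA bound vs ParA2 concentration.

    Default titration: 8 points log-spaced over 10-1200 nM.  Warns when
    every concentration sits below KD/3 (the fit downstream will be
    unidentifiable).
    """
    if protein_concs_nM is None:
        protein_concs_nM = np.geomspace(10.0, 1200.0, 8)
    c = np.asarray(protein_concs_nM, dtype=float)
    if len(c) < 6:
        raise ValueError("need at least 6 titration points")
    flags = []
    if np.max(c) < params.kd_nM / 3.0:
        warnings.warn("all concentrations well below KD; Hill fit will be unidentifiable")
        flags.append("unidentifiable_titration")
    rng = np.random.default_rng(seed)
    f = params.plateau * c**params.n / (params.kd_nM**params.n + c**params.n)
    y, sigma_abs, clipped = _apply_noise(f, noise_sigma, rng, clip01=True)
    return Trace(
        assay="emsa",
        x=c,
        y=y,
        xlabel="conc_nM",
        ylabel="fraction_bound",
        condition={"kd_nM": params.kd_nM, "n": params.n, "plateau": params.plateau},
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"flags": flags, "sigma_abs": sigma_abs, "clipped_points": clipped},
    )


# ----------------------------------------------------------------------
# DNA-carpet TIRF flow assay


def _carpet_plateau(conc_uM: float, omega: float) -> float:
    """Steady-state carpet intensity vs concentration (cooperative, a.u.).

    Linear at low concentration with a quadratic cooperative term, so the
    bound level roughly doubles from 0.25 to 0.5 uM and rises faster than
    linearly near 1 uM.
    """
    return conc_uM + (omega - 1.0) / 6.0 * conc_uM**2


def gen_carpet_timecourse(
    rates: RateSet,
    protein_conc_uM: float = 1.0,
    t_switch: float = 380.0,
    t_end: float = 600.0,
    condition: str = "ATP",
    mode: str = "preincubated",
    parb2_in_wash: bool = False,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """ParA2-GFP intensity on a DNA carpet with a flow switch to wash buffer.

    Association follows a single exponential toward a cooperative plateau at
    rate k3 x [ParA2] (supply-limited by remodeling in ``atp-start`` mode);
    at ``t_switch`` the solution phase is replaced by wash buffer and the
    bound signal decays biphasically: the hydrolysis-coupled path at
    k_minus3 + k4 and the unbinding-only path at k_minus3, weighted by
    their branching ratio k4 : k_minus3.  ADP or no-nucleotide conditions
    give negligible binding; ATPgS slows loading and removes the
    hydrolysis path.  1 s frames.
    """
    if t_switch <= 0:
        raise ValueError("t_switch must be positive")
    if t_switch >= t_end:
        raise ValueError("t_switch must precede t_end")
    if condition not in ("ATP", "ADP", "ATPgS", "none"):
        raise ValueError(f"unknown condition {condition!r}")
    if mode not in ("preincubated", "atp-start"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + 1e-9, 1.0)

    if condition == "ATP":
        ka = rates.k3 * protein_conc_uM
        plateau = _carpet_plateau(protein_conc_uM, rates.coop_omega)
        k4_eff = rates.k4 * (rates.stim_both / rates.stim_dna if parb2_in_wash else 1.0)
        k_fast, k_slow = rates.k_minus3 + k4_eff, rates.k_minus3
        f_fast = k4_eff / (k4_eff + rates.k_minus3) if (k4_eff + rates.k_minus3) > 0 else 0.0
    elif condition == "ATPgS":
        ka = ATPGS_K3_FACTOR * rates.k3 * protein_conc_uM
        plateau = _carpet_plateau(protein_conc_uM, rates.coop_omega)
        k_fast, k_slow = rates.k_minus3, rates.k_minus3
        f_fast = 1.0
    else:  # ADP / apo: negligible binding
        ka = rates.k3 * protein_conc_uM
        plateau = 0.02 * _carpet_plateau(protein_conc_uM, 1.0)
        k_fast, k_slow = rates.k_minus5, rates.k_minus5
        f_fast = 1.0

    t_delay = 0.0
    if mode == "atp-start":
        if condition != "ATP":
            raise ValueError("atp-start mode applies to the ATP condition")
        # protein meets ATP only at infusion: binding + remodeling delay,
        # plus cooperative nucleation on the bare carpet
        t_delay = 1.0 / rates.k2 + 1.0 / max(rates.k1 * 1000.0, 1e-9) + CARPET_NUCLEATION_DELAY_S
        plateau *= 0.15  # flow carries most not-yet-active protein away
        ka /= 3.0

    y = np.where(
        t < t_delay, 0.0, plateau * (1.0 - np.exp(-ka * np.clip(t - t_delay, 0.0, None)))
    )
    after = t >= t_switch
    y_sw = plateau * (1.0 - np.exp(-ka * max(t_switch - t_delay, 0.0)))
    dt = t[after] - t_switch
    y[after] = y_sw * (f_fast * np.exp(-k_fast * dt) + (1.0 - f_fast) * np.exp(-k_slow * dt))
    y, sigma_abs, _ = _apply_noise(y, noise_sigma, rng)
    return Trace(
        assay="carpet",
        x=t,
        y=y,
        ylabel="intensity_au",
        condition={
            "condition": condition,
            "mode": mode,
            "protein_conc_uM": protein_conc_uM,
            "t_switch_s": t_switch,
            "parb2_in_wash": parb2_in_wash,
        },
        noise_sigma=noise_sigma,
        seed=seed,
        meta={
            "sigma_abs": sigma_abs,
            "assoc_rate_s": ka,
            "wash_fast_s": k_fast,
            "wash_slow_s": k_slow,
            "delay_s": t_delay,
        },
    )


# ----------------------------------------------------------------------
# FRAP


def gen_frap(
    params: FrapParams,
    t_end: float = 600.0,
    frame_s: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Photobleaching recovery curve, double-exponential with an immobile
    fraction: y(t) = (1 - immobile) - f_fast e^(-t/tau_fast)
    - f_slow e^(-t/tau_slow); y(0) = 0 when the fractions sum to 1 and the
    asymptote is 1 - immobile."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + 1e-9, frame_s)
    y = (
        (1.0 - params.fraction_immobile)
        - params.fraction_fast * np.exp(-t / params.tau_fast_s)
        - params.fraction_slow * np.exp(-t / params.tau_slow_s)
    )
    y, sigma_abs, clipped = _apply_noise(y, noise_sigma, rng, clip01=True)
    return Trace(
        assay="frap",
        x=t,
        y=y,
        ylabel="recovery_fraction",
        condition={
            "tau_fast_s": params.tau_fast_s,
            "tau_slow_s": params.tau_slow_s,
            "fraction_immobile": params.fraction_immobile,
        },
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"sigma_abs": sigma_abs, "clipped_points": clipped},
    )


# ----------------------------------------------------------------------
# radiolabel ATPase


def gen_atpase(
    rates: RateSet,
    condition: str = "basal",
    parA2_uM: float | np.ndarray = 1.5,
    atp_uM: float = 100.0,
    t_points: np.ndarray | None = None,
    fixed_time_s: float = 1800.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Percent ATP hydrolysed, pre-steady-state or steady-state mode.

    ``condition`` is one of basal / DNA / ParB2 / both; the TLC readout does
    not resolve DNA-bound intermediates, so hydrolysis enters as the lumped
    stimulated step kcat x fold-stimulation on ATP-loaded dimers, and the
    finite labelled-ATP pool saturates the steady-state series at high
    ParA2 (substrate depletion).

    Pre-steady-state: scalar ``parA2_uM``, ``t_points`` in s (default ten
    points to 3600 s).  Steady-state: array ``parA2_uM``, hydrolysis after
    ``fixed_time_s`` (30 min).
    """
    stim_map = {"basal": (False, False), "DNA": (True, False), "ParB2": (False, True), "both": (True, True)}
    if condition not in stim_map:
        raise ValueError(f"unknown condition {condition!r}")
    dna, parb = stim_map[condition]
    lumped = rates.replace(kcat=rates.kcat * rates.stimulation(dna, parb))
    sch = assemble_scheme(lumped, AssayCondition(nucleotide="ATP"))
    rng = np.random.default_rng(seed)

    def percent_hydrolysed(conc_uM: float, t_grid: np.ndarray) -> np.ndarray:
        init = initial_state(D=monomer_to_dimer(conc_uM), ATP=atp_uM)
        traj = integrate(sch, init, t_grid)
        return 100.0 * traj.adp_equivalents() / atp_uM

    if np.ndim(parA2_uM) == 0:  # pre-steady state: vary time
        t = np.linspace(0.0, 3600.0, 10) if t_points is None else np.asarray(t_points, float)
        y = percent_hydrolysed(float(parA2_uM), t)
        x, xlabel = t, "time_s"
    else:  # steady state: vary ParA2, fixed interval
        concs = np.asarray(parA2_uM, dtype=float)
        y = np.array(
            [percent_hydrolysed(cc, np.array([0.0, fixed_time_s]))[-1] for cc in concs]
        )
        x, xlabel = concs, "parA2_uM"
    y, sigma_abs, _ = _apply_noise(y, noise_sigma, rng)
    return Trace(
        assay="atpase",
        x=x,
        y=y,
        xlabel=xlabel,
        ylabel="percent_hydrolysed",
        condition={"condition": condition, "atp_uM": atp_uM},
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"sigma_abs": sigma_abs},
    )


# ----------------------------------------------------------------------
# CD thermal melt


def gen_thermal_melt(
    params: MeltParams,
    T_grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Ellipticity at 220 nm vs temperature: two-state Boltzmann sigmoid
    between folded and unfolded baselines with midpoint Tm.  Default scan
    23 -> 63 C in 2 C increments.  Flags a Tm outside the scanned range."""
    if T_grid is None:
        T_grid = np.arange(23.0, 63.0 + 1e-9, 2.0)
    T = np.asarray(T_grid, dtype=float)
    flags = []
    if not (T[0] <= params.tm_C <= T[-1]):
        warnings.warn("Tm lies outside the scanned temperature range")
        flags.append("tm_outside_grid")
    rng = np.random.default_rng(seed)
    frac_unfolded = 1.0 / (1.0 + np.exp((params.tm_C - T) / params.slope_C))
    y = params.theta_folded + (params.theta_unfolded - params.theta_folded) * frac_unfolded
    y, sigma_abs, _ = _apply_noise(y, noise_sigma, rng)
    return Trace(
        assay="melt",
        x=T,
        y=y,
        xlabel="temperature_C",
        ylabel="theta220_au",
        condition={"tm_C": params.tm_C},
        noise_sigma=noise_sigma,
        seed=seed,
        meta={"flags": flags, "sigma_abs": sigma_abs},
    )
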