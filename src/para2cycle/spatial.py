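"""1D stochastic reaction-diffusion model of tug-of-war ParA2 oscillations.

The cell is a 1D lattice over which ParA2 cycles through the kinetic
states of the ATPase cycle, with only the nucleoid-bound state immobile:

    B --(k_minus3, no hydrolysis)--> C3 (active ParA2*_2-ATP_2, diffusing)
    B --(hydrolysis, focus-stimulated)--> C1 (ParA2_2-ADP_2, diffusing)
    C1 --nucleotide exchange (k6 x [ATP])--> C2 (ParA2_2-ATP_2)
    C2 --remodeling (uncatalyzed k2)------> C3
    C3 --cooperative loading--------------> B

The two release channels differ in kind: unbinding without hydrolysis
returns an ACTIVE dimer that can rebind immediately, while
hydrolysis-coupled release — stimulated ~100-fold where ParB2 is
concentrated on the partition complex — routes the dimer through the slow
nucleotide-exchange + remodeling recovery before it can rebind.

Loading at site i follows k_on (1 + (omega - 1) theta_i^2)(1 - theta_i)
with theta_i the local occupancy of a finite site capacity: a
nucleation-elongation form (insertion is strongly favoured only where a
dimer lands between existing neighbours, i.e. inside growing oligomers)
with saturation of the available sites.

The ParB2-parS2 focus acts as a local hydrolysis catalyst.  In the
default ``gradient`` mode it drifts toward nearby bound ParA2 at a
capped speed (transient ParA2*-ParB2 tethers acting as springs); the
pulling force itself is not mechanically modelled.

A static focus (or one without hydrolysis stimulation) relaxes to a
stationary ParA2 distribution: linear stability analysis of this model
class shows the pole-to-pole mode carries only stationary instabilities.
Sustained oscillation appears when the focus responds to the wave — the
locus chases the bound-ParA2 gradient, erodes the wave it reaches, and
the released protein rebuilds the wave on the opposite side after the
slow nucleotide-exchange/remodeling delay, swinging the system pole to
pole with a period set by the locus speed and the recovery delay.

Both a deterministic PDE engine (operator splitting: exact diffusion
propagator + RK4 reactions) and an exact RDME-style SSA engine (Gillespie
over hops and reactions, numba-accelerated when available) are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .rates import RateSet, default_rates

__all__ = [
    "SpatialConfig",
    "Kymograph",
    "PeriodResult",
    "simulate_cell",
    "measure_period",
    "measure_transit",
    "asymmetry_index",
    "StepSizeError",
    "InsufficientSpanError",
]


class StepSizeError(ValueError):
    """Reaction step too large for the fastest local rate (PDE mode)."""


class InsufficientSpanError(ValueError):
    """Kymograph shorter than three putative oscillation periods."""


@dataclass(frozen=True)
class SpatialConfig:
    """Geometry, transport and kinetic context of the simulated cell.

    Defaults place the model in the oscillatory regime located by a coarse
    parameter scan; the in-vivo copy number, diffusion coefficient,
    carrying capacity and focus strength are declared assumptions (the
    measurements behind the RateSet are in-vitro).
    """

    length_um: float = 2.0
    n_sites: int = 100
    d_cyto_um2_s: float = 3.0
    d_bound_um2_s: float = 0.0
    rates: RateSet = field(default_factory=default_rates)
    #: ParB2-parS2 focus position(s), as fractions of cell length
    focus_positions: tuple = (0.5,)
    focus_width_um: float = 0.25
    #: local fold-stimulation of hydrolysis-coupled release at the focus
    #: (1 = off).  The default puts the focal release at the k4
    #: wash-regime scale: kcat x stim_dna x 100 ~ 0.1 /s.
    focus_stimulation: float = 100.0
    #: "gradient": the focus is tugged toward nearby bound ParA2 (capped
    #: speed) — the tug-of-war proper, and the only mode with sustained
    #: pole-to-pole oscillations; "fixed": static focus, which relaxes to
    #: a stationary ParA2 distribution (no oscillation).
    focus_mode: str = "gradient"
    #: maximum focus drift speed (um/s) in gradient mode
    focus_speed_um_s: float = 0.02
    #: reach of the ParA2-ParB2 tethers pulling the focus (um)
    focus_sense_um: float = 0.4
    total_copies: int = 2000
    #: bound-state carrying capacity of the whole nucleoid, in copies
    capacity_copies: int = 4000
    atp_uM: float = 1000.0
    #: cooperative loading rate constant of the active dimer (per s)
    k_on_s: float = 0.1
    #: nearest-neighbour lattice cooperativity of loading.  Distinct from
    #: the mean-field EMSA-derived coop_omega of the RateSet: a 1D lattice
    #: contact factor is not bounded by the Hill coefficient of a 69 bp
    #: probe, and the oscillatory regime needs the stronger
    #: self-reinforcement that full-length DNA permits.
    omega_lattice: float = 100.0
    t_end_s: float = 1500.0
    dt_s: float = 0.05
    record_every_s: float = 2.0
    engine: str = "pde"
    #: initial bound distribution: "left" (post-division bias) or "uniform"
    init: str = "left"
    seed: int = 0

    def __post_init__(self):
        if self.length_um <= 0:
            raise ValueError("cell length must be positive")
        if self.n_sites < 50:
            raise ValueError("need at least 50 lattice sites")
        if self.d_cyto_um2_s < 0 or self.d_bound_um2_s < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        for f in self.focus_positions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("focus positions are cell-length fractions in [0, 1]")
        if self.focus_stimulation < 1.0:
            raise ValueError("focus stimulation factor must be >= 1")
        if self.omega_lattice < 1.0:
            raise ValueError("lattice cooperativity must be >= 1")
        if self.focus_mode not in ("gradient", "fixed"):
            raise ValueError("focus_mode must be 'gradient' or 'fixed'")
        if self.engine not in ("pde", "ssa"):
            raise ValueError("engine must be 'pde' or 'ssa'")
        if self.init not in ("left", "uniform"):
            raise ValueError("init must be 'left' or 'uniform'")

    @property
    def dx_um(self) -> float:
        return self.length_um / self.n_sites

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_sites) + 0.5) * self.dx_um

    def foci_um(self) -> np.ndarray:
        return np.array([f * self.length_um for f in self.focus_positions])

    def hydrolysis_profile(self, foci_um: np.ndarray | None = None) -> np.ndarray:
        """Per-site hydrolysis-coupled release rate (per s, delayed path)."""
        r = self.rates
        background = r.kcat * r.stim_dna
        phi = np.zeros(self.n_sites)
        x = self.x_centers()
        foci = self.foci_um() if foci_um is None else foci_um
        for fx in foci:
            phi += np.exp(-0.5 * ((x - fx) / self.focus_width_um) ** 2)
        phi = np.clip(phi, 0.0, 1.0)
        return background * (1.0 + (self.focus_stimulation - 1.0) * phi)

    def drift_focus(self, foci_um: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
        """Tug the focus toward nearby bound ParA2 (capped speed).

        The net pull is the bound-density-weighted mean displacement within
        the tether reach ``focus_sense_um`` — transient ParA2*-ParB2 bonds
        act like springs, so the locus drifts toward the side holding more
        bound ParA2 within reach.
        """
        if self.focus_mode != "gradient":
            return foci_um
        x = self.x_centers()
        out = foci_um.copy()
        for j, fx in enumerate(foci_um):
            w = np.exp(-0.5 * ((x - fx) / self.focus_sense_um) ** 2) * b
            wsum = float(w.sum())
            if wsum <= 0:
                continue
            disp = float((w @ (x - fx)) / wsum)
            v = self.focus_speed_um_s * math.tanh(disp / (0.5 * self.focus_sense_um))
            out[j] = min(max(fx + v * dt, 0.05 * self.length_um), 0.95 * self.length_um)
        return out

    def cycle_rates(self) -> tuple:
        """(k_exchange, k_remodel) for the cytoplasmic recovery chain.

        Remodeling uses the uncatalyzed k2: the DNA acceleration acts on
        dimers already engaging the nucleoid, not on the diffusing pool,
        and the slow uncatalyzed switch (~1/k2 = 60 s) is the delay that
        the observed 30-60 s pole-to-pole transit times rest on.
        """
        r = self.rates
        return r.k6_adp_to_atp * self.atp_uM, r.k2


@dataclass
class Kymograph:
    """Space x time record of nucleoid-bound ParA2 density."""

    t: np.ndarray
    density: np.ndarray  # (n_t, n_sites) bound copies per site
    x_um: np.ndarray
    total_copies: np.ndarray  # all species, all sites, per frame
    focus_positions: tuple
    focus_trajectory_um: np.ndarray | None = None  # (n_t, n_foci)
    config: SpatialConfig | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.density = np.asarray(self.density, float)
        if self.density.shape != (len(self.t), len(self.x_um)):
            raise ValueError("density matrix shape mismatch")
        if np.any(self.density < -1e-9):
            raise ValueError("bound density must be non-negative")

    @property
    def length_um(self) -> float:
        return float(self.x_um[-1] + self.x_um[0])

    def bound_mass(self) -> np.ndarray:
        return self.density.sum(axis=1)

    def halves(self) -> tuple:
        mid = self.density.shape[1] // 2
        return self.density[:, :mid].sum(axis=1), self.density[:, mid:].sum(axis=1)

    def centroid_um(self) -> np.ndarray:
        mass = self.bound_mass()
        with np.errstate(invalid="ignore"):
            return np.where(mass > 0, self.density @ self.x_um / np.where(mass > 0, mass, 1.0), np.nan)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.density, columns=[f"x_{x:.3f}um" for x in self.x_um])
        df.insert(0, "time_s", self.t)
        df.to_csv(path, index=False)
        from .io import write_json
        from pathlib import Path

        p = Path(path)
        write_json(
            p.with_suffix(p.suffix + ".json"),
            {
                "focus_positions": list(self.focus_positions),
                "provenance": self.provenance,
            },
        )

    def render_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            self.density.T,
            aspect="auto",
            origin="lower",
            extent=(self.t[0], self.t[-1], 0, self.x_um[-1]),
            cmap="viridis",
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position (um)")
        fig.colorbar(im, ax=ax, label="bound ParA2 (copies/site)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _diffusion_propagator(n: int, d_over_dx2: float, dt: float) -> np.ndarray:
    """exp(dt L) for the reflecting 1D Laplacian (exactly mass-conserving)."""
    lap = np.zeros((n, n))
    idx = np.arange(n)
    lap[idx, idx] = -2.0
    lap[idx[:-1], idx[:-1] + 1] = 1.0
    lap[idx[1:], idx[1:] - 1] = 1.0
    lap[0, 0] = -1.0
    lap[-1, -1] = -1.0
    return expm(d_over_dx2 * dt * lap)


def _initial_bound(config: SpatialConfig, rng) -> np.ndarray:
    n = config.n_sites
    b = np.zeros(n)
    if config.init == "left":
        b[: n // 2] = 1.0
    else:
        b[:] = 1.0
        # seeded relative perturbation so the deterministic engine can
        # break left/right symmetry the way copy-number noise would
        b *= 1.0 + 0.02 * rng.standard_normal(n)
    b = np.clip(b, 0.0, None)
    return b / b.sum() * (0.8 * config.total_copies)


def _simulate_pde(config: SpatialConfig) -> Kymograph:
    n = config.n_sites
    dx2 = config.dx_um**2
    k_ex, k_rm = config.cycle_rates()
    k_hyd = config.hydrolysis_profile()
    k_unbind = config.rates.k_minus3
    omega = config.omega_lattice
    cap = config.capacity_copies / n
    k_on = config.k_on_s

    max_rate = max(k_ex, k_rm, k_on * (omega + 1.0) ** 2 / (4.0 * omega),
                   float(k_hyd.max()) + k_unbind)
    if config.dt_s * max_rate > 0.5:
        raise StepSizeError(
            f"dt={config.dt_s}s too large for fastest rate {max_rate:.3g}/s"
        )

    rng = np.random.default_rng(config.seed)
    b = _initial_bound(config, rng)
    pool = (config.total_copies - b.sum()) / n
    c1 = np.full(n, pool)
    c2 = np.zeros(n)
    c3 = np.zeros(n)

    prop = _diffusion_propagator(n, config.d_cyto_um2_s / dx2, config.dt_s)
    prop_b = (
        _diffusion_propagator(n, config.d_bound_um2_s / dx2, config.dt_s)
        if config.d_bound_um2_s > 0
        else None
    )

    def reaction_rhs(state):
        c1_, c2_, c3_, b_ = state
        theta = np.clip(b_ / cap, 0.0, 1.0)
        # nearest-neighbour cooperativity: the enhancement senses the
        # occupancy of the site and its two neighbours, so oligomer
        # regions grow along the lattice (waves spread spatially);
        # edge sites count themselves twice (same rule as the SSA engine)
        theta_nb = (
            np.concatenate((theta[:1], theta[:-1]))
            + theta
            + np.concatenate((theta[1:], theta[-1:]))
        ) / 3.0
        bind = k_on * (1.0 + (omega - 1.0) * theta_nb**2) * (1.0 - theta) * c3_
        hyd = k_hyd * b_  # k_hyd follows the moving focus profile
        unbind = k_unbind * b_
        return np.array(
            [
                hyd - k_ex * c1_,
                k_ex * c1_ - k_rm * c2_,
                k_rm * c2_ - bind + unbind,
                bind - hyd - unbind,
            ]
        )

    n_steps = int(round(config.t_end_s / config.dt_s))
    every = max(1, int(round(config.record_every_s / config.dt_s)))
    foci = config.foci_um()
    t_rec, b_rec, tot_rec = [0.0], [b.copy()], [config.total_copies * 1.0]
    foci_rec = [foci.copy()]
    state = np.array([c1, c2, c3, b])
    dt = config.dt_s
    for step in range(1, n_steps + 1):
        # Lie splitting: exact diffusion propagator, then RK4 reactions
        state[0] = prop @ state[0]
        state[1] = prop @ state[1]
        state[2] = prop @ state[2]
        if prop_b is not None:
            state[3] = prop_b @ state[3]
        k1_ = reaction_rhs(state)
        k2_ = reaction_rhs(state + 0.5 * dt * k1_)
        k3_ = reaction_rhs(state + 0.5 * dt * k2_)
        k4_ = reaction_rhs(state + dt * k3_)
        state = state + dt / 6.0 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        state = np.clip(state, 0.0, None)
        if config.focus_mode == "gradient" and step % 10 == 0:
            new_foci = config.drift_focus(foci, state[3], 10 * dt)
            if not np.array_equal(new_foci, foci):
                foci = new_foci
                k_hyd = config.hydrolysis_profile(foci)
        if step % every == 0:
            t_rec.append(step * dt)
            b_rec.append(state[3].copy())
            tot_rec.append(float(state.sum()))
            foci_rec.append(foci.copy())
    return Kymograph(
        np.array(t_rec),
        np.array(b_rec),
        config.x_centers(),
        np.array(tot_rec),
        config.focus_positions,
        focus_trajectory_um=np.array(foci_rec),
        config=config,
        provenance={"engine": "pde", "seed": config.seed},
    )


# ----------------------------------------------------------------------
# exact stochastic engine (RDME): hops between neighbouring sites plus
# the four reactions, direct-method Gillespie


def _ssa_core(state, hop, k_ex, k_rm, k_on, omega, cap, k_hyd, k_unbind, t_end, rec_times, seed):
    """Event loop (numba-compiled when available; legacy RNG API for that)."""
    np.random.seed(seed)
    n = state.shape[1]
    n_rec = len(rec_times)
    out = np.zeros((n_rec, n), dtype=np.int64)
    tot = np.zeros(n_rec, dtype=np.int64)
    t = 0.0
    rec = 0
    while True:
        # propensities
        a_hop = 0.0
        for s in range(4):
            if hop[s] > 0:
                a_hop += hop[s] * (2 * state[s].sum() - state[s, 0] - state[s, n - 1])
        a_react = np.zeros(5)
        a_react[0] = k_ex * state[0].sum()
        a_react[1] = k_rm * state[1].sum()
        theta = np.minimum(state[3] / cap, 1.0)
        theta_nb = np.empty(n)
        for j in range(n):
            lo = j - 1 if j > 0 else j
            hi = j + 1 if j < n - 1 else j
            theta_nb[j] = (theta[lo] + theta[j] + theta[hi]) / 3.0
        bind_site = k_on * (1.0 + (omega - 1.0) * theta_nb**2) * (1.0 - theta) * state[2]
        a_react[2] = bind_site.sum()
        hyd_site = k_hyd * state[3]
        a_react[3] = hyd_site.sum()
        unbind_site = k_unbind * state[3].astype(np.float64)
        a_react[4] = unbind_site.sum()
        a0 = a_hop + a_react.sum()
        if a0 <= 0:
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_end:
            break
        while rec < n_rec and rec_times[rec] < t:
            out[rec] = state[3]
            tot[rec] = state.sum()
            rec += 1
        u = np.random.random() * a0
        if u < a_hop:
            # pick species, then site, then direction
            for s in range(4):
                if hop[s] <= 0:
                    continue
                w = hop[s] * (2 * state[s].sum() - state[s, 0] - state[s, n - 1])
                if u < w:
                    # site weights: interior 2, edges 1
                    u2 = u / hop[s]
                    i = 0
                    acc = 0.0
                    for j in range(n):
                        wj = state[s, j] * (1 if (j == 0 or j == n - 1) else 2)
                        acc += wj
                        if u2 < acc:
                            i = j
                            break
                    if i == 0:
                        dest = 1
                    elif i == n - 1:
                        dest = n - 2
                    else:
                        dest = i + 1 if np.random.random() < 0.5 else i - 1
                    state[s, i] -= 1
                    state[s, dest] += 1
                    break
                u -= w
        else:
            u -= a_hop
            if u < a_react[0]:
                i = _pick(state[0].astype(np.float64), u / k_ex)
                state[0, i] -= 1
                state[1, i] += 1
            elif u < a_react[0] + a_react[1]:
                i = _pick(state[1].astype(np.float64), (u - a_react[0]) / k_rm)
                state[1, i] -= 1
                state[2, i] += 1
            elif u < a_react[0] + a_react[1] + a_react[2]:
                i = _pick(bind_site, u - a_react[0] - a_react[1])
                state[2, i] -= 1
                state[3, i] += 1
            elif u < a_react[0] + a_react[1] + a_react[2] + a_react[3]:
                i = _pick(hyd_site, u - a_react[0] - a_react[1] - a_react[2])
                state[3, i] -= 1
                state[0, i] += 1
            else:
                i = _pick(unbind_site, u - a_react[0] - a_react[1] - a_react[2] - a_react[3])
                state[3, i] -= 1
                state[2, i] += 1
    while rec < n_rec:
        out[rec] = state[3]
        tot[rec] = state.sum()
        rec += 1
    return out, tot


def _pick(weights, u):
    acc = 0.0
    for j in range(len(weights)):
        acc += weights[j]
        if u < acc:
            return j
    return len(weights) - 1


try:  # optional numba acceleration of the event loop
    import numba as _nb

    _pick = _nb.njit(cache=False)(_pick)
    _ssa_core_nb = _nb.njit(cache=False)(_ssa_core)

    def _ssa_dispatch(*args):
        return _ssa_core_nb(*args)

except Exception:  # pragma: no cover - numba is present in the test env

    def _ssa_dispatch(*args):
        return _ssa_core(*args)


def _simulate_ssa(config: SpatialConfig) -> Kymograph:
    n = config.n_sites
    dx2 = config.dx_um**2
    k_ex, k_rm = config.cycle_rates()
    k_hyd = config.hydrolysis_profile()
    rng = np.random.default_rng(config.seed)
    b0 = _initial_bound(config, rng)
    # integer-valued initial state with the exact total copy number
    b = np.floor(b0).astype(np.int64)
    remainder = int(config.total_copies - b.sum())
    c1 = np.zeros(n, dtype=np.int64)
    idx = rng.integers(0, n, size=remainder)
    np.add.at(c1, idx, 1)
    state = np.zeros((4, n), dtype=np.int64)
    state[0] = c1
    state[3] = b
    hop = np.array(
        [config.d_cyto_um2_s / dx2] * 3 + [config.d_bound_um2_s / dx2], dtype=float
    )
    rec_times = np.arange(0.0, config.t_end_s + 1e-9, config.record_every_s)
    args = (
        float(k_ex),
        float(k_rm),
        float(config.k_on_s),
        float(config.omega_lattice),
        float(config.capacity_copies / n),
    )
    foci = config.foci_um()
    if config.focus_mode == "fixed":
        out, tot = _ssa_dispatch(
            state, hop, *args, k_hyd.astype(float), float(config.rates.k_minus3),
            float(config.t_end_s), rec_times, int(config.seed),
        )
        foci_traj = np.tile(foci, (len(rec_times), 1))
    else:
        # frame-wise segments: the focus drifts between frames, the exact
        # SSA runs within each frame with a frozen hydrolysis profile
        out = np.zeros((len(rec_times), n), dtype=np.int64)
        tot = np.zeros(len(rec_times), dtype=np.int64)
        foci_traj = np.zeros((len(rec_times), len(foci)))
        out[0], tot[0], foci_traj[0] = state[3], state.sum(), foci
        seg = float(config.record_every_s)
        one = np.array([seg])
        for fr in range(1, len(rec_times)):
            k_hyd = config.hydrolysis_profile(foci)
            o, tt = _ssa_dispatch(
                state, hop, *args, k_hyd.astype(float),
                float(config.rates.k_minus3), seg, one, int(config.seed) + fr,
            )
            out[fr], tot[fr] = o[0], tt[0]
            foci = config.drift_focus(foci, state[3].astype(float), seg)
            foci_traj[fr] = foci
    return Kymograph(
        rec_times,
        out.astype(float),
        config.x_centers(),
        tot.astype(float),
        config.focus_positions,
        focus_trajectory_um=np.asarray(foci_traj, dtype=float),
        config=config,
        provenance={"engine": "ssa", "seed": config.seed},
    )


def simulate_cell(config: SpatialConfig) -> Kymograph:
    """Run the tug-of-war cell model and return the bound-ParA2 kymograph.

    Total ParA2 over all states and sites is conserved exactly in SSA mode
    and to 1e-6 (relative) in PDE mode.
    """
    if config.engine == "pde":
        return _simulate_pde(config)
    return _simulate_ssa(config)


# ----------------------------------------------------------------------
# kymograph metrics


@dataclass
class PeriodResult:
    period_s: float | None
    oscillatory: bool
    peak_correlation: float
    threshold: float
    flags: list = field(default_factory=list)


def measure_period(
    kymo: Kymograph, n_surrogates: int = 100, seed: int = 0
) -> PeriodResult:
    """Oscillation period from the left/right bound-mass difference.

    The period is the lag of the first off-zero peak of the
    autocorrelation of the half-mass difference signal; the peak must
    exceed the 95th percentile of peak autocorrelations from
    ``n_surrogates`` time-shuffled surrogates, otherwise the kymograph is
    flagged non-oscillatory.  A detected period longer than a third of the
    span raises :class:`InsufficientSpanError`.
    """
    left, right = kymo.halves()
    sig = left - right
    sig = sig - sig.mean()
    n = len(sig)
    if n < 8 or np.allclose(sig, 0):
        return PeriodResult(None, False, 0.0, np.inf, ["signal flat"])
    dt = float(np.median(np.diff(kymo.t)))

    def first_peak(s) -> tuple:
        ac = np.correlate(s, s, mode="full")[n - 1 :]
        if ac[0] <= 0:
            return None, 0.0
        ac = ac / ac[0]
        # first local max after the first zero-ish dip
        for i in range(1, len(ac) - 1):
            if ac[i] >= ac[i - 1] and ac[i] > ac[i + 1] and ac[i] > 0:
                return i, float(ac[i])
        return None, 0.0

    lag, peak = first_peak(sig)
    rng = np.random.default_rng(seed)
    surrogate_peaks = []
    for _ in range(n_surrogates):
        s = rng.permutation(sig)
        _, p = first_peak(s)
        surrogate_peaks.append(p)
    threshold = float(np.percentile(surrogate_peaks, 95))
    if lag is None or peak <= threshold:
        return PeriodResult(None, False, peak, threshold, ["no significant peak"])
    period = lag * dt
    if period * 3 > (kymo.t[-1] - kymo.t[0]):
        raise InsufficientSpanError(
            f"span {kymo.t[-1] - kymo.t[0]:.0f}s covers fewer than 3 periods of {period:.0f}s"
        )
    return PeriodResult(period, True, peak, threshold)


def measure_transit(kymo: Kymograph, lo: float = 0.25, hi: float = 0.75):
    """Mean pole-to-pole transit time of the bound-mass centroid.

    A transit is one crossing of the centroid from the 25% to the 75%
    cell-length position (either direction) per half-cycle.  Returns
    (mean_transit_s, n_events); a non-oscillatory kymograph with no
    complete crossing returns (None, 0).
    """
    c = kymo.centroid_um() / kymo.length_um
    t = kymo.t
    events = []
    state = None  # which band the centroid last occupied
    t_enter = None
    for i in range(len(c)):
        if not np.isfinite(c[i]):
            continue
        if c[i] <= lo:
            if state == "hi" and t_enter is not None:
                events.append(t[i] - t_enter)
            state, t_enter = "lo", t[i]
        elif c[i] >= hi:
            if state == "lo" and t_enter is not None:
                events.append(t[i] - t_enter)
            state, t_enter = "hi", t[i]
    if not events:
        return None, 0
    return float(np.mean(events)), len(events)


def asymmetry_index(kymo: Kymograph, t: float) -> float:
    """(left-half bound mass - right-half) / total at the frame nearest t.

    +1 means all bound ParA2 sits in the left half, 0 a symmetric
    distribution.  Returns NaN (undefined) when no ParA2 is bound.
    """
    if not kymo.t[0] <= t <= kymo.t[-1]:
        raise ValueError("t outside the simulated span")
    i = int(np.argmin(np.abs(kymo.t - t)))
    left, right = kymo.halves()
    total = left[i] + right[i]
    if total <= 0:
        return float("nan")
    return float((left[i] - right[i]) / total)
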