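"""Deterministic and stochastic engines for an assembled reaction scheme.

`integrate` solves the mass-action ODEs with a stiff adaptive solver;
`sample_ssa` runs an exact Gillespie direct-method simulation on copy
numbers; `project_observable` maps a trajectory to a fluorescence-style
signal through a linear observable map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .scheme import ADP_CONTENT, NUCLEOTIDE_CONTENT, PARA2_SPECIES, ReactionScheme, SPECIES
from .trace import Trace

__all__ = [
    "Trajectory",
    "ObservableMap",
    "IntegrationError",
    "ProjectionError",
    "initial_state",
    "integrate",
    "sample_ssa",
    "project_observable",
]


class IntegrationError(RuntimeError):
    """Stiff-solver failure; carries the failing time in ``.t_fail``."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class ProjectionError(KeyError):
    """Observable map does not cover a species present in the trajectory."""


def initial_state(**conc: float) -> dict:
    """Build a species->concentration dict, validating names and signs."""
    for sp, v in conc.items():
        if sp not in SPECIES:
            raise KeyError(f"unknown species {sp!r}")
        if v < 0:
            raise ValueError(f"negative concentration for {sp}: {v}")
    return {sp: float(conc.get(sp, 0.0)) for sp in SPECIES}


def _state_vector(init: dict) -> np.ndarray:
    full = initial_state(**init)
    return np.array([full[sp] for sp in SPECIES])


@dataclass
class Trajectory:
    """Time grid x species-state matrix with provenance."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_species)
    species: list = field(default_factory=lambda: list(SPECIES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.t), len(self.species)):
            raise ValueError("state matrix shape does not match time grid / species")

    def conc(self, species: str) -> np.ndarray:
        return self.y[:, self.species.index(species)]

    def total_para2(self) -> np.ndarray:
        """Total ParA2 dimer concentration at every time point (conserved)."""
        idx = [self.species.index(s) for s in PARA2_SPECIES]
        return self.y[:, idx].sum(axis=1)

    def total_nucleotide(self) -> np.ndarray:
        """Total adenine nucleotide, free + bound, labelled + unlabelled."""
        out = np.zeros(len(self.t))
        for sp, n in NUCLEOTIDE_CONTENT.items():
            out += n * self.conc(sp)
        return out

    def adp_equivalents(self) -> np.ndarray:
        out = np.zeros(len(self.t))
        for sp, n in ADP_CONTENT.items():
            out += n * self.conc(sp)
        return out

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.y, columns=self.species)
        df.insert(0, "time_s", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate(
    scheme: ReactionScheme,
    init: dict,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Mass-action ODE solution of the scheme on ``t_grid``.

    Uses LSODA (adaptive, switches to BDF on stiffness).  Conservation of
    total ParA2 holds to the relative integration tolerance.  The time grid
    must start at 0 and be strictly increasing.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    y0 = _state_vector(init)
    if len(t_grid) == 1 or len(scheme) == 0:
        y = np.tile(y0, (len(t_grid), 1))
        return Trajectory(t_grid, y, provenance={"engine": "ode", "rates": scheme.rates.to_dict()})
    sol = solve_ivp(
        scheme.rhs,
        (0.0, float(t_grid[-1])),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationError(f"ODE integration failed at t={t_fail:g}s: {sol.message}", t_fail)
    y = np.clip(sol.y.T, 0.0, None)  # clip solver noise below zero
    return Trajectory(
        t_grid,
        y,
        provenance={
            "engine": "ode",
            "rates": scheme.rates.to_dict(),
            "condition": vars(scheme.condition) if hasattr(scheme.condition, "__dict__") else str(scheme.condition),
            "init": dict(init),
            "rtol": rtol,
            "atol": atol,
        },
    )


def sample_ssa(
    scheme: ReactionScheme,
    init_copies: dict,
    t_end: float,
    seed: int,
    volume_factor: float = 100.0,
    n_record: int = 201,
) -> Trajectory:
    """Exact stochastic (Gillespie direct-method) trajectory.

    ``init_copies`` are integer copy numbers; ``volume_factor`` is the
    number of copies corresponding to 1 uM, converting second-order
    uM-rates to propensities (k2nd * n_i * n_j / volume_factor).  The
    returned trajectory is recorded on a uniform grid of ``n_record``
    points and reported in uM so observables project identically to the
    ODE engine.  Reproducible given ``seed``; if the total propensity
    reaches zero before ``t_end`` the state is frozen and the trajectory
    is flagged ``exhausted`` in its provenance.
    """
    rng = np.random.default_rng(seed)
    n = np.zeros(len(SPECIES), dtype=np.int64)
    for sp, c in init_copies.items():
        if sp not in SPECIES:
            raise KeyError(f"unknown species {sp!r}")
        if c < 0 or int(c) != c:
            raise ValueError(f"copy numbers must be non-negative integers ({sp}={c})")
        n[SPECIES.index(sp)] = int(c)

    reactions = scheme.reactions
    k = np.array([r.rate for r in reactions])
    # propensity order and stoichiometry index lists
    order_idx = []
    for r in reactions:
        order_idx.append([(SPECIES.index(sp), int(e)) for sp, e in r.rate_law.items()])
    stoich = scheme.stoich.astype(np.int64)
    react_stoich = [[(SPECIES.index(sp), int(nu)) for sp, nu in r.reactants.items()] for r in reactions]
    coop = np.array([r.modifier == "coop" for r in reactions])
    i_B, i_BM, i_sites = SPECIES.index("B"), SPECIES.index("B_M"), SPECIES.index("sites")
    omega = scheme.rates.coop_omega

    t_grid = np.linspace(0.0, t_end, n_record)
    out = np.zeros((n_record, len(SPECIES)), dtype=np.int64)
    rec = 0
    t = 0.0
    exhausted = False

    def propensities() -> np.ndarray:
        a = k.copy()
        for j, terms in enumerate(order_idx):
            second = 0
            for i, e in terms:
                a[j] *= float(n[i]) ** e
                second += e
            if second >= 2:  # one volume factor per extra reactant
                a[j] /= volume_factor ** (second - 1)
            # zero out if stoichiometry cannot be satisfied
            for i, nu in react_stoich[j]:
                if n[i] < nu:
                    a[j] = 0.0
                    break
        if coop.any():
            bound = n[i_B] + n[i_BM]
            tot = bound + n[i_sites]
            theta = bound / tot if tot > 0 else 0.0
            a[coop] *= 1.0 + (omega - 1.0) * theta
        return a

    while t < t_end:
        a = propensities()
        a0 = a.sum()
        if a0 <= 0:
            exhausted = True
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        while rec < n_record and t_grid[rec] < t:
            out[rec] = n
            rec += 1
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0, a0)))
        n += stoich[j]
    while rec < n_record:
        out[rec] = n
        rec += 1

    return Trajectory(
        t_grid,
        out.astype(float) / volume_factor,
        provenance={
            "engine": "ssa",
            "seed": int(seed),
            "volume_factor": volume_factor,
            "exhausted": exhausted,
            "rates": scheme.rates.to_dict(),
        },
    )


@dataclass(frozen=True)
class ObservableMap:
    """Linear map from species concentrations to an instrument signal.

    signal(t) = baseline + sum_s coeff[s] * conc_s(t).  Every species that
    is actually populated in the trajectory must appear in ``coeffs`` —
    silently treating a missing species as zero is not allowed.
    """

    coeffs: dict
    baseline: float = 0.0

    def __post_init__(self):
        for sp, c in self.coeffs.items():
            if sp not in SPECIES:
                raise ProjectionError(f"unknown species {sp!r} in observable map")
            if not np.isfinite(c):
                raise ValueError(f"non-finite coefficient for {sp}")
        if not np.isfinite(self.baseline):
            raise ValueError("non-finite baseline")


def project_observable(traj: Trajectory, omap: ObservableMap, assay: str = "observable") -> Trace:
    """Project a trajectory onto a linear observable."""
    populated = [sp for i, sp in enumerate(traj.species) if np.any(traj.y[:, i] > 0)]
    missing = [sp for sp in populated if sp not in omap.coeffs]
    if missing:
        raise ProjectionError(f"observable map missing populated species: {missing}")
    signal = np.full(len(traj.t), omap.baseline)
    for sp, c in omap.coeffs.items():
        signal = signal + c * traj.conc(sp)
    return Trace(assay=assay, x=traj.t, y=signal, meta={"baseline": omap.baseline})
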