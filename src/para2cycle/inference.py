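"""Fitting procedures for the assay readouts.

Every rate constant and affinity the package deals in is the output of one
of these operations applied to a :class:`~para2cycle.trace.Trace`:
single-exponential association/dissociation (kobs), two-phase decay,
pseudo-first-order analysis (kon, koff, KD from a kobs-vs-concentration
line), cooperative Hill and hyperbolic binding isotherms, double-
exponential FRAP recovery, and two-state Boltzmann thermal melts.

Nonlinear fits use trust-region least squares (lmfit) with multi-start
from five log-spaced rate guesses; model selection between single- and
two-phase decays uses AICc with a threshold of 2.  All fitters are
invariant to uniform y-scaling: rates and time constants are unchanged,
amplitudes scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .trace import Trace

__all__ = [
    "FitResult",
    "fit_single_exponential",
    "fit_two_phase_decay",
    "pseudo_first_order",
    "fit_hill",
    "fit_hyperbolic_kd",
    "fit_frap",
    "fit_melt",
    "detect_lag",
]

#: convergence tolerance on the sum of squares
_SSE_TOL = 1e-10


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and diagnostics.

    ``params`` carries named estimates (kobs /s, kon /uM/s, koff /s, KD in
    the assay's printed unit, n, tau_fast_s/tau_slow_s, fractions, Tm_C...).
    Whenever both kon and koff are present, ``params['kd']`` is their ratio
    (the consistency field).  ``window`` is the x-range actually fitted.
    """

    model: str
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    rss: float = np.inf
    converged: bool = False
    flags: list = field(default_factory=list)
    window: tuple | None = None
    n_points: int = 0

    def __post_init__(self):
        if "kon" in self.params and "koff" in self.params and "kd" not in self.params:
            kon = self.params["kon"]
            self.params["kd"] = self.params["koff"] / kon if kon > 0 else np.nan
        # a converged fit carries finite estimates; NaN is only allowed when
        # a flag documents why (e.g. KD undefined after a negative intercept)
        if self.converged and not self.flags and any(
            not np.isfinite(v) for v in self.params.values() if v is not None
        ):
            raise ValueError("converged fit must carry finite estimates")

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "flags": self.flags,
            "window": list(self.window) if self.window else None,
            "n_points": self.n_points,
        }

    def to_json(self, path: str | Path) -> None:
        from .io import write_json

        write_json(path, self.to_dict())


def _aicc(rss: float, n: int, p: int, scale: float = 1.0) -> float:
    # floor at numerical precision of the signal so that exact fits do not
    # reward extra parameters with meaningless 1e-20-level RSS gains
    rss = max(rss, n * (1e-8 * max(scale, 1e-30)) ** 2)
    if n - p - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _multistart(residual, build_params, k_guesses) -> object | None:
    """Run trust-region least squares from several rate guesses, keep the
    lowest SSE (ties broken by fewer varying parameters)."""
    import warnings as _warnings

    best = None
    for g in k_guesses:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                out = minimize(residual, build_params(g), method="least_squares", xtol=_SSE_TOL, ftol=_SSE_TOL)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr - _SSE_TOL * (1 + best.chisqr):
            best = out
    return best


def detect_lag(x: np.ndarray, y: np.ndarray, threshold: float = 0.2) -> float:
    """Start of the rising/falling phase for lag exclusion.

    The fit start is the first time the smoothed derivative exceeds
    ``threshold`` (20%) of its maximum magnitude.
    """
    n = len(x)
    w = max(3, n // 50)
    kernel = np.ones(w)
    # normalized smoothing (no zero-padding cliff at the edges)
    ys = np.convolve(y, kernel, mode="same") / np.convolve(np.ones(n), kernel, mode="same")
    dy = np.abs(np.gradient(ys, x))
    peak = dy.max()
    if peak <= 0:
        return float(x[0])
    idx = int(np.argmax(dy >= threshold * peak))
    return float(x[idx])


def _stderr_dict(out, names: dict) -> dict:
    errs = {}
    for pname, label in names.items():
        par = out.params.get(pname)
        errs[label] = float(par.stderr) if par is not None and par.stderr else np.nan
    return errs


def fit_single_exponential(
    trace: Trace, direction: str = "rise", exclude_lag: bool = False
) -> FitResult:
    """Observed-rate fit: y = y0 + A(1 - e^(-kobs t)) or y0 + A e^(-kobs t).

    Requires >= 20 points.  With ``exclude_lag`` the initial lag window is
    detected from the smoothed derivative and excluded; the fitted window
    is always reported.  An amplitude indistinguishable from zero
    (|A| < 3 sigma of the residuals) returns not-converged with a
    "flat trace" flag.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    x, y = trace.x, trace.y
    if len(x) < 20:
        raise ValueError("need at least 20 points for a rate fit")
    x0 = detect_lag(x, y) if exclude_lag else float(x[0])
    mask = x >= x0
    xw, yw = x[mask] - x0, y[mask]
    span = max(xw[-1], 1e-12)
    scale = float(np.ptp(yw)) or 1.0

    def build(k0):
        p = Parameters()
        p.add("y0", value=float(yw[0]))
        amp = float(yw[-1] - yw[0]) if direction == "rise" else float(yw[0] - yw[-1])
        p.add("A", value=amp if amp != 0 else scale)
        p.add("kobs", value=k0, min=0.0)
        return p

    def model(p):
        if direction == "rise":
            return p["y0"] + p["A"] * (1 - np.exp(-p["kobs"] * xw))
        return p["y0"] + p["A"] * np.exp(-p["kobs"] * xw)

    out = _multistart(lambda p: model(p) - yw, build, np.geomspace(0.3, 300, 5) / span)
    flags = []
    if out is None:
        return FitResult("single_exponential", converged=False, flags=["optimizer failed"], n_points=len(xw))
    resid_sd = float(np.std(model(out.params) - yw))
    a_hat = float(out.params["A"].value)
    if np.ptp(yw) == 0 or abs(a_hat) < max(3 * resid_sd, 1e-12):
        return FitResult(
            "single_exponential",
            params={"kobs": np.nan, "amplitude": a_hat, "y0": float(out.params["y0"].value)},
            converged=False,
            flags=["flat trace"],
            window=(x0, float(x[-1])),
            n_points=len(xw),
        )
    return FitResult(
        "single_exponential",
        params={
            "kobs": float(out.params["kobs"].value),
            "amplitude": a_hat,
            "y0": float(out.params["y0"].value),
        },
        stderr=_stderr_dict(out, {"kobs": "kobs", "A": "amplitude"}),
        rss=float(out.chisqr),
        converged=True,
        flags=flags,
        window=(x0, float(x[-1])),
        n_points=len(xw),
    )


def fit_two_phase_decay(trace: Trace) -> FitResult:
    """Two-phase decay y = y0 + A1 e^(-k_fast t) + A2 e^(-k_slow t).

    Constrained to k_fast > k_slow and non-negative amplitudes; needs
    >= 40 points.  If AICc prefers a single exponential (threshold 2) the
    single-phase result is returned flagged "collapsed".
    """
    x, y = trace.x, trace.y
    if len(x) < 40:
        raise ValueError("need at least 40 points for a two-phase fit")
    xw = x - x[0]
    span = max(xw[-1], 1e-12)
    amp = float(y[0] - y[-1])
    scale = abs(amp) or float(np.ptp(y)) or 1.0

    def build(k0):
        p = Parameters()
        p.add("y0", value=float(y[-1]))
        p.add("A1", value=0.5 * scale, min=0.0)
        p.add("A2", value=0.5 * scale, min=0.0)
        p.add("k_slow", value=k0, min=0.0)
        p.add("dk", value=9 * k0, min=1e-12)  # k_fast = k_slow + dk > k_slow
        return p

    def model(p):
        kf = p["k_slow"] + p["dk"]
        return p["y0"] + p["A1"] * np.exp(-kf * xw) + p["A2"] * np.exp(-p["k_slow"] * xw)

    out = _multistart(lambda p: model(p) - y, build, np.geomspace(0.3, 100, 5) / span)
    single = fit_single_exponential(trace, direction="decay")
    if out is None:
        single.flags.append("collapsed")
        return single
    n = len(x)
    yscale = float(np.ptp(y))
    aicc_two = _aicc(float(out.chisqr), n, 5, yscale)
    aicc_one = _aicc(single.rss, n, 3, yscale) if single.converged else np.inf
    if aicc_one <= aicc_two + 2.0:
        single.flags.append("collapsed")
        return single
    k_slow = float(out.params["k_slow"].value)
    k_fast = k_slow + float(out.params["dk"].value)
    return FitResult(
        "two_phase_decay",
        params={
            "k_fast": k_fast,
            "k_slow": k_slow,
            "amplitude_fast": float(out.params["A1"].value),
            "amplitude_slow": float(out.params["A2"].value),
            "y0": float(out.params["y0"].value),
        },
        stderr=_stderr_dict(out, {"k_slow": "k_slow", "A1": "amplitude_fast", "A2": "amplitude_slow"}),
        rss=float(out.chisqr),
        converged=True,
        window=(float(x[0]), float(x[-1])),
        n_points=n,
    )


def pseudo_first_order(kobs_points) -> FitResult:
    """kon and koff from the kobs-vs-substrate line.

    ``kobs_points`` is a sequence of (substrate uM, kobs /s) pairs from
    excess-substrate binding (or exchange) series.  Ordinary least squares:
    kon is the slope, koff the y-intercept, KD = koff/kon with propagated
    standard error.  A negative fitted intercept is reported as koff = 0
    with a warning flag (KD undefined).
    """
    pts = np.asarray(list(kobs_points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (concentration, kobs) pairs")
    if len(pts) < 3:
        flags = ["fewer than 3 concentrations"]
    else:
        flags = []
    res = stats.linregress(pts[:, 0], pts[:, 1])
    kon, koff = float(res.slope), float(res.intercept)
    params: dict = {"kon": kon}
    stderr = {"kon": float(res.stderr) if np.isfinite(res.stderr) else np.nan,
              "koff": float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else np.nan}
    if koff < 0:
        params["koff"] = 0.0
        params["kd"] = np.nan
        flags.append("negative intercept; koff set to 0, KD undefined")
    else:
        params["koff"] = koff
        params["kd"] = koff / kon if kon > 0 else np.nan
        if kon > 0 and koff > 0 and np.isfinite(stderr["kon"]) and np.isfinite(stderr["koff"]):
            rel = np.hypot(stderr["kon"] / kon, stderr["koff"] / koff)
            stderr["kd"] = params["kd"] * rel
    fitted = kon * pts[:, 0] + koff
    return FitResult(
        "pseudo_first_order",
        params=params,
        stderr=stderr,
        rss=float(np.sum((fitted - pts[:, 1]) ** 2)),
        converged=np.isfinite(kon),
        flags=flags,
        window=(float(pts[:, 0].min()), float(pts[:, 0].max())),
        n_points=len(pts),
    )


def _titration_fit(trace: Trace, hill: bool, fix_n: bool = False) -> FitResult:
    c, f = trace.x, trace.y
    kd_guesses = np.geomspace(max(c.min(), 1e-6), c.max(), 5)
    fmax = float(f.max()) or 1.0
    flags = []

    def build(kd0):
        p = Parameters()
        p.add("kd", value=kd0, min=1e-9)
        if hill:
            # gel-shift fraction bound saturates at 1 by definition
            p.add("plateau", value=min(fmax, 1.0), min=1e-6, max=1.0)
            p.add("n", value=1.0 if fix_n else 2.0, min=1.0, max=12.0, vary=not fix_n)
        else:
            # generic isotherm: ymax is in arbitrary signal units
            p.add("plateau", value=fmax, min=1e-6)
        return p

    def model(p):
        kd = p["kd"]
        if hill:
            nn = p["n"]
            return p["plateau"] * c**nn / (kd**nn + c**nn)
        return p["plateau"] * c / (kd + c)

    out = _multistart(lambda p: model(p) - f, build, kd_guesses)
    name = "hill" if hill else "hyperbolic"
    if out is None:
        return FitResult(name, converged=False, flags=["optimizer failed"], n_points=len(c))
    plateau = float(out.params["plateau"].value)
    # identifiability diagnostics
    if hill and not fix_n and fmax < 0.8 * plateau:
        refit = _titration_fit(trace, hill=True, fix_n=True)
        refit.flags.append("n fixed to 1: no point above 80% of plateau")
        return refit
    if not hill and float(f.min()) > 0.8 * fmax:
        flags.append("saturated titration: KD unidentifiable")
    if plateau >= 0.999 and fmax < 0.6:
        flags.append("plateau unidentifiable; fixed near max(f)")
    params = {"kd": float(out.params["kd"].value), "plateau": plateau}
    if hill:
        params["n"] = float(out.params["n"].value)
    labels = {"kd": "kd", "plateau": "plateau"}
    if hill:
        labels["n"] = "n"
    return FitResult(
        name,
        params=params,
        stderr=_stderr_dict(out, labels),
        rss=float(out.chisqr),
        converged=True,
        flags=flags,
        window=(float(c.min()), float(c.max())),
        n_points=len(c),
    )


def fit_hill(titration: Trace) -> FitResult:
    """Cooperative binding fit f = plateau c^n / (KD^n + c^n).

    Needs >= 6 concentrations.  KD is reported in the titration's x unit
    (nM for the gel-shift DNA titrations).  When no point reaches 80% of
    the fitted plateau the Hill coefficient is fixed to 1 and flagged.
    """
    if len(titration.x) < 6:
        raise ValueError("need at least 6 titration points")
    return _titration_fit(titration, hill=True)


def fit_hyperbolic_kd(titration: Trace) -> FitResult:
    """Non-cooperative isotherm y = ymax c / (KD + c) (steady-state
    nucleotide binding); equals the Hill fit with n fixed to 1."""
    if len(titration.x) < 5:
        raise ValueError("need at least 5 titration points")
    return _titration_fit(titration, hill=False)


def fit_frap(curve: Trace) -> FitResult:
    """Double-exponential FRAP recovery.

    y(t) = (1 - immobile) - f_fast e^(-t/tau_fast) - f_slow e^(-t/tau_slow)
    with the asymptote 1 - immobile.  Returns tau_fast_s, tau_slow_s, the
    mobile fractions and the immobile fraction.  A flat (fully immobile)
    curve is flagged with unidentifiable time constants.
    """
    t, y = curve.x, curve.y
    if len(t) < 40:
        raise ValueError("need at least 40 points for a FRAP fit")
    if float(np.ptp(y)) < 1e-3:
        return FitResult(
            "frap",
            params={"fraction_immobile": 1.0 - float(np.mean(y)),
                    "tau_fast_s": np.nan, "tau_slow_s": np.nan,
                    "fraction_fast": 0.0, "fraction_slow": 0.0},
            converged=False,
            flags=["flat recovery: time constants unidentifiable"],
            n_points=len(t),
        )
    span = max(float(t[-1] - t[0]), 1e-12)

    def build(k0):
        p = Parameters()
        p.add("asym", value=float(y[-1]), min=0.0, max=1.0)
        p.add("f_fast", value=0.5 * float(y[-1]), min=0.0, max=1.0)
        p.add("f_slow", value=0.25 * float(y[-1]), min=0.0, max=1.0)
        p.add("tau_fast", value=1.0 / k0, min=1e-6)
        p.add("tau_ratio", value=30.0, min=1.0 + 1e-9)  # tau_slow = ratio * tau_fast
        return p

    def model(p):
        tau_s = p["tau_fast"] * p["tau_ratio"]
        return (
            p["asym"]
            - p["f_fast"] * np.exp(-t / p["tau_fast"])
            - p["f_slow"] * np.exp(-t / tau_s)
        )

    out = _multistart(lambda p: model(p) - y, build, np.geomspace(1, 1000, 5) / span)
    if out is None:
        return FitResult("frap", converged=False, flags=["optimizer failed"], n_points=len(t))
    tau_fast = float(out.params["tau_fast"].value)
    tau_slow = tau_fast * float(out.params["tau_ratio"].value)
    asym = float(out.params["asym"].value)
    return FitResult(
        "frap",
        params={
            "tau_fast_s": tau_fast,
            "tau_slow_s": tau_slow,
            "fraction_fast": float(out.params["f_fast"].value),
            "fraction_slow": float(out.params["f_slow"].value),
            "fraction_immobile": 1.0 - asym,
        },
        stderr=_stderr_dict(out, {"tau_fast": "tau_fast_s", "f_fast": "fraction_fast", "f_slow": "fraction_slow"}),
        rss=float(out.chisqr),
        converged=True,
        window=(float(t[0]), float(t[-1])),
        n_points=len(t),
    )


def fit_melt(curve: Trace) -> FitResult:
    """Two-state Boltzmann melt: theta(T) between folded and unfolded
    baselines with midpoint Tm and transition width (the cooperativity
    slope).  A flat trace is flagged unidentifiable."""
    T, y = curve.x, curve.y
    if len(T) < 8:
        raise ValueError("need at least 8 temperature points")
    if float(np.ptp(y)) < 1e-9:
        return FitResult(
            "melt",
            params={"tm_C": np.nan, "slope_C": np.nan},
            converged=False,
            flags=["flat melt: Tm unidentifiable"],
            n_points=len(T),
        )

    def build(width):
        p = Parameters()
        p.add("theta_f", value=float(y[0]))
        p.add("theta_u", value=float(y[-1]))
        mid = 0.5 * (y[0] + y[-1])
        tm0 = float(T[np.argmin(np.abs(y - mid))])
        p.add("tm", value=tm0, min=float(T[0]) - 20, max=float(T[-1]) + 20)
        p.add("slope", value=1.0 / width, min=1e-3)
        return p

    def model(p):
        frac = 1.0 / (1.0 + np.exp((p["tm"] - T) / p["slope"]))
        return p["theta_f"] + (p["theta_u"] - p["theta_f"]) * frac

    out = _multistart(lambda p: model(p) - y, build, np.geomspace(0.05, 2.0, 5))
    if out is None:
        return FitResult("melt", converged=False, flags=["optimizer failed"], n_points=len(T))
    return FitResult(
        "melt",
        params={
            "tm_C": float(out.params["tm"].value),
            "slope_C": float(out.params["slope"].value),
            "theta_folded": float(out.params["theta_f"].value),
            "theta_unfolded": float(out.params["theta_u"].value),
        },
        stderr=_stderr_dict(out, {"tm": "tm_C", "slope": "slope_C"}),
        rss=float(out.chisqr),
        converged=True,
        window=(float(T[0]), float(T[-1])),
        n_points=len(T),
    )
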