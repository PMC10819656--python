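"""Delayed-exponential VO2 kinetics: models, fitting, bootstrap, integrals.

The on-transient is modelled as a baseline plus one (mono) or two (bi)
delayed exponentials gated by the Heaviside step H (H(x)=1 for x>=0):

    VO2(t) = A0 + H(t-TDp)*Ap*(1 - exp(-(t-TDp)/tau_p))
                [+ H(t-TDsc)*Asc*(1 - exp(-(t-TDsc)/tau_sc))]

and the off-transient (recovery / excess post-exercise VO2) as the same
components subtracted from the end-exercise level A0.  VO2 here is
mass-normalized (mL·kg⁻¹·min⁻¹); time is phase-relative seconds.

Fitting is nonlinear least squares (scipy's trust-region reflective)
with heuristic initialization and jittered restarts; uncertainty comes
from a residual-resampling bootstrap with percentile confidence
intervals, which preserves the single transient's time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .gasio import BreathSeries, slice_phase

__all__ = [
    "KineticsParams",
    "KineticsFit",
    "model_value",
    "fit_vo2_curve",
    "fit_transient",
    "bootstrap_fit",
    "accumulated_vo2",
    "epoc",
]

_TAU_BOUNDS = (0.1, 120.0)
_TD_BOUNDS = (0.0, 30.0)


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the delayed-exponential VO2 model.

    a0 : baseline (on) or end-exercise (off) VO2, mL·kg⁻¹·min⁻¹
    ap, tdp, tau_p : primary-component amplitude, time delay, time constant
    asc, tdsc, tau_sc : optional slow/second component
    direction : "on" (rise above a0) or "off" (decay below a0)
    """

    a0: float
    ap: float
    tdp: float
    tau_p: float
    asc: float | None = None
    tdsc: float | None = None
    tau_sc: float | None = None
    direction: str = "on"

    def __post_init__(self) -> None:
        if self.direction not in ("on", "off"):
            raise ValueError("direction must be 'on' or 'off'")
        if self.tau_p <= 0 or self.tdp < 0 or self.ap < 0:
            raise ValueError("require tau_p > 0, tdp >= 0, ap >= 0")
        slow = (self.asc, self.tdsc, self.tau_sc)
        if any(v is not None for v in slow):
            if any(v is None for v in slow):
                raise ValueError("slow component requires asc, tdsc and tau_sc")
            if self.tau_sc <= 0 or self.tdsc < self.tdp:
                raise ValueError("require tau_sc > 0 and tdsc >= tdp")

    @property
    def has_slow(self) -> bool:
        return self.asc is not None

    def to_dict(self) -> dict:
        d = {"a0": self.a0, "ap": self.ap, "tdp": self.tdp,
             "tau_p": self.tau_p, "direction": self.direction}
        if self.has_slow:
            d.update(asc=self.asc, tdsc=self.tdsc, tau_sc=self.tau_sc)
        return d

    @classmethod
    def from_dict(cls, d) -> "KineticsParams":
        return cls(**d)


def _component(t: np.ndarray, amp: float, td: float, tau: float) -> np.ndarray:
    u = t - td
    return np.where(u >= 0, amp * -np.expm1(-np.clip(u, 0, None) / tau), 0.0)


def model_value(t, params: KineticsParams):
    """Evaluate the kinetics model at time(s) ``t`` (phase-relative s)."""
    t = np.asarray(t, float)
    y = _component(t, params.ap, params.tdp, params.tau_p)
    if params.has_slow:
        y = y + _component(t, params.asc, params.tdsc, params.tau_sc)
    out = params.a0 + y if params.direction == "on" else params.a0 - y
    return out if out.ndim else float(out)


@dataclass
class KineticsFit:
    """A fitted transient: point estimates, residuals, bootstrap CIs."""

    params: KineticsParams
    rss: float
    n_points: int
    residuals: np.ndarray
    t: np.ndarray
    y: np.ndarray
    converged: bool
    model: str = "mono"
    diagnostics: dict = field(default_factory=dict)
    bootstrap: dict[str, np.ndarray] | None = None
    ci95: dict[str, tuple[float, float]] | None = None

    @property
    def fitted(self) -> np.ndarray:
        return model_value(self.t, self.params)

    def summary(self) -> dict:
        out = {"params": self.params.to_dict(), "rss": self.rss,
               "n_points": self.n_points, "converged": self.converged,
               "model": self.model}
        if self.ci95 is not None:
            out["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        return out


_PARAM_NAMES = {
    "mono": ("a0", "ap", "tdp", "tau_p"),
    "bi": ("a0", "ap", "tdp", "tau_p", "asc", "dtd_sc", "tau_sc"),
}


def _vec_to_params(x: np.ndarray, model: str, direction: str) -> KineticsParams:
    if model == "mono":
        a0, ap, tdp, tau_p = x
        return KineticsParams(a0, ap, tdp, tau_p, direction=direction)
    a0, ap, tdp, tau_p, asc, dtd, tau_sc = x
    # the second delay is parameterized as tdp + dtd so tdsc >= tdp by bounds
    return KineticsParams(a0, ap, tdp, tau_p, asc=asc, tdsc=tdp + dtd,
                          tau_sc=tau_sc, direction=direction)


def _initial_guess(t: np.ndarray, y: np.ndarray, direction: str) -> np.ndarray:
    """Heuristic start: a0 from the early points, amplitude from the last
    30 s, TD at 10% of the amplitude, tau at 63% minus TD."""
    n_early = max(3, int(0.05 * len(t)))
    early = float(np.mean(np.sort(y)[:n_early])) if direction == "on" \
        else float(np.mean(np.sort(y)[-n_early:]))
    late = float(np.mean(y[t >= t[-1] - 30.0]))
    amp = abs(late - early)
    if amp < 1e-6:
        amp = max(float(np.ptp(y)), 1e-3)
    target10 = early + 0.1 * amp if direction == "on" else early - 0.1 * amp
    target63 = early + 0.63 * amp if direction == "on" else early - 0.63 * amp
    cmp = np.greater_equal if direction == "on" else np.less_equal
    hit10 = np.flatnonzero(cmp(y, target10))
    hit63 = np.flatnonzero(cmp(y, target63))
    td = float(t[hit10[0]]) if len(hit10) else 0.0
    td = float(np.clip(td, *_TD_BOUNDS))
    t63 = float(t[hit63[0]]) if len(hit63) else td + 20.0
    tau = float(np.clip(t63 - td, 1.0, _TAU_BOUNDS[1]))
    return np.array([max(early, 0.0), amp, td, tau])


def fit_vo2_curve(t, y, direction: str = "on", model: str = "mono",
                  max_restarts: int = 5) -> KineticsFit:
    """Nonlinear least-squares fit of the kinetics model to (t, y).

    ``t`` is phase-relative time (s), ``y`` mass-normalized VO2
    (mL·kg⁻¹·min⁻¹).  Deterministic for identical input: the jittered
    restarts draw from a fixed-seed generator.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if model not in _PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    n_par = len(_PARAM_NAMES[model])
    if len(t) < n_par:
        raise ValueError(f"{len(t)} points cannot constrain {n_par} parameters")

    x0m = _initial_guess(t, y, direction)
    ymax = max(float(np.max(np.abs(y))) * 2.0, 10.0)
    if model == "mono":
        x0 = x0m
        lo = np.array([0.0, 0.0, _TD_BOUNDS[0], _TAU_BOUNDS[0]])
        hi = np.array([ymax, 2 * ymax, _TD_BOUNDS[1], _TAU_BOUNDS[1]])
    else:
        x0 = np.r_[x0m * [1, 0.9, 1, 1], 0.1 * x0m[1], 30.0, 60.0]
        lo = np.array([0.0, 0.0, _TD_BOUNDS[0], _TAU_BOUNDS[0],
                       0.0, 0.0, _TAU_BOUNDS[0]])
        hi = np.array([ymax, 2 * ymax, _TD_BOUNDS[1], _TAU_BOUNDS[1],
                       2 * ymax, 240.0, 300.0])
    x0 = np.clip(x0, lo, hi)

    def resid(x):
        return model_value(t, _vec_to_params(x, model, direction)) - y

    rng = np.random.default_rng(12345)  # fixed: restarts are deterministic
    best, n_tries = None, 0
    start = x0
    for attempt in range(max_restarts + 1):
        n_tries += 1
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer failure path
            sol = None
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.status > 0:
            break
        jitter = rng.uniform(0.7, 1.3, size=len(x0))
        start = np.clip(x0 * jitter + rng.uniform(0, 1, len(x0)), lo, hi)

    if best is None:
        raise RuntimeError("optimizer failed on every restart")
    params = _vec_to_params(best.x, model, direction)
    res = resid(best.x)
    return KineticsFit(params=params, rss=float(res @ res), n_points=len(t),
                       residuals=res, t=t, y=y,
                       converged=bool(best.status > 0), model=model,
                       diagnostics={"n_starts": n_tries,
                                    "optimizer_status": int(best.status)})


def fit_transient(series: BreathSeries, phase: str = "exercise",
                  model: str = "mono", exclude_s: float = 20.0,
                  direction: str | None = None) -> KineticsFit:
    """Fit the on- or off-transient of a session's phase.

    The phase slice is re-zeroed to its onset, VO2 is mass-normalized,
    and points with t < ``exclude_s`` (the cardiodynamic window) are
    omitted.  Direction defaults to "on" for exercise and "off" for
    recovery.  Note: with a short time delay and fast time constant
    (as in brief maximal efforts) a 20 s exclusion removes most of the
    rise — pass ``exclude_s=0`` to model the full transient.
    """
    if direction is None:
        direction = "on" if phase == "exercise" else "off"
    sub = slice_phase(series, phase, rezero=True)
    t = sub.times
    y = sub.channel("vo2") / series.body_mass
    keep = t >= exclude_s
    t, y = t[keep], y[keep]
    if len(t) < 5:
        raise ValueError("need at least 5 usable points after the "
                         "cardiodynamic exclusion")
    # refit on time since the start of the retained window keeps TD
    # interpretable relative to phase onset only when exclude_s == 0;
    # keep absolute phase time so TD stays phase-anchored.
    return fit_vo2_curve(t, y, direction=direction, model=model)


def bootstrap_fit(fit: KineticsFit, b: int = 1000,
                  seed: int | None = None) -> KineticsFit:
    """Residual-resampling bootstrap of a converged fit.

    Builds ``b`` synthetic datasets as fitted curve + residuals
    resampled with replacement, refits each (warm-started at the point
    estimate), and stores per-parameter empirical distributions and
    percentile 95% CIs.  Resampled residuals are inflated by
    sqrt(n/(n-p)) because least-squares residuals underestimate the
    error scale by the degrees of freedom the model absorbed.
    Reproducible for a fixed seed.  If more than 20% of refits fail to
    converge a warning is recorded in the diagnostics.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged base fit")
    rng = np.random.default_rng(seed)
    yhat = fit.fitted
    n_par = len(_PARAM_NAMES[fit.model])
    res = fit.residuals * np.sqrt(max(fit.n_points, n_par + 1)
                                  / (max(fit.n_points, n_par + 1) - n_par))
    names = _PARAM_NAMES[fit.model]
    x_hat = _params_to_vec(fit.params, fit.model)
    lo = np.minimum(x_hat, 0.0)
    hi = np.maximum(np.abs(x_hat) * 10 + 10.0, 1.0)
    lo_b = np.where(np.isin(np.array(names), ["tau_p", "tau_sc"]),
                    _TAU_BOUNDS[0], lo)

    draws = np.empty((b, len(names)))
    n_bad = 0
    for i in range(b):
        yb = yhat + rng.choice(res, size=len(res), replace=True)

        def resid(x):
            return model_value(fit.t, _vec_to_params(x, fit.model,
                                                     fit.params.direction)) - yb

        sol = least_squares(resid, x_hat, bounds=(lo_b, hi), method="trf",
                            ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=500)
        if sol.status <= 0:
            n_bad += 1
        draws[i] = sol.x

    boot = {name: draws[:, j] for j, name in enumerate(names)}
    ci95 = {name: (float(np.percentile(col, 2.5)),
                   float(np.percentile(col, 97.5)))
            for name, col in boot.items()}
    diagnostics = dict(fit.diagnostics)
    diagnostics["bootstrap_b"] = b
    diagnostics["bootstrap_nonconverged"] = n_bad
    if n_bad > 0.2 * b:
        diagnostics["bootstrap_warning"] = (
            f"{n_bad}/{b} bootstrap refits did not converge")
        warnings.warn(diagnostics["bootstrap_warning"])
    return replace(fit, bootstrap=boot, ci95=ci95, diagnostics=diagnostics)


def _params_to_vec(p: KineticsParams, model: str) -> np.ndarray:
    if model == "mono":
        return np.array([p.a0, p.ap, p.tdp, p.tau_p])
    return np.array([p.a0, p.ap, p.tdp, p.tau_p,
                     p.asc, p.tdsc - p.tdp, p.tau_sc])


# ---------------------------------------------------------------------------
# oxygen integrals
# ---------------------------------------------------------------------------

def _net_integral(t_s: np.ndarray, rate_l_min: np.ndarray,
                  baseline_rate_l_min: float,
                  span: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral (L) of the above-baseline VO2 rate.

    With ``span`` the integral covers the full window: the first/last
    sampled values are held constant out to the span edges, so a
    constant net rate integrates to rate x full duration.
    """
    net = np.clip(rate_l_min - baseline_rate_l_min, 0.0, None)
    if span is not None and len(t_s):
        lo, hi = span
        if t_s[0] > lo:
            t_s = np.r_[lo, t_s]
            net = np.r_[net[0], net]
        if t_s[-1] < hi:
            t_s = np.r_[t_s, hi]
            net = np.r_[net, net[-1]]
    return float(np.trapezoid(net, np.asarray(t_s) / 60.0))


def accumulated_vo2(series: BreathSeries, baseline_rate_l_min: float,
                    phase: str = "exercise") -> tuple[float, float]:
    """Accumulated net VO2 over the exercise phase.

    Returns ``(net_volume_l, mean_net_rate_l_min)``: the trapezoidal
    time integral of VO2 above ``baseline_rate_l_min`` (clipped at 0),
    and that volume divided by the exercise duration.  The baseline
    rate should be the baseline-phase mean in L·min⁻¹.
    """
    if baseline_rate_l_min <= 0:
        raise ValueError("baseline_rate_l_min must be > 0")
    sub = slice_phase(series, phase, rezero=True)
    if len(sub) == 0:
        raise ValueError(f"{phase} phase contains no breaths")
    lo, hi = series.marks.bounds(phase)
    vol = _net_integral(sub.times, sub.channel("vo2") / 1000.0,
                        baseline_rate_l_min, span=(0.0, hi - lo))
    return vol, vol / ((hi - lo) / 60.0)


def epoc(series: BreathSeries, baseline_rate_l_min: float,
         window_s: float = 300.0) -> float:
    """Excess post-exercise oxygen consumption (L) over the recovery window.

    Trapezoidal integral of max(VO2 - baseline, 0) over the first
    ``window_s`` seconds of recovery (default 5 min).
    """
    if baseline_rate_l_min <= 0:
        raise ValueError("baseline_rate_l_min must be > 0")
    sub = slice_phase(series, "recovery", rezero=True)
    if len(sub) == 0:
        raise ValueError("recovery phase contains no breaths")
    keep = sub.times <= window_s
    lo, hi = series.marks.bounds("recovery")
    end = min(window_s, hi - lo)
    return _net_integral(sub.times[keep], sub.channel("vo2")[keep] / 1000.0,
                         baseline_rate_l_min, span=(0.0, end))
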