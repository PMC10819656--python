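"""Synthetic breath-by-breath sessions and metabolic panels.

No raw recordings from the cohort are publicly deposited, so the
pipeline is exercised on simulated subjects whose generating
parameters are drawn around the cohort's printed means and SDs:
body mass 87.9 ± 10.5 kg, primary amplitude 42.0 ± 6.0
mL·kg⁻¹·min⁻¹, time delay 4.3 ± 2.2 s, time constant 14.2 ± 6.0 s,
effort duration 117 ± 10 s, baseline VO2 0.6 ± 0.1 L·min⁻¹, lactate
1.5 ± 0.3 → 20.7 ± 2.6 mM, glucose 97.1 ± 4.6 → 141.8 ± 8.6 mg·dL⁻¹,
RPE 6 ± 1 → 18 ± 2.  Draws are truncated to physiologic positivity
and deterministic per (master_seed, index).

The forward model is the delayed-exponential kinetics curve per phase
plus additive breath noise.  Breath timing follows gamma-distributed
intervals (shape 8, CV ~ 35%).  Breath-to-breath VO2 scatter is
*uniform* on ±sqrt(3)·sd (same SD, bounded support): real breath
scatter is effectively bounded, and a bounded model makes "artifact"
well-defined — deviations of 5 SD or more cannot arise from clean
breaths, only from the injected, flagged artifact spikes.  Gaussian
noise is available via ``noise_dist="gaussian"``.  Ancillary channels
(HR, VE, VCO2, fr, VT) follow smooth phase profiles at plausible
ranges; they are invented (no numeric traces are published) and only
carried so the container is fully populated.

The recovery (off-transient) kinetics are not printed for the cohort;
defaults (amplitude 75% of the primary, tau 45 s) keep VO2 elevated
above baseline at minute 5 of recovery, matching the reported
persistent excess post-exercise VO2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .gasio import (BreathSeries, MetabolicPanel, PhaseMarks, write_breath_csv)
from .kinetics import KineticsParams, model_value

__all__ = [
    "NoiseSpec",
    "SubjectProfile",
    "CohortSpec",
    "SubjectData",
    "make_subject",
    "generate_breaths",
    "generate_panel",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Breath-timing and measurement-noise parameters."""

    vo2_sd: float = 2.0            # mL·kg⁻¹·min⁻¹, additive per breath
    interval_shape: float = 8.0    # gamma shape of breath intervals
    interval_mean_s: tuple[float, float, float] = (2.4, 1.2, 1.2)
    artifact_rate: float = 0.02    # per-breath spike probability
    dist: str = "uniform"          # "uniform" (bounded) or "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate <= 0.1:
            raise ValueError("artifact_rate must lie in [0, 0.1]")
        if self.vo2_sd < 0 or self.interval_shape <= 0 \
                or any(m <= 0 for m in self.interval_mean_s):
            raise ValueError("noise parameters must be positive")
        if self.dist not in ("uniform", "gaussian"):
            raise ValueError("dist must be 'uniform' or 'gaussian'")


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generating parameters for one synthetic subject."""

    subject_id: str
    mass: float
    true_kinetics_on: KineticsParams
    true_kinetics_off: KineticsParams
    baseline_vo2_l_min: float
    durations: tuple[float, float, float]  # baseline, exercise, recovery (s)
    lactate: tuple[float, float, int]      # baseline mM, peak mM, peak minute
    glucose: tuple[float, float]           # baseline, post (mg·dL⁻¹)
    rpe: tuple[int, int]                   # baseline, post (6-20)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.baseline_vo2_l_min <= 0:
            raise ValueError("mass and baseline VO2 must be > 0")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be > 0")
        if self.lactate[0] <= 0 or self.lactate[1] <= 0 \
                or self.lactate[2] not in (1, 3, 5, 7):
            raise ValueError("invalid lactate specification")
        if not all(6 <= r <= 20 for r in self.rpe):
            raise ValueError("RPE must lie in [6, 20]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_kinetics_on"] = self.true_kinetics_on.to_dict()
        d["true_kinetics_off"] = self.true_kinetics_off.to_dict()
        return d


def _pair(mean: float, sd: float) -> tuple[float, float]:
    return (mean, sd)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sampling distributions, defaulting to the printed values."""

    n: int = 14
    master_seed: int = 0
    mass: tuple = _pair(87.9, 10.5)
    ap: tuple = _pair(42.0, 6.0)
    tdp: tuple = _pair(4.3, 2.2)
    tau_p: tuple = _pair(14.2, 6.0)
    exercise_s: tuple = _pair(117.0, 10.0)
    baseline_vo2_l_min: tuple = _pair(0.6, 0.1)
    lactate_baseline: tuple = _pair(1.5, 0.3)
    lactate_peak: tuple = _pair(20.7, 2.6)
    glucose_baseline: tuple = _pair(97.1, 4.6)
    glucose_post: tuple = _pair(141.8, 8.6)
    rpe_baseline: tuple = _pair(6.0, 1.0)
    rpe_post: tuple = _pair(18.0, 2.0)
    # recovery kinetics are unpublished; see module docstring
    off_amp_frac: tuple = _pair(0.75, 0.05)
    off_tau: tuple = _pair(45.0, 8.0)
    off_td: tuple = _pair(5.0, 2.0)
    baseline_s: float = 180.0
    recovery_s: float = 420.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("mass", "ap", "tdp", "tau_p", "exercise_s",
                     "baseline_vo2_l_min", "lactate_baseline", "lactate_peak",
                     "glucose_baseline", "glucose_post", "rpe_baseline",
                     "rpe_post", "off_amp_frac", "off_tau", "off_td"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float = np.inf) -> float:
    """Truncated-normal draw by rejection; exact mean when sd == 0."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))  # pragma: no cover


def _subject_seed(master_seed: int, index: int) -> int:
    return int((master_seed * 1000003 + index * 7919 + 17) % (2 ** 31))


def make_subject(spec: CohortSpec, index: int) -> SubjectProfile:
    """Draw one subject's ground-truth profile from the cohort spec."""
    rng = np.random.default_rng([spec.master_seed, index, 0])
    mass = _trunc_normal(rng, *spec.mass, lo=40.0)
    baseline_vo2 = _trunc_normal(rng, *spec.baseline_vo2_l_min, lo=0.2)
    a0 = baseline_vo2 * 1000.0 / mass
    ap = _trunc_normal(rng, *spec.ap, lo=10.0)
    tdp = _trunc_normal(rng, *spec.tdp, lo=0.0, hi=15.0)
    tau_p = _trunc_normal(rng, *spec.tau_p, lo=5.0)
    duration = _trunc_normal(rng, *spec.exercise_s, lo=60.0)
    on = KineticsParams(a0=a0, ap=ap, tdp=tdp, tau_p=tau_p, direction="on")
    end_value = float(model_value(duration, on))
    off = KineticsParams(
        a0=end_value,
        ap=_trunc_normal(rng, *spec.off_amp_frac, lo=0.3, hi=0.95) * ap,
        tdp=_trunc_normal(rng, *spec.off_td, lo=0.0, hi=15.0),
        tau_p=_trunc_normal(rng, *spec.off_tau, lo=15.0),
        direction="off")
    la_base = _trunc_normal(rng, *spec.lactate_baseline, lo=0.4)
    la_peak = _trunc_normal(rng, *spec.lactate_peak, lo=la_base + 1.0)
    peak_minute = int(rng.choice([3, 5, 7]))
    glucose = (_trunc_normal(rng, *spec.glucose_baseline, lo=50.0),
               _trunc_normal(rng, *spec.glucose_post, lo=50.0))
    rpe = (int(np.clip(round(_trunc_normal(rng, *spec.rpe_baseline, lo=6,
                                           hi=20)), 6, 20)),
           int(np.clip(round(_trunc_normal(rng, *spec.rpe_post, lo=6,
                                           hi=20)), 6, 20)))
    return SubjectProfile(
        subject_id=f"S{index + 1:02d}",
        mass=mass,
        true_kinetics_on=on,
        true_kinetics_off=off,
        baseline_vo2_l_min=baseline_vo2,
        durations=(spec.baseline_s, duration, spec.recovery_s),
        lactate=(la_base, la_peak, peak_minute),
        glucose=glucose,
        rpe=rpe,
        noise=spec.noise,
        seed=_subject_seed(spec.master_seed, index),
    )


def _phase_times(rng: np.random.Generator, start: float, end: float,
                 mean_s: float, shape: float) -> np.ndarray:
    n_max = int((end - start) / mean_s * 2) + 20
    gaps = rng.gamma(shape, mean_s / shape, size=n_max)
    t = start + np.cumsum(gaps)
    return t[t < end]


def _noise(rng: np.random.Generator, sd: float, n: int, dist: str) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if dist == "uniform":
        a = np.sqrt(3.0) * sd
        return rng.uniform(-a, a, n)
    return rng.normal(0.0, sd, n)


# smooth, invented phase profiles for the ancillary channels
_HR_ON = KineticsParams(a0=68.0, ap=104.0, tdp=0.0, tau_p=25.0)
_VE_ON = KineticsParams(a0=12.0, ap=116.0, tdp=2.0, tau_p=18.0)
_RER_ON = KineticsParams(a0=0.85, ap=0.23, tdp=0.0, tau_p=30.0)
_RER_REC = KineticsParams(a0=1.08, ap=0.25, tdp=0.0, tau_p=60.0)


def generate_breaths(profile: SubjectProfile) -> BreathSeries:
    """Forward-simulate one subject's breath-by-breath session.

    VO2 per breath is the phase's kinetics curve (mass-normalized,
    scaled to absolute mL·min⁻¹) plus bounded breath noise.  Artifact
    breaths are injected at the profile's artifact rate as upward
    spikes of (5-10) noise SDs with the artifact flag set, so the
    injection log is exactly the set of flagged breaths.
    """
    base_s, ex_s, rec_s = profile.durations
    marks = PhaseMarks(0.0, base_s, base_s + ex_s, base_s + ex_s + rec_s)
    rng = np.random.default_rng([profile.seed, 1])
    ns = profile.noise
    a0 = profile.true_kinetics_on.a0
    sd_abs = ns.vo2_sd * profile.mass  # noise in absolute mL·min⁻¹

    frames = []
    phase_bounds = ((0.0, base_s, ns.interval_mean_s[0]),
                    (base_s, base_s + ex_s, ns.interval_mean_s[1]),
                    (base_s + ex_s, base_s + ex_s + rec_s,
                     ns.interval_mean_s[2]))
    for phase_i, (lo, hi, mean_gap) in enumerate(phase_bounds):
        t = _phase_times(rng, lo, hi, mean_gap, ns.interval_shape)
        u = t - lo  # phase-relative time
        if phase_i == 0:
            vo2_kg = np.full(len(t), a0)
            hr = np.full(len(t), _HR_ON.a0)
            ve = np.full(len(t), _VE_ON.a0)
            rer = np.full(len(t), _RER_ON.a0)
        elif phase_i == 1:
            vo2_kg = model_value(u, profile.true_kinetics_on)
            hr = model_value(u, _HR_ON)
            ve = model_value(u, _VE_ON)
            rer = model_value(u, _RER_ON)
        else:
            off = profile.true_kinetics_off
            vo2_kg = model_value(u, off)
            hr_top = float(model_value(profile.durations[1], _HR_ON))
            ve_top = float(model_value(profile.durations[1], _VE_ON))
            hr = model_value(u, KineticsParams(a0=hr_top, ap=hr_top - 95.0,
                                               tdp=0.0, tau_p=80.0,
                                               direction="off"))
            ve = model_value(u, KineticsParams(a0=ve_top, ap=0.7 * ve_top,
                                               tdp=0.0, tau_p=70.0,
                                               direction="off"))
            rer = model_value(u, _RER_REC)

        vo2 = np.clip(vo2_kg * profile.mass + _noise(rng, sd_abs, len(t),
                                                     ns.dist), 0.0, None)
        artifact = rng.random(len(t)) < ns.artifact_rate
        vo2 = vo2 + artifact * (5.0 + rng.uniform(0.0, 5.0, len(t))) * sd_abs

        gaps = np.diff(np.r_[lo, t])
        fr = 60.0 / gaps
        ve_b = np.clip(ve * (1.0 + _noise(rng, 0.02, len(t), ns.dist)), 0.1,
                       None)
        frames.append(pd.DataFrame({
            "time": t,
            "vo2": vo2,
            "vco2": np.clip(vo2 * rer, 0.0, None),
            "ve": ve_b,
            "fr": fr,
            "vt": ve_b / fr,
            "hr": np.clip(hr * (1.0 + _noise(rng, 0.01, len(t), ns.dist)),
                          30.0, None),
            "artifact": artifact,
        }))
    df = pd.concat(frames, ignore_index=True)
    return BreathSeries(df, marks, profile.mass)


def generate_panel(profile: SubjectProfile,
                   lactate_jitter_sd: float = 0.0) -> MetabolicPanel:
    """Metabolic panel with lactate sampled at minutes 1, 3, 5 and 7.

    The lactate course rises linearly to the profile's peak at its
    peak minute and declines 2% per minute afterwards (at most 8% by
    minute 7).  Glucose and RPE are copied from the profile.
    """
    base, peak, peak_min = profile.lactate
    rng = np.random.default_rng([profile.seed, 2])
    post = {}
    for m in (1, 3, 5, 7):
        if m <= peak_min:
            v = base + (peak - base) * (m / peak_min)
        else:
            v = peak * (1.0 - 0.02 * (m - peak_min))
        if lactate_jitter_sd > 0 and m != peak_min:
            # jitter bounded so the constructed peak minute stays the max
            v = v - abs(rng.normal(0.0, lactate_jitter_sd))
        post[m] = max(v, 0.1)
    return MetabolicPanel(
        lactate_baseline=base,
        lactate_post=post,
        glucose_baseline=profile.glucose[0],
        glucose_post=profile.glucose[1],
        rpe_baseline=profile.rpe[0],
        rpe_post=profile.rpe[1],
    )


class SubjectData(NamedTuple):
    profile: SubjectProfile
    series: BreathSeries
    panel: MetabolicPanel


def generate_cohort(spec: CohortSpec | None = None,
                    out_dir=None) -> list[SubjectData]:
    """Generate ``spec.n`` independent subjects (profile, breaths, panel).

    Reproducible from ``spec.master_seed``.  With ``out_dir`` the
    canonical CSV + sidecar files and a ground-truth manifest are
    written as well.
    """
    spec = spec if spec is not None else CohortSpec()
    cohort = []
    for i in range(spec.n):
        profile = make_subject(spec, i)
        cohort.append(SubjectData(profile, generate_breaths(profile),
                                  generate_panel(profile)))
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: list[SubjectData], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for profile, series, panel in cohort:
        write_breath_csv(series, out_dir / f"{profile.subject_id}_breaths.csv",
                         panel=panel)
        manifest.append(profile.to_dict())
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
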