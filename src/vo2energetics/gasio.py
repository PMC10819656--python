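"""Breath-by-breath gas-exchange data model and file I/O.

The central container is :class:`BreathSeries`: a time-ordered table of
breath records (VO2, VCO2, ventilation, respiratory frequency, tidal
volume, heart rate) together with the session's phase boundaries
(baseline / exercise / recovery) and the subject's body mass.  VO2 is
stored in absolute mL·min⁻¹ throughout; mass normalization happens at
presentation and model-fitting time, because the energy integrals need
absolute volumes while the kinetics models are expressed per kilogram.

File format: a plain UTF-8 CSV with canonical column names plus a JSON
sidecar holding phase marks, body mass and (optionally) the metabolic
panel.  Vendor exports can be ingested by supplying a column-name
mapping (``dialect``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "BreathRecord",
    "PhaseMarks",
    "BreathSeries",
    "MetabolicPanel",
    "read_breath_csv",
    "write_breath_csv",
    "slice_phase",
    "final_window_summary",
]

#: numeric breath channels, in canonical column order
CHANNELS = ("vo2", "vco2", "ve", "fr", "vt", "hr")

#: canonical CSV header -> internal column name
CANONICAL_COLUMNS = {
    "time_s": "time",
    "vo2_ml_min": "vo2",
    "vco2_ml_min": "vco2",
    "ve_l_min": "ve",
    "fr_bpm": "fr",
    "vt_l": "vt",
    "hr_bpm": "hr",
    "artifact": "artifact",
}
_INTERNAL_TO_CANONICAL = {v: k for k, v in CANONICAL_COLUMNS.items()}

PHASES = ("baseline", "exercise", "recovery")


@dataclass(frozen=True)
class PhaseMarks:
    """Phase boundaries of a session, in seconds from session start.

    Phase intervals are half-open: baseline = [baseline_start,
    exercise_start), exercise = [exercise_start, exercise_end),
    recovery = [exercise_end, recovery_end).
    """

    baseline_start: float
    exercise_start: float
    exercise_end: float
    recovery_end: float

    def __post_init__(self) -> None:
        seq = (self.baseline_start, self.exercise_start,
               self.exercise_end, self.recovery_end)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"phase marks must be strictly increasing, got {seq}")

    @property
    def exercise_duration(self) -> float:
        return self.exercise_end - self.exercise_start

    def bounds(self, phase: str) -> tuple[float, float]:
        if phase == "baseline":
            return self.baseline_start, self.exercise_start
        if phase == "exercise":
            return self.exercise_start, self.exercise_end
        if phase == "recovery":
            return self.exercise_end, self.recovery_end
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")

    def shifted(self, offset: float) -> "PhaseMarks":
        return PhaseMarks(self.baseline_start + offset,
                          self.exercise_start + offset,
                          self.exercise_end + offset,
                          self.recovery_end + offset)

    def to_dict(self) -> dict:
        return {
            "baseline_start": self.baseline_start,
            "exercise_start": self.exercise_start,
            "exercise_end": self.exercise_end,
            "recovery_end": self.recovery_end,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhaseMarks":
        return cls(float(d["baseline_start"]), float(d["exercise_start"]),
                   float(d["exercise_end"]), float(d["recovery_end"]))


@dataclass(frozen=True)
class BreathRecord:
    """A single breath. VO2/VCO2 in mL·min⁻¹, VE in L·min⁻¹, VT in L."""

    time: float
    vo2: float
    vco2: float = 0.0
    ve: float = 0.0
    fr: float = 0.0
    vt: float = 0.0
    hr: float = 0.0
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        for name in CHANNELS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def rer(self) -> float:
        """Respiratory exchange ratio VCO2/VO2 (defined only for VO2 > 0)."""
        if self.vo2 <= 0:
            raise ValueError("RER undefined for vo2 <= 0")
        return self.vco2 / self.vo2


class BreathSeries:
    """Time-ordered breath records with phase marks and subject mass.

    Internally a :class:`pandas.DataFrame` with columns ``time``, the
    six channels of :data:`CHANNELS` and a boolean ``artifact`` column.
    """

    def __init__(self, df: pd.DataFrame, marks: PhaseMarks, body_mass: float,
                 validate: bool = True):
        df = df.copy()
        for col in CHANNELS:
            if col not in df.columns:
                df[col] = 0.0
        if "artifact" not in df.columns:
            df["artifact"] = False
        df = df[["time", *CHANNELS, "artifact"]]
        df["artifact"] = df["artifact"].astype(bool)
        df = df.reset_index(drop=True)
        self.df = df
        self.marks = marks
        self.body_mass = float(body_mass)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        t = self.df["time"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"breath times must be strictly increasing; first violation at "
                f"row {i} (time {t[i]} after {t[i - 1]})")
        if len(t) and (t[0] < self.marks.baseline_start
                       or t[-1] > self.marks.recovery_end):
            raise ValueError("record times must lie within "
                             "[baseline_start, recovery_end]")
        num = self.df[list(CHANNELS)].to_numpy(float)
        if np.any(num < 0):
            raise ValueError("breath channels must be non-negative")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(float)

    @property
    def records(self) -> Iterator[BreathRecord]:
        for row in self.df.itertuples(index=False):
            yield BreathRecord(row.time, row.vo2, row.vco2, row.ve,
                               row.fr, row.vt, row.hr, bool(row.artifact))

    def channel(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(float)

    def replace_df(self, df: pd.DataFrame, marks: PhaseMarks | None = None,
                   validate: bool = True) -> "BreathSeries":
        return BreathSeries(df, marks if marks is not None else self.marks,
                            self.body_mass, validate=validate)

    def equals(self, other: "BreathSeries", atol: float = 1e-9) -> bool:
        if len(self) != len(other) or self.marks != other.marks:
            return False
        if abs(self.body_mass - other.body_mass) > atol:
            return False
        a = self.df.drop(columns="artifact").to_numpy(float)
        b = other.df.drop(columns="artifact").to_numpy(float)
        return (np.allclose(a, b, atol=atol)
                and (self.df["artifact"] == other.df["artifact"]).all())


@dataclass(frozen=True)
class MetabolicPanel:
    """Capillary blood panel and perceived exertion, pre vs post workout.

    ``lactate_post`` maps the sampling minute (1, 3, 5, 7 post-workout)
    to blood lactate in mM.  RPE is on the 6-20 Borg scale.
    """

    lactate_baseline: float
    lactate_post: Mapping[int, float]
    glucose_baseline: float
    glucose_post: float
    rpe_baseline: int
    rpe_post: int

    def __post_init__(self) -> None:
        if self.lactate_baseline <= 0 or self.glucose_baseline <= 0 \
                or self.glucose_post <= 0:
            raise ValueError("concentrations must be > 0")
        if not self.lactate_post:
            raise ValueError("at least one post-exercise lactate sample required")
        if any(v <= 0 for v in self.lactate_post.values()):
            raise ValueError("lactate samples must be > 0")
        for r in (self.rpe_baseline, self.rpe_post):
            if not 6 <= r <= 20:
                raise ValueError(f"RPE must lie in [6, 20], got {r}")

    @property
    def lactate_peak(self) -> float:
        return max(self.lactate_post.values())

    def to_dict(self) -> dict:
        return {
            "lactate_baseline": self.lactate_baseline,
            "lactate_post": {str(k): v for k, v in self.lactate_post.items()},
            "glucose_baseline": self.glucose_baseline,
            "glucose_post": self.glucose_post,
            "rpe_baseline": self.rpe_baseline,
            "rpe_post": self.rpe_post,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetabolicPanel":
        return cls(
            lactate_baseline=float(d["lactate_baseline"]),
            lactate_post={int(k): float(v) for k, v in d["lactate_post"].items()},
            glucose_baseline=float(d["glucose_baseline"]),
            glucose_post=float(d["glucose_post"]),
            rpe_baseline=int(d["rpe_baseline"]),
            rpe_post=int(d["rpe_post"]),
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_breath_csv(path, dialect: Mapping[str, str] | None = None,
                    sidecar=None) -> tuple[BreathSeries, MetabolicPanel | None]:
    """Read a breath CSV plus its JSON sidecar.

    Parameters
    ----------
    path
        CSV file with a header row. Canonical columns are
        ``time_s, vo2_ml_min, vco2_ml_min, ve_l_min, fr_bpm, vt_l,
        hr_bpm, artifact``; only time and VO2 are required.
    dialect
        Optional mapping from the file's column names to canonical
        names, for vendor exports.
    sidecar
        JSON file with ``marks`` (phase boundaries), ``body_mass`` and
        optionally ``panel``. Defaults to ``path`` with a .json suffix.

    Returns the series and the metabolic panel (or None if the sidecar
    carries no panel).  Rows whose time or VO2 is non-numeric are
    dropped with a warning that reports their CSV line numbers.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} with phase marks and body mass is required")

    raw = pd.read_csv(path, dtype=str)
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    raw = raw.rename(columns=CANONICAL_COLUMNS)
    for required in ("time", "vo2"):
        if required not in raw.columns:
            raise ValueError(
                f"{path}: missing required column "
                f"{_INTERNAL_TO_CANONICAL[required]!r}")

    df = pd.DataFrame()
    df["time"] = pd.to_numeric(raw["time"], errors="coerce")
    for col in CHANNELS:
        df[col] = (pd.to_numeric(raw[col], errors="coerce")
                   if col in raw.columns else 0.0)
    if "artifact" in raw.columns:
        df["artifact"] = pd.to_numeric(raw["artifact"],
                                       errors="coerce").fillna(0).astype(bool)
    else:
        df["artifact"] = False

    bad = df.index[df["time"].isna() | df["vo2"].isna()]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        lines = [int(i) + 2 for i in bad]
        warnings.warn(f"{path}: dropped {len(bad)} row(s) with non-numeric "
                      f"time/vo2 at line(s) {lines}")
        df = df.drop(index=bad).reset_index(drop=True)
    df[list(CHANNELS)] = df[list(CHANNELS)].fillna(0.0)

    meta = json.loads(sidecar.read_text())
    marks = PhaseMarks.from_dict(meta["marks"])
    series = BreathSeries(df, marks, float(meta["body_mass"]))
    panel = (MetabolicPanel.from_dict(meta["panel"])
             if meta.get("panel") else None)
    return series, panel


def write_breath_csv(series: BreathSeries, path,
                     panel: MetabolicPanel | None = None,
                     float_format: str = "%.6f") -> None:
    """Write a series (and optional panel) to CSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = series.df.copy()
    out["artifact"] = out["artifact"].astype(int)
    out = out.rename(columns=_INTERNAL_TO_CANONICAL)
    out.to_csv(path, index=False, float_format=float_format)
    meta = {"marks": series.marks.to_dict(), "body_mass": series.body_mass}
    if panel is not None:
        meta["panel"] = panel.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# phase slicing and summaries
# ---------------------------------------------------------------------------

def slice_phase(series: BreathSeries, phase: str,
                rezero: bool = False) -> BreathSeries:
    """Return the records with time in the half-open phase interval.

    With ``rezero=True`` all times (and the marks) are shifted so the
    phase starts at 0.
    """
    start, end = series.marks.bounds(phase)
    t = series.times
    sub = series.df[(t >= start) & (t < end)]
    if sub.empty:
        warnings.warn(f"phase {phase!r} window [{start}, {end}) contains "
                      "no breaths")
    marks = series.marks
    if rezero:
        sub = sub.copy()
        sub["time"] = sub["time"] - start
        marks = marks.shifted(-start)
    return series.replace_df(sub, marks=marks)


def final_window_summary(series: BreathSeries,
                         window_s: float = 30.0) -> dict[str, float]:
    """Mean cardiorespiratory values over the final window of exercise.

    Averages every channel over breaths with time in
    [exercise_end - window_s, exercise_end).  VO2 is reported in
    absolute mL·min⁻¹ and L·min⁻¹ and mass-normalized mL·kg⁻¹·min⁻¹;
    RER is the ratio of the mean VCO2 to the mean VO2.
    """
    ex = slice_phase(series, "exercise")
    if len(ex) == 0:
        raise ValueError("exercise phase contains no breaths")
    if window_s > series.marks.exercise_duration:
        raise ValueError("window exceeds the exercise duration")
    lo = series.marks.exercise_end - window_s
    sub = ex.df[(ex.df["time"] >= lo) & (ex.df["time"] < series.marks.exercise_end)]
    if sub.empty:
        raise ValueError(
            f"no breaths in the final {window_s} s of exercise; widen the window")
    means = sub[list(CHANNELS)].mean()
    out = {f"{c}_mean": float(means[c]) for c in CHANNELS}
    out["vo2_ml_min"] = float(means["vo2"])
    out["vo2_l_min"] = float(means["vo2"]) / 1000.0
    out["vo2_ml_kg_min"] = float(means["vo2"]) / series.body_mass
    out["rer"] = float(means["vco2"] / means["vo2"]) if means["vo2"] > 0 else float("nan")
    out["n_breaths"] = int(len(sub))
    return out
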