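"""Domain types and tabular I/O for dynamic-PET studies.

Time convention: **seconds** in every on-disk file, **minutes** internally for
all kinetics (rate constants are conventionally min^-1).  The conversion lives
here and nowhere else.  All stored activities are decay-corrected to injection
time.

On-disk dialect (comma-separated, mandatory header, '.' decimal):

* ``tac.csv``    — columns ``frame_start_s, frame_end_s, activity_kBq_per_ml``
* ``blood.csv``  — columns ``time_s, whole_blood_kBq_per_ml, plasma_kBq_per_ml``
  (optionally ``plasma_parent_corrected_kBq_per_ml``)
* ``parent.csv`` — columns ``time_min, fraction_intact``
* ``study.yaml`` — subjects with group, dose_mg_per_kg, injected_dose_MBq,
  body_weight_g and per-subject file paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError, FormatError

SEC_PER_MIN = 60.0

#: physical half-life of carbon-11 in minutes
C11_HALF_LIFE_MIN = 20.38

_TAC_COLUMNS = ["frame_start_s", "frame_end_s", "activity_kBq_per_ml"]
_BLOOD_COLUMNS = ["time_s", "whole_blood_kBq_per_ml", "plasma_kBq_per_ml"]
_BLOOD_CORRECTED = "plasma_parent_corrected_kBq_per_ml"
_PARENT_COLUMNS = ["time_min", "fraction_intact"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous acquisition frames, the time axis of every TAC.

    Parameters
    ----------
    frame_start, frame_end:
        Frame boundaries in **seconds** from injection.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise FormatError("frame_start and frame_end must be equal-length 1-d arrays")
        if np.any(end - start <= 0):
            i = int(np.argmax(end - start <= 0))
            raise FormatError(f"non-positive frame duration at row {i}")
        if np.any(np.diff(start) <= 0):
            i = int(np.argmax(np.diff(start) <= 0)) + 1
            raise FormatError(f"frame starts not strictly increasing at row {i}")
        if start.size > 1 and not np.allclose(start[1:], end[:-1], rtol=0, atol=1e-9):
            i = int(np.argmax(~np.isclose(start[1:], end[:-1], rtol=0, atol=1e-9))) + 1
            raise FormatError(f"frames not contiguous at row {i}")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_mid(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.frame_end - self.frame_start

    # minute-domain views used by the kinetics modules
    @property
    def mid_min(self) -> np.ndarray:
        return self.frame_mid / SEC_PER_MIN

    @property
    def start_min(self) -> np.ndarray:
        return self.frame_start / SEC_PER_MIN

    @property
    def end_min(self) -> np.ndarray:
        return self.frame_end / SEC_PER_MIN

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration / SEC_PER_MIN


@dataclass
class TimeActivityCurve:
    """Tissue activity per frame, decay-corrected to injection time (kBq/ml)."""

    schedule: FrameSchedule
    activity: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise FormatError(
                f"activity length {self.activity.size} != {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.activity)):
            i = int(np.argmax(~np.isfinite(self.activity)))
            raise FormatError(f"non-finite activity at row {i}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.activity.shape:
                raise FormatError("weights length mismatch")
            if np.any(self.weights < 0):
                raise FormatError("negative fit weight")


@dataclass
class BloodSeries:
    """Arterial samples: whole blood and plasma concentrations (kBq/ml).

    ``plasma_parent_corrected`` is filled by the metabolite stage;
    ``parent_corrected_applied`` guards against double correction.
    """

    sample_time: np.ndarray  # seconds from injection
    whole_blood: np.ndarray
    plasma: np.ndarray
    plasma_parent_corrected: np.ndarray | None = None
    parent_corrected_applied: bool = False

    def __post_init__(self):
        self.sample_time = np.asarray(self.sample_time, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        n = self.sample_time.size
        if n == 0:
            raise FormatError("empty blood series")
        if self.whole_blood.shape != (n,) or self.plasma.shape != (n,):
            raise FormatError("blood series column length mismatch")
        if np.any(self.sample_time <= 0):
            i = int(np.argmax(self.sample_time <= 0))
            raise FormatError(f"non-positive sample time at row {i}")
        if np.any(np.diff(self.sample_time) <= 0):
            i = int(np.argmax(np.diff(self.sample_time) <= 0)) + 1
            raise FormatError(f"sample times not strictly increasing at row {i}")
        for name in ("whole_blood", "plasma"):
            v = getattr(self, name)
            if np.any(v < 0):
                i = int(np.argmax(v < 0))
                raise FormatError(f"negative {name} concentration at row {i}")
        if self.plasma_parent_corrected is not None:
            self.plasma_parent_corrected = np.asarray(
                self.plasma_parent_corrected, dtype=float
            )
            if self.plasma_parent_corrected.shape != (n,):
                raise FormatError("corrected plasma column length mismatch")

    @property
    def time_min(self) -> np.ndarray:
        return self.sample_time / SEC_PER_MIN


@dataclass
class ScanRecord:
    """One animal's scan: metadata plus its TAC and blood series."""

    subject_id: str
    group: str  # "baseline" or "drug"
    drug_dose: float  # mg/kg, 0 for baseline
    injected_dose: float  # MBq
    body_weight: float  # g
    tac: TimeActivityCurve
    blood: BloodSeries

    def __post_init__(self):
        if self.group not in ("baseline", "drug"):
            raise ConfigError(f"unknown group label {self.group!r}")
        if self.injected_dose <= 0:
            raise DomainError("injected_dose must be > 0")
        if self.body_weight <= 0:
            raise DomainError("body_weight must be > 0")
        if self.drug_dose < 0:
            raise DomainError("drug_dose must be >= 0")
        if self.group == "baseline" and self.drug_dose != 0:
            raise ConfigError(f"baseline subject {self.subject_id} has nonzero dose")


@dataclass
class StudyConfig:
    """Run-wide options with documented defaults.

    isotope_half_life: physical half-life in minutes (default carbon-11).
    t_star_logan / t_star_patlak: graphical-analysis start times in minutes.
    n_multistart: multistart count for compartment fits.
    suv_window_min: (start, end) minutes for the SUV interval mean.
    """

    isotope_half_life: float = C11_HALF_LIFE_MIN
    seed: int = 0
    t_star_logan: float = 10.0
    t_star_patlak: float = 20.0
    n_multistart: int = 5
    suv_window_min: tuple[float, float] = (0.0, 60.0)
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.isotope_half_life <= 0:
            raise DomainError("isotope_half_life must be > 0")

    @property
    def decay_constant(self) -> float:
        """lambda_phys in min^-1."""
        return np.log(2.0) / self.isotope_half_life


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path, required):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def read_tac(path) -> TimeActivityCurve:
    """Read a ``tac.csv`` file; rejects non-contiguous or non-monotone frames."""
    df = _read_csv(path, _TAC_COLUMNS)
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy()
    )
    return TimeActivityCurve(schedule, df["activity_kBq_per_ml"].to_numpy())


def write_tac(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.schedule.frame_start,
            "frame_end_s": tac.schedule.frame_end,
            "activity_kBq_per_ml": tac.activity,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_blood(path) -> BloodSeries:
    df = _read_csv(path, _BLOOD_COLUMNS)
    corrected = df[_BLOOD_CORRECTED].to_numpy() if _BLOOD_CORRECTED in df else None
    return BloodSeries(
        df["time_s"].to_numpy(),
        df["whole_blood_kBq_per_ml"].to_numpy(),
        df["plasma_kBq_per_ml"].to_numpy(),
        plasma_parent_corrected=corrected,
        parent_corrected_applied=corrected is not None,
    )


def write_blood(blood: BloodSeries, path) -> None:
    cols = {
        "time_s": blood.sample_time,
        "whole_blood_kBq_per_ml": blood.whole_blood,
        "plasma_kBq_per_ml": blood.plasma,
    }
    if blood.plasma_parent_corrected is not None:
        cols[_BLOOD_CORRECTED] = blood.plasma_parent_corrected
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_parent_samples(path) -> list[tuple[float, float]]:
    """Read ``parent.csv`` -> list of (time_min, fraction_intact)."""
    df = _read_csv(path, _PARENT_COLUMNS)
    frac = df["fraction_intact"].to_numpy(dtype=float)
    t = df["time_min"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        i = int(np.argmax((frac < 0) | (frac > 1)))
        raise FormatError(f"{path}: fraction_intact outside [0,1] at row {i}")
    if np.any(t <= 0):
        i = int(np.argmax(t <= 0))
        raise FormatError(f"{path}: non-positive time at row {i}")
    return list(zip(t.tolist(), frac.tolist()))


def write_parent_samples(samples, path) -> None:
    t, f = zip(*samples)
    pd.DataFrame({"time_min": t, "fraction_intact": f}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_study(config_path) -> tuple[list[ScanRecord], StudyConfig]:
    """Load a ``study.yaml`` manifest and every per-subject TAC/blood file.

    Returns records sorted as listed, baseline (dose 0) subjects first in their
    stated order; duplicate subject ids raise :class:`ConfigError`.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise ConfigError(f"{config_path}: missing 'subjects' section")
    base = config_path.parent
    records: list[ScanRecord] = []
    seen: set[str] = set()
    for sub in manifest["subjects"]:
        sid = str(sub["subject_id"])
        if sid in seen:
            raise ConfigError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        records.append(
            ScanRecord(
                subject_id=sid,
                group=sub["group"],
                drug_dose=float(sub["dose_mg_per_kg"]),
                injected_dose=float(sub["injected_dose_MBq"]),
                body_weight=float(sub["body_weight_g"]),
                tac=read_tac(base / sub["tac"]),
                blood=read_blood(base / sub["blood"]),
            )
        )
    opts = manifest.get("options", {}) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(opts) - known
    if unknown:
        raise ConfigError(f"unknown study options {sorted(unknown)}")
    if "suv_window_min" in opts:
        opts["suv_window_min"] = tuple(opts["suv_window_min"])
    cfg = StudyConfig(**opts)
    return records, cfg


def write_study(records: list[ScanRecord], out_dir, config: StudyConfig | None = None) -> Path:
    """Write per-subject tac/blood CSVs plus a ``study.yaml`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for rec in records:
        tac_name = f"{rec.subject_id}_tac.csv"
        blood_name = f"{rec.subject_id}_blood.csv"
        write_tac(rec.tac, out_dir / tac_name)
        write_blood(rec.blood, out_dir / blood_name)
        subjects.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "dose_mg_per_kg": float(rec.drug_dose),
                "injected_dose_MBq": float(rec.injected_dose),
                "body_weight_g": float(rec.body_weight),
                "tac": tac_name,
                "blood": blood_name,
            }
        )
    manifest: dict = {"subjects": subjects}
    if config is not None:
        manifest["options"] = {
            "isotope_half_life": float(config.isotope_half_life),
            "seed": int(config.seed),
            "t_star_logan": float(config.t_star_logan),
            "t_star_patlak": float(config.t_star_patlak),
            "n_multistart": int(config.n_multistart),
            "suv_window_min": [float(x) for x in config.suv_window_min],
        }
    path = out_dir / "study.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

def suv(
    tac: TimeActivityCurve,
    injected_dose_MBq: float,
    body_weight_g: float,
    window_min: tuple[float, float] = (0.0, 60.0),
) -> tuple[np.ndarray, float]:
    """Standardized uptake value curve and its duration-weighted interval mean.

    SUV = C[kBq/ml] * BW[g] / ID[kBq] under unit tissue density, so a tissue
    concentration equal to the injected dose per gram of body weight gives
    SUV = 1.  The interval mean covers frames whose mid-time falls inside
    ``window_min`` (minutes), weighted by frame duration.
    """
    if injected_dose_MBq <= 0 or body_weight_g <= 0:
        raise DomainError("injected dose and body weight must be > 0")
    id_kbq = injected_dose_MBq * 1000.0
    curve = tac.activity * body_weight_g / id_kbq
    mid = tac.schedule.mid_min
    sel = (mid >= window_min[0]) & (mid <= window_min[1])
    if not np.any(sel):
        raise DomainError(f"no frames inside SUV window {window_min}")
    w = tac.schedule.duration_min[sel]
    mean = float(np.sum(curve[sel] * w) / np.sum(w))
    return curve, mean
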