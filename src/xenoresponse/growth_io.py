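"""Domain types, validation and I/O for caliper tumor-volume studies.

The unit of raw data is one caliper measurement: ``(model_id, animal_id,
arm, study_day, volume_mm3)`` in a long-format TSV/CSV table.  Study day 0
is the day of randomization / first dose; negative days are permitted for
pre-randomization measurements (they are only consulted as an initial-volume
fallback).  Volumes are mm^3 throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VEHICLE = "vehicle"
TREATED = "treated"

ENDPOINT_REASONS = frozenset({"resected", "max_volume", "welfare", "study_end"})

REQUIRED_COLUMNS = ("model_id", "animal_id", "arm", "study_day", "volume_mm3")


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


class SchemaError(ValidationError):
    """Raised when an input table is missing required columns."""


class AlignmentError(ValidationError):
    """Raised when a growth curve cannot be anchored to the start window."""


@dataclass(frozen=True, order=True)
class Measurement:
    """A single caliper measurement: integer study day, volume in mm^3 (> 0)."""

    study_day: int
    volume: float

    def __post_init__(self) -> None:
        if not (self.volume > 0 and math.isfinite(self.volume)):
            raise ValidationError(
                f"volume must be finite and > 0, got {self.volume!r} on day {self.study_day}"
            )


@dataclass(frozen=True)
class Endpoint:
    """Why and when an animal left the study (resection, cap, welfare, study end)."""

    day: int
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in ENDPOINT_REASONS:
            raise ValidationError(
                f"endpoint reason {self.reason!r} not in {sorted(ENDPOINT_REASONS)}"
            )
        if self.day < 0:
            raise ValidationError(f"endpoint day must be >= 0, got {self.day}")


@dataclass
class AnimalCourse:
    """One animal's measurement series plus arm label, dosing days and endpoint.

    Measurements are sorted ascending by day on construction; duplicate days
    within one animal are an error.
    """

    animal_id: str
    model_id: str
    arm: str
    measurements: list[Measurement]
    dosing_days: list[int] = field(default_factory=list)
    endpoint: Endpoint | None = None

    def __post_init__(self) -> None:
        ms = sorted(self.measurements, key=lambda m: m.study_day)
        days = [m.study_day for m in ms]
        if len(set(days)) != len(days):
            dup = sorted({d for d in days if days.count(d) > 1})
            raise ValidationError(
                f"animal {self.animal_id!r}: duplicate study_day(s) {dup}"
            )
        self.measurements = ms

    @property
    def days(self) -> np.ndarray:
        return np.array([m.study_day for m in self.measurements], dtype=int)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.volume for m in self.measurements], dtype=float)

    @property
    def n(self) -> int:
        return len(self.measurements)

    def first(self) -> Measurement:
        return self.measurements[0]

    def last(self) -> Measurement:
        return self.measurements[-1]


@dataclass(frozen=True)
class CycleSchedule:
    """Per-cycle dosing layout: cisplatin on day 1, etoposide on days 1-3,
    cycles 14 days apart (cycle c starts on day 14*c, day 0 = randomization)."""

    cisplatin_days: tuple[int, ...] = (1,)
    etoposide_days: tuple[int, ...] = (1, 2, 3)
    cycle_length_days: int = 14
    n_cycles: int = 1

    def dose_days(self) -> list[int]:
        """All absolute dosing days over all cycles, sorted, deduplicated."""
        days = set()
        for c in range(self.n_cycles):
            start = c * self.cycle_length_days
            for d in self.cisplatin_days + self.etoposide_days:
                days.add(start + d)
        return sorted(days)

    def cycle_first_dose_days(self) -> list[int]:
        first = min(self.cisplatin_days + self.etoposide_days)
        return [c * self.cycle_length_days + first for c in range(self.n_cycles)]

    def last_dose_day(self) -> int:
        """Last administered dose day of the last completed cycle."""
        last = max(self.cisplatin_days + self.etoposide_days)
        return (self.n_cycles - 1) * self.cycle_length_days + last


@dataclass(frozen=True)
class ResponseThresholds:
    """Percent-change cut-offs of the six-class response call.

    growth_threshold_pct: growth over initial volume defining the time-to-
    threshold Tx (300 => tumor at 4x initial volume).  pd_increase_pct,
    pr_regression_pct, cr_regression_pct: the 25/50/90 percent rules.
    tgd_cut: tumor-growth-delay ratio separating PD1 from PD2.
    """

    growth_threshold_pct: float = 300.0
    pd_increase_pct: float = 25.0
    pr_regression_pct: float = 50.0
    cr_regression_pct: float = 90.0
    tgd_cut: float = 1.5

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        for k, v in vals.items():
            if not v > 0:
                raise ValidationError(f"threshold {k} must be > 0, got {v}")
        if not self.cr_regression_pct > self.pr_regression_pct:
            raise ValidationError("cr_regression_pct must exceed pr_regression_pct")


@dataclass(frozen=True)
class AlignmentParams:
    """Start-volume alignment window: anchor at the earliest measurement in
    [target - tol, target + tol] mm^3, or at the first measurement if it
    already exceeds high_cut."""

    target: float = 50.0
    tol: float = 10.0
    high_cut: float = 60.0

    def __post_init__(self) -> None:
        if not self.tol < self.target:
            raise ValidationError("alignment tol must be < target")
        if not self.high_cut >= self.target + self.tol:
            raise ValidationError("alignment high_cut must be >= target + tol")


@dataclass(frozen=True)
class StudyConfig:
    """Bundle of all analysis settings for one study run."""

    thresholds: ResponseThresholds = ResponseThresholds()
    alignment: AlignmentParams = AlignmentParams()
    slope_transform: str = "cube"
    end_of_dosing_rule: str | int = "last_dose_last_cycle"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_transform not in ("cube", "cube_root", "log", "identity"):
            raise ValidationError(
                f"unknown slope_transform {self.slope_transform!r}"
            )


@dataclass
class CohortStudy:
    """All animals of one xenograft model plus its dosing schedule/thresholds."""

    model_id: str
    subtype_label: str
    animals: list[AnimalCourse]
    cycle_schedule: CycleSchedule = CycleSchedule()
    thresholds: ResponseThresholds = ResponseThresholds()

    def __post_init__(self) -> None:
        for a in self.animals:
            if a.model_id != self.model_id:
                raise ValidationError(
                    f"animal {a.animal_id!r} has model_id {a.model_id!r}, "
                    f"study is {self.model_id!r}"
                )

    def arm(self, label: str) -> list[AnimalCourse]:
        return [a for a in self.animals if a.arm == label]

    @property
    def vehicle(self) -> list[AnimalCourse]:
        return self.arm(VEHICLE)

    @property
    def treated(self) -> list[AnimalCourse]:
        return [a for a in self.animals if a.arm != VEHICLE]


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_measurements(
    path: str | Path,
    schema: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> list[AnimalCourse]:
    """Read a long-format measurement table into validated animal courses.

    Parameters
    ----------
    path : file with header row and columns model_id, animal_id, arm,
        study_day, volume_mm3 (delimiter from the extension: .tsv/.tab/.txt
        are tab, anything else comma; override with ``delimiter``).
    schema : optional map from canonical column name to the actual column
        name in the file.

    Raises ``SchemaError`` on missing columns and ``ValidationError`` (with
    1-based file line numbers) on non-positive volumes or duplicate
    (animal, day) pairs.  Missing arm labels default to "treated" with a
    warning; the vehicle arm must always be explicit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"measurement table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    if df["arm"].isna().any():
        n_missing = int(df["arm"].isna().sum())
        warnings.warn(
            f"{path}: {n_missing} row(s) without arm label; defaulting to "
            f"'{TREATED}' (vehicle must be explicit)",
            stacklevel=2,
        )
        df["arm"] = df["arm"].fillna(TREATED)

    bad_rows = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            day = int(row["study_day"])
            vol = float(row["volume_mm3"])
        except (TypeError, ValueError):
            bad_rows.append(f"line {line}: non-numeric study_day/volume_mm3")
            continue
        if not (vol > 0 and math.isfinite(vol)):
            bad_rows.append(f"line {line}: volume_mm3 must be > 0, got {vol}")
    if bad_rows:
        raise ValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_rows))

    courses: list[AnimalCourse] = []
    for (model_id, animal_id), grp in df.groupby(
        ["model_id", "animal_id"], sort=True
    ):
        arms = grp["arm"].unique()
        if len(arms) > 1:
            raise ValidationError(
                f"{path}: animal {animal_id!r} has conflicting arm labels {list(arms)}"
            )
        dup = grp["study_day"].astype(int).duplicated()
        if dup.any():
            lines = [int(i) + 2 for i in grp.index[dup]]
            raise ValidationError(
                f"{path}: duplicate (animal, day) for animal {animal_id!r} "
                f"at line(s) {lines}"
            )
        ms = [
            Measurement(int(d), float(v))
            for d, v in zip(grp["study_day"], grp["volume_mm3"])
        ]
        courses.append(
            AnimalCourse(
                animal_id=str(animal_id),
                model_id=str(model_id),
                arm=str(arms[0]),
                measurements=ms,
            )
        )
    return courses


def write_measurements(courses: list[AnimalCourse], path: str | Path) -> None:
    """Write animal courses back to the long-format table read by
    :func:`read_measurements`."""
    path = Path(path)
    rows = [
        {
            "model_id": c.model_id,
            "animal_id": c.animal_id,
            "arm": c.arm,
            "study_day": m.study_day,
            "volume_mm3": m.volume,
        }
        for c in courses
        for m in c.measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, None), index=False)


SCORE_COLUMNS = (
    "row_type",
    "model_id",
    "animal_id",
    "itv_mm3",
    "tx_days",
    "tx_extrapolated",
    "tgd",
    "best_regression_pct",
    "end_of_dosing_change_pct",
    "max_increase_pct",
    "cr_sustained_days",
    "call",
)


def write_score_table(records, path: str | Path, model_summary: dict | None = None):
    """Write per-animal score records plus one model-level summary row.

    ``records`` are duck-typed score records (see the scoring module); floats
    are serialized at 6 significant digits and round-trip losslessly at that
    precision through :func:`read_score_table`.
    """
    if not records:
        raise ValidationError("write_score_table: empty record list")
    path = Path(path)

    def fmt(x):
        if x is None:
            return ""
        if isinstance(x, float):
            if math.isinf(x):
                return "inf"
            return f"{x:.6g}"
        return x

    rows = []
    for r in records:
        rows.append(
            {
                "row_type": "animal",
                "model_id": getattr(r, "model_id", ""),
                "animal_id": r.animal_id,
                "itv_mm3": fmt(float(r.itv)),
                "tx_days": fmt(float(r.tx)),
                "tx_extrapolated": bool(r.tx_extrapolated),
                "tgd": fmt(None if r.tgd is None else float(r.tgd)),
                "best_regression_pct": fmt(float(r.best_regression_pct)),
                "end_of_dosing_change_pct": fmt(float(r.end_of_dosing_change_pct)),
                "max_increase_pct": fmt(float(r.max_increase_pct)),
                "cr_sustained_days": int(r.cr_sustained_days),
                "call": r.call.name,
            }
        )
    summary = dict(model_summary or {})
    rows.append(
        {
            "row_type": "model_summary",
            "model_id": summary.get("model_id", rows[0]["model_id"]),
            "animal_id": "",
            "itv_mm3": "",
            "tx_days": fmt(summary.get("median_vehicle_tx")),
            "tx_extrapolated": "",
            "tgd": "",
            "best_regression_pct": "",
            "end_of_dosing_change_pct": "",
            "max_increase_pct": "",
            "cr_sustained_days": "",
            "call": summary.get("model_call", ""),
        }
    )
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(
        path, sep=_sep_for(path, None), index=False
    )


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_score_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score table not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path, None))


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def config_to_dict(config: StudyConfig) -> dict:
    return {
        "thresholds": dataclasses.asdict(config.thresholds),
        "alignment": dataclasses.asdict(config.alignment),
        "slope_transform": config.slope_transform,
        "end_of_dosing_rule": config.end_of_dosing_rule,
        "rng_seed": config.rng_seed,
    }


def config_from_dict(d: dict) -> StudyConfig:
    return StudyConfig(
        thresholds=ResponseThresholds(**d.get("thresholds", {})),
        alignment=AlignmentParams(**d.get("alignment", {})),
        slope_transform=d.get("slope_transform", "cube"),
        end_of_dosing_rule=d.get("end_of_dosing_rule", "last_dose_last_cycle"),
        rng_seed=int(d.get("rng_seed", 0)),
    )


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML or JSON study config; absent keys take their defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return config_from_dict(d or {})


def save_config(config: StudyConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: StudyConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
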