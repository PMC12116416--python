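"""Growth-curve preprocessing for longitudinal xenograft volume data.

Implements the preprocessing used for knockdown-style growth comparisons:
re-anchoring every animal to a common starting volume, filling the measurement
grid to daily resolution by linear interpolation between consecutive caliper
readings, carrying the final reading forward so all animals share a common
end day, and summarizing a cohort as per-day mean +/- SD.

Provenance is tracked per day: ``observed`` days carry the raw caliper value
bit-exactly, ``interpolated`` days lie on the chord between the two flanking
observations, ``extended`` days repeat the carried value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .growth_io import (
    AlignmentError,
    AlignmentParams,
    AnimalCourse,
    Endpoint,
    Measurement,
    ValidationError,
)

OBSERVED = "observed"
INTERPOLATED = "interpolated"
EXTENDED = "extended"


@dataclass
class DailySeries:
    """A volume series at daily resolution with per-day provenance flags."""

    start_day: int
    volumes: np.ndarray
    flags: np.ndarray  # str array, entries in {observed, interpolated, extended}

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if len(self.volumes) < 1:
            raise ValidationError("DailySeries must have length >= 1")
        if len(self.volumes) != len(self.flags):
            raise ValidationError("volumes and flags must have equal length")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.start_day, self.start_day + len(self.volumes))

    @property
    def last_day(self) -> int:
        return self.start_day + len(self.volumes) - 1

    def value_on(self, day: int) -> float:
        """Value on a given day; for days past the end (series not extended
        that far) the nearest available day is used."""
        idx = int(np.clip(day - self.start_day, 0, len(self.volumes) - 1))
        return float(self.volumes[idx])

    def observed_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(days, volumes) of the raw caliper observations only."""
        mask = self.flags == OBSERVED
        return self.days[mask], self.volumes[mask]


def align_to_start(
    course: AnimalCourse,
    target: float = 50.0,
    tol: float = 10.0,
    high_cut: float = 60.0,
) -> AnimalCourse:
    """Re-time a course so day 0 is the start-volume anchor.

    The anchor is the earliest measurement with volume in
    ``[target - tol, target + tol]``; if no measurement falls in that window
    and the first measurement already exceeds ``high_cut``, the first
    measurement anchors the series.  Measurements before the anchor are
    dropped; relative spacing is preserved.  Dosing days and the endpoint day
    are shifted by the same offset (shifted dosing days that become negative
    are dropped).

    Raises :class:`AlignmentError` when no measurement is in-window and the
    first measurement is at or below ``high_cut`` (ambiguous start).
    """
    AlignmentParams(target=target, tol=tol, high_cut=high_cut)  # validate
    if course.n < 1:
        raise ValidationError(f"animal {course.animal_id!r}: no measurements")
    lo, hi = target - tol, target + tol
    anchor = None
    for m in course.measurements:
        if lo <= m.volume <= hi:
            anchor = m
            break
    if anchor is None:
        if course.first().volume > high_cut:
            anchor = course.first()
        else:
            raise AlignmentError(
                f"animal {course.animal_id!r}: no measurement in "
                f"[{lo:g}, {hi:g}] mm^3 and first measurement "
                f"{course.first().volume:g} <= {high_cut:g} mm^3"
            )
    shift = anchor.study_day
    kept = [
        Measurement(m.study_day - shift, m.volume)
        for m in course.measurements
        if m.study_day >= shift
    ]
    endpoint = course.endpoint
    if endpoint is not None:
        endpoint = Endpoint(max(endpoint.day - shift, 0), endpoint.reason)
    return replace(
        course,
        measurements=kept,
        dosing_days=[d - shift for d in course.dosing_days if d - shift >= 0],
        endpoint=endpoint,
    )


def interpolate_daily(course: AnimalCourse) -> DailySeries:
    """Fill the series to daily resolution.

    Each missing integer day between two consecutive observations takes the
    value of the straight line through those two observations (a two-point
    regression is exactly the chord).  Observed days keep the raw caliper
    value bit-exactly.  A single-measurement course yields a length-1 series.
    """
    if course.n < 1:
        raise ValidationError(f"animal {course.animal_id!r}: no measurements")
    days = course.days
    vols = course.volumes
    grid = np.arange(days[0], days[-1] + 1)
    values = np.interp(grid, days, vols)
    flags = np.full(len(grid), INTERPOLATED, dtype=object)
    obs_idx = days - days[0]
    values[obs_idx] = vols  # exact raw values on observed days
    flags[obs_idx] = OBSERVED
    return DailySeries(start_day=int(days[0]), volumes=values, flags=flags)


def extend_series(
    series: DailySeries, end_day: int, carry: str = "last"
) -> DailySeries:
    """Carry the series forward to ``end_day``.

    Days after the last available day are filled with the final value
    (``carry="last"``, default) or with the series maximum (``carry="max"``),
    flagged ``extended``.  A no-op when ``end_day`` equals the last day;
    never changes pre-existing values, and is idempotent.
    """
    if carry not in ("last", "max"):
        raise ValidationError(f"carry must be 'last' or 'max', got {carry!r}")
    if end_day < series.last_day:
        raise ValidationError(
            f"end_day {end_day} precedes last series day {series.last_day}"
        )
    n_extra = end_day - series.last_day
    if n_extra == 0:
        return series
    fill = float(series.volumes[-1] if carry == "last" else series.volumes.max())
    return DailySeries(
        start_day=series.start_day,
        volumes=np.concatenate([series.volumes, np.full(n_extra, fill)]),
        flags=np.concatenate([series.flags, np.full(n_extra, EXTENDED, dtype=object)]),
    )


def cohort_profile(series_list: list[DailySeries]) -> pd.DataFrame:
    """Per-day mean, sample SD (n-1 denominator) and n over a cohort.

    All series must share the same start day and length (extend first);
    SD is reported as NaN when n = 1.
    """
    if not series_list:
        raise ValidationError("cohort_profile: empty series list")
    starts = {s.start_day for s in series_list}
    lengths = {len(s.volumes) for s in series_list}
    if len(starts) > 1 or len(lengths) > 1:
        raise ValidationError(
            "cohort_profile: series have unequal day coverage; "
            "extend all series to a common end day first"
        )
    mat = np.vstack([s.volumes for s in series_list])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if n > 1 else np.full(mat.shape[1], np.nan)
    return pd.DataFrame(
        {
            "day": series_list[0].days,
            "mean": mean,
            "sd": sd,
            "n": n,
        }
    )


def daily_to_table(
    series_map: dict[tuple[str, str, str], DailySeries]
) -> pd.DataFrame:
    """Flatten {(model_id, animal_id, arm): DailySeries} into a long table."""
    rows = []
    for (model_id, animal_id, arm), s in series_map.items():
        for day, vol, flag in zip(s.days, s.volumes, s.flags):
            rows.append(
                {
                    "model_id": model_id,
                    "animal_id": animal_id,
                    "arm": arm,
                    "study_day": int(day),
                    "volume_mm3": float(vol),
                    "provenance": flag,
                }
            )
    return pd.DataFrame(rows)
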