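"""Modified pRECIST scoring of xenograft volume trajectories.

The scoring is anchored to the initial tumor volume (ITV) at randomization.
For each animal we derive:

* ``Tx`` — the first study day the tumor exceeds +300% growth over ITV
  (i.e. 4x ITV).  When the threshold is never reached within the observation
  window, Tx is extrapolated by ordinary least squares of the raw
  measurements on study day.
* ``TGD`` — tumor growth delay, the ratio Tx_treated / median(Tx_vehicle).
* regression / growth percentages relative to ITV, and the tumor volume
  doubling time DT = dt * ln 2 / ln(V_last / V_first).

These feed an ordered six-class response call (worst to best):
PD1 < PD2 < SD < PR < CR < MCR.  A complete response (>90% regression) is
"maintained" (MCR) when the sub-10%-of-ITV state persists for at least one
doubling time of the untreated tumor.  Per-animal calls are aggregated to a
model-level call by ordinal mean, rounding exact halves toward the worse
call.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .curve_prep import DailySeries, extend_series, interpolate_daily
from .growth_io import (
    VEHICLE,
    AnimalCourse,
    CohortStudy,
    ResponseThresholds,
    StudyConfig,
    ValidationError,
)


class ResponseCall(enum.IntEnum):
    """Six-class response call, ordinal codes 1 (worst) to 6 (best)."""

    PD1 = 1
    PD2 = 2
    SD = 3
    PR = 4
    CR = 5
    MCR = 6


@dataclass(frozen=True)
class DoublingTime:
    """Tumor volume doubling time in days; None when there is no net growth."""

    dt_days: float | None

    def __post_init__(self) -> None:
        if self.dt_days is not None and not self.dt_days > 0:
            raise ValidationError(f"doubling time must be > 0, got {self.dt_days}")

    @property
    def defined(self) -> bool:
        return self.dt_days is not None


@dataclass
class ScoreRecord:
    """Per-animal pRECIST quantities and the categorical call."""

    animal_id: str
    itv: float
    tx: float
    tx_extrapolated: bool
    tgd: float | None
    best_regression_pct: float
    end_of_dosing_change_pct: float
    max_increase_pct: float
    max_increase_dosing_pct: float
    cr_sustained_days: int
    call: ResponseCall
    model_id: str = ""
    warnings: list[str] = field(default_factory=list)


def initial_tumor_volume(course: AnimalCourse) -> float:
    """ITV: the day-0 volume if observed, else the latest measurement at
    day <= 0, else (with a warning) the first measurement."""
    if course.n < 1:
        raise ValidationError(f"animal {course.animal_id!r}: no measurements")
    at_or_before = [m for m in course.measurements if m.study_day <= 0]
    if at_or_before:
        return at_or_before[-1].volume
    warnings.warn(
        f"animal {course.animal_id!r}: no measurement at day <= 0; using the "
        f"first measurement (day {course.first().study_day}) as ITV",
        stacklevel=2,
    )
    return course.first().volume


def time_to_growth_threshold(
    daily: DailySeries,
    itv: float,
    threshold_pct: float = 300.0,
    cap_days: float | None = None,
) -> tuple[float, bool]:
    """First day the volume exceeds ``itv * (1 + threshold_pct/100)``.

    If the daily series never exceeds the threshold, Tx is extrapolated from
    an OLS fit of the *raw observed measurements* from day 0 onward (not the
    interpolated grid); a fit with slope <= 0, fewer than 2 usable
    observations, or a crossing beyond ``cap_days`` yields Tx = +inf.

    Returns ``(tx_days, extrapolated)``.
    """
    if not itv > 0:
        raise ValidationError(f"ITV must be > 0, got {itv}")
    thr = itv * (1.0 + threshold_pct / 100.0)
    above = np.nonzero(daily.volumes > thr)[0]
    if above.size:
        return float(daily.days[above[0]]), False
    obs_days, obs_vols = daily.observed_points()
    keep = obs_days >= 0
    obs_days, obs_vols = obs_days[keep], obs_vols[keep]
    if len(obs_days) < 2:
        warnings.warn(
            "threshold not reached and <2 observed points from day 0: "
            "Tx regression undefined, returning +inf",
            stacklevel=2,
        )
        return math.inf, True
    slope, intercept = np.polyfit(obs_days.astype(float), obs_vols, 1)
    if slope <= 0:
        return math.inf, True
    tx = (thr - intercept) / slope
    if cap_days is not None and tx > cap_days:
        return math.inf, True
    return float(tx), True


def tumor_growth_delay(tx_treated: float, tx_vehicle: list[float]) -> float:
    """TGD = tx_treated / median of the finite vehicle Tx values."""
    finite = [t for t in tx_vehicle if math.isfinite(t)]
    if not finite:
        raise ValidationError(
            "tumor_growth_delay: no finite vehicle Tx (no reference growth)"
        )
    med = float(np.median(finite))
    if math.isinf(tx_treated):
        return math.inf
    return float(tx_treated) / med


def doubling_time(
    v_first: float, day_first: float, v_last: float, day_last: float
) -> DoublingTime:
    """DT = (day_last - day_first) * ln2 / ln(v_last / v_first); undefined
    (None) when there is no net growth."""
    if not (v_first > 0 and v_last > 0):
        raise ValidationError("doubling_time: volumes must be > 0")
    if not day_last > day_first:
        raise ValidationError("doubling_time: day_last must exceed day_first")
    if v_last <= v_first:
        return DoublingTime(None)
    return DoublingTime((day_last - day_first) * math.log(2) / math.log(v_last / v_first))


def classify_animal(
    daily: DailySeries,
    itv: float,
    tgd: float | None,
    dt: DoublingTime,
    thresholds: ResponseThresholds = ResponseThresholds(),
    end_of_dosing_day: int = 3,
    animal_id: str = "",
    model_id: str = "",
    tx: float = math.nan,
    tx_extrapolated: bool = False,
) -> ScoreRecord:
    """Apply the ordered six-class decision tree to one daily trajectory.

    Rules, evaluated in order against percentages relative to ITV:

    1. MCR — regression > cr_regression_pct with the sub-(100-cr)% state
       sustained for at least one doubling time (consecutive days);
    2. CR  — regression > cr_regression_pct at >= 1 day;
    3. PR  — regression > pr_regression_pct;
    4. SD  — change at end of dosing <= pd_increase_pct AND maximum increase
       during the dosing window <= pd_increase_pct;
    5. PD1 / PD2 — otherwise, split on TGD <= tgd_cut / > tgd_cut.

    Boundary convention: strict ">" at the 90/50/25 cuts, "<=" at the TGD cut.
    With an undefined doubling time a CR-depth trajectory is called CR (MCR
    unreachable) and a warning is recorded.
    """
    if not itv > 0:
        raise ValidationError(f"ITV must be > 0, got {itv}")
    notes: list[str] = []
    rel = daily.volumes / itv
    days = daily.days

    best_regression = max(0.0, 100.0 * (1.0 - float(rel.min())))
    max_increase = max(0.0, 100.0 * (float(rel.max()) - 1.0))

    # end-of-dosing value: nearest daily value on/after the end-of-dosing day
    if end_of_dosing_day > daily.last_day:
        notes.append(
            f"end_of_dosing_day {end_of_dosing_day} beyond series end "
            f"{daily.last_day}; using last day"
        )
    end_val = daily.value_on(max(end_of_dosing_day, daily.start_day))
    end_change = 100.0 * (end_val / itv - 1.0)

    dosing_mask = (days >= 0) & (days <= end_of_dosing_day)
    if dosing_mask.any():
        max_increase_dosing = max(0.0, 100.0 * (float(rel[dosing_mask].max()) - 1.0))
    else:
        max_increase_dosing = 0.0

    # longest run of consecutive days below the complete-response floor
    below = rel < (1.0 - thresholds.cr_regression_pct / 100.0)
    cr_sustained = 0
    run = 0
    for b in below:
        run = run + 1 if b else 0
        cr_sustained = max(cr_sustained, run)

    if best_regression > thresholds.cr_regression_pct:
        if dt.defined and cr_sustained >= dt.dt_days:
            call = ResponseCall.MCR
        else:
            call = ResponseCall.CR
            if not dt.defined:
                notes.append(
                    "doubling time undefined: MCR unreachable, CR returned"
                )
    elif best_regression > thresholds.pr_regression_pct:
        call = ResponseCall.PR
    elif (
        end_change <= thresholds.pd_increase_pct
        and max_increase_dosing <= thresholds.pd_increase_pct
    ):
        call = ResponseCall.SD
    else:
        if tgd is None:
            raise ValidationError(
                f"animal {animal_id!r}: progressive trajectory but TGD missing"
            )
        call = ResponseCall.PD1 if tgd <= thresholds.tgd_cut else ResponseCall.PD2

    return ScoreRecord(
        animal_id=animal_id,
        model_id=model_id,
        itv=float(itv),
        tx=float(tx),
        tx_extrapolated=tx_extrapolated,
        tgd=tgd,
        best_regression_pct=best_regression,
        end_of_dosing_change_pct=end_change,
        max_increase_pct=max_increase,
        max_increase_dosing_pct=max_increase_dosing,
        cr_sustained_days=int(cr_sustained),
        call=call,
        warnings=notes,
    )


def aggregate_model(calls: list[ResponseCall]) -> ResponseCall:
    """Model-level call: arithmetic mean of ordinal codes, exact halves
    rounded toward the worse (lower) code."""
    if not calls:
        raise ValidationError("aggregate_model: empty call list")
    s = sum(int(c) for c in calls)
    mean = Fraction(s, len(calls))
    floor = mean.numerator // mean.denominator
    frac = mean - floor
    code = floor + 1 if frac > Fraction(1, 2) else floor
    return ResponseCall(code)


# ---------------------------------------------------------------------------
# Whole-study scoring
# ---------------------------------------------------------------------------

def end_of_dosing_day(study: CohortStudy, config: StudyConfig) -> int:
    rule = config.end_of_dosing_rule
    if isinstance(rule, int):
        return rule
    if rule == "last_dose_last_cycle":
        return study.cycle_schedule.last_dose_day()
    raise ValidationError(f"unknown end_of_dosing_rule {rule!r}")


def score_study(
    study: CohortStudy, config: StudyConfig = StudyConfig()
) -> tuple[list[ScoreRecord], dict]:
    """Run the full per-model scoring pipeline.

    Daily interpolation and common-end-day extension, ITV and Tx per animal,
    median vehicle Tx, per-treated-animal TGD, the vehicle-arm median
    doubling time, per-animal classification of the treated arm, and the
    ordinal-mean model call.  Deterministic given inputs and config.

    Returns (treated-arm score records, model-level summary dict).
    """
    vehicle = study.vehicle
    treated = study.treated
    if not vehicle or not treated:
        raise ValidationError(
            f"model {study.model_id!r}: scoring requires >= 1 vehicle and "
            f">= 1 treated animal (got {len(vehicle)} vehicle, {len(treated)} treated)"
        )
    thresholds = study.thresholds
    horizon = max(a.last().study_day for a in study.animals)
    cap_days = 10.0 * horizon if horizon > 0 else None
    eod = end_of_dosing_day(study, config)

    daily_map: dict[str, DailySeries] = {}
    itv_map: dict[str, float] = {}
    tx_map: dict[str, tuple[float, bool]] = {}
    for a in study.animals:
        try:
            d = extend_series(interpolate_daily(a), horizon)
            itv = initial_tumor_volume(a)
            tx = time_to_growth_threshold(
                d, itv, thresholds.growth_threshold_pct, cap_days=cap_days
            )
        except ValidationError as err:
            raise ValidationError(f"animal {a.animal_id!r}: {err}") from err
        daily_map[a.animal_id] = d
        itv_map[a.animal_id] = itv
        tx_map[a.animal_id] = tx

    vehicle_tx = [tx_map[a.animal_id][0] for a in vehicle]
    finite_vtx = [t for t in vehicle_tx if math.isfinite(t)]
    if not finite_vtx:
        raise ValidationError(
            f"model {study.model_id!r}: no finite vehicle Tx; TGD undefined"
        )
    median_vtx = float(np.median(finite_vtx))

    # intrinsic growth: per-vehicle-animal doubling time from first/last
    # measurements, summarized by the median
    vdts = []
    for a in vehicle:
        f, l = a.first(), a.last()
        d = doubling_time(f.volume, f.study_day, l.volume, l.study_day)
        if d.defined:
            vdts.append(d.dt_days)
    dt = DoublingTime(float(np.median(vdts))) if vdts else DoublingTime(None)

    records: list[ScoreRecord] = []
    for a in treated:
        tx, extrapolated = tx_map[a.animal_id]
        tgd = tumor_growth_delay(tx, vehicle_tx)
        rec = classify_animal(
            daily_map[a.animal_id],
            itv_map[a.animal_id],
            tgd,
            dt,
            thresholds=thresholds,
            end_of_dosing_day=eod,
            animal_id=a.animal_id,
            model_id=study.model_id,
            tx=tx,
            tx_extrapolated=extrapolated,
        )
        records.append(rec)

    model_call = aggregate_model([r.call for r in records])
    summary = {
        "model_id": study.model_id,
        "subtype_label": study.subtype_label,
        "n_vehicle": len(vehicle),
        "n_treated": len(treated),
        "median_vehicle_tx": median_vtx,
        "vehicle_doubling_time_days": dt.dt_days,
        "end_of_dosing_day": eod,
        "model_call": model_call.name,
        "calls": [r.call.name for r in records],
    }
    return records, summary
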