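"""Seeded synthetic CDX-cohort generator.

The generative model mirrors the design of a subcutaneous xenograft
chemotherapy study: animals enter at randomization (day 0) with initial
volumes deterministically spread over 200-300 mm^3, grow exponentially at a
per-animal rate, receive cisplatin on day 1 and etoposide on days 1-3 of
each 14-day cycle, are measured three times weekly (Mon/Wed/Fri grid), and
leave the study when the tumor reaches 1200 mm^3 or at the study horizon.

Treatment acts through an instantaneous fractional volume kill at the first
dose day of each cycle and/or a fractional suppression of the growth rate
over a window (optionally with delayed onset — a cytostatic effect that
builds up after dosing — and a post-kill dormancy delay).  Measurement
noise is multiplicative lognormal (caliper error scales with tumor size)
with a 10 mm^3 detection floor.

Six class presets encode trajectory shapes that, in the fully deterministic
zero-noise regime, land squarely in each of the six response classes; they
are the ground truth for end-to-end pipeline tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .growth_io import (
    TREATED,
    VEHICLE,
    AnimalCourse,
    CohortStudy,
    CycleSchedule,
    Endpoint,
    Measurement,
    ResponseThresholds,
    ValidationError,
)
from .stats import SurvivalRecord

DEFAULT_RATE_CV = 0.10  # biological CV of the per-animal growth rate


@dataclass(frozen=True)
class TreatmentEffect:
    """Cytotoxic/cytostatic action of one treatment cycle.

    kill_fraction: fraction of tumor volume removed at the first dose day of
    each cycle.  growth_suppression: fractional reduction of the growth rate
    during the suppression window.  onset_day: days after the first dose
    before suppression begins (may be negative to cover the dose day
    itself).  suppression_days: window length.  regrowth_delay: days of zero
    growth immediately after the kill, before (suppressed or normal) growth
    resumes.
    """

    kill_fraction: float = 0.0
    growth_suppression: float = 0.0
    suppression_days: int = 0
    onset_day: int = 0
    regrowth_delay: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.kill_fraction < 1:
            raise ValidationError("kill_fraction must be in [0, 1)")
        if not 0 <= self.growth_suppression <= 1:
            raise ValidationError("growth_suppression must be in [0, 1]")
        for name in ("suppression_days", "regrowth_delay"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


NO_EFFECT = TreatmentEffect()


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one synthetic cohort.

    growth_rate is the vehicle exponential rate per day (default 0.20/day,
    a 3.5-day doubling time typical of an aggressive SCLC xenograft);
    rate_cv the lognormal CV of that rate across animals; noise_cv the
    multiplicative lognormal measurement CV.  schedule holds the weekly
    measurement offsets (0, 2, 4 = Mon/Wed/Fri anchored at randomization).
    """

    growth_rate: float = 0.20
    rate_cv: float = DEFAULT_RATE_CV
    effect: TreatmentEffect = NO_EFFECT
    noise_cv: float = 0.0
    schedule: tuple[int, ...] = (0, 2, 4)
    randomization_window: tuple[float, float] = (200.0, 300.0)
    cap: float = 1200.0
    floor: float = 10.0
    cycles: CycleSchedule = CycleSchedule()
    horizon_days: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValidationError("growth_rate must be > 0")
        for name in ("rate_cv", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.randomization_window
        if not 0 < lo <= hi:
            raise ValidationError("randomization_window must satisfy 0 < lo <= hi")
        if not 0 < self.floor < lo:
            raise ValidationError("floor must be in (0, randomization lo)")
        if not self.cap > hi:
            raise ValidationError("cap must exceed the randomization window")
        if not all(0 <= o < 7 for o in self.schedule) or len(self.schedule) < 1:
            raise ValidationError("schedule must be weekly offsets in [0, 7)")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Per-animal RNG stream: stable hash of the id spliced into the master
    seed, so adding animals never perturbs existing trajectories."""
    tag = zlib.crc32(animal_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def latent_trajectory(
    v0: float,
    growth_rate: float,
    effect: TreatmentEffect,
    cycles: CycleSchedule,
    horizon_days: int,
) -> np.ndarray:
    """Deterministic daily latent volume, days 0..horizon inclusive.

    Day-by-day piecewise-exponential integration: over [t, t+1) the rate is
    the base rate, reduced by growth_suppression inside a cycle's
    suppression window, or zero during post-kill dormancy; the fractional
    kill applies once per cycle at that cycle's first dose day.
    """
    kill_days = set(cycles.cycle_first_dose_days()) if effect.kill_fraction else set()
    supp, dorm = [], []
    for start in cycles.cycle_first_dose_days():
        s0 = start + effect.onset_day
        supp.append((s0, s0 + effect.suppression_days))
        dorm.append((start, start + effect.regrowth_delay))
    v = np.empty(horizon_days + 1)
    v[0] = v0
    for t in range(1, horizon_days + 1):
        t0 = t - 1
        if any(a <= t0 < b for a, b in dorm):
            g = 0.0
        elif any(a <= t0 < b for a, b in supp):
            g = growth_rate * (1.0 - effect.growth_suppression)
        else:
            g = growth_rate
        v[t] = v[t - 1] * math.exp(g)
        if t in kill_days:
            v[t] *= 1.0 - effect.kill_fraction
    return v


def simulate_animal(
    params: SimParams,
    arm: str,
    animal_id: str = "A001",
    model_id: str = "SIM",
    v0: float | None = None,
) -> AnimalCourse:
    """Simulate one animal's measurement course.

    Deterministic given (params, animal_id): the animal's RNG stream is
    derived from the master seed and a stable hash of the id.  Treated arms
    experience ``params.effect``; the vehicle arm grows untreated.  The
    course ends with the first observation at/over the cap (reason
    ``max_volume``) or at the horizon (``study_end``).
    """
    rng = _animal_rng(params.seed, animal_id)
    lo, hi = params.randomization_window
    if v0 is None:
        v0 = float(rng.uniform(lo, hi))
    g = params.growth_rate * float(_lognormal_factor(rng, params.rate_cv))
    effect = params.effect if arm != VEHICLE else NO_EFFECT
    latent = latent_trajectory(v0, g, effect, params.cycles, params.horizon_days)

    obs_days = [
        d for d in range(params.horizon_days + 1) if d % 7 in set(params.schedule)
    ]
    noise = _lognormal_factor(rng, params.noise_cv, size=len(obs_days))
    measurements: list[Measurement] = []
    endpoint = Endpoint(params.horizon_days, "study_end")
    for day, eps in zip(obs_days, noise):
        vol = max(latent[day] * float(eps), params.floor)
        measurements.append(Measurement(day, vol))
        if vol >= params.cap:
            endpoint = Endpoint(day, "max_volume")
            break
    dosing = params.cycles.dose_days() if arm != VEHICLE else []
    return AnimalCourse(
        animal_id=animal_id,
        model_id=model_id,
        arm=arm,
        measurements=measurements,
        dosing_days=dosing,
        endpoint=endpoint,
    )


def randomize_arms(itvs, arms: tuple[str, str] = (TREATED, VEHICLE)) -> list[str]:
    """Deterministic serpentine randomization by initial tumor volume.

    Volumes are sorted descending and assigned A,B,B,A,A,B,... (pairs with
    alternating order), which balances arm sizes to within one animal and
    arm means within the serpentine family; of the two serpentine phases the
    one with the smaller |mean(A) - mean(B)| wins (ties: A first).  Returns
    one arm label per input position.
    """
    itvs = np.asarray(itvs, dtype=float)
    if itvs.size < 2:
        raise ValidationError("randomize_arms: need >= 2 animals")
    order = np.argsort(-itvs, kind="stable")

    def serpentine(first: int) -> np.ndarray:
        # pattern over sorted positions: pairs (first, other), (other, first), ...
        pat = np.empty(itvs.size, dtype=int)
        for i in range(itvs.size):
            pair, pos = divmod(i, 2)
            pat[i] = (first ^ pos) if pair % 2 == 0 else (first ^ 1 ^ pos)
        return pat

    best = None
    for first in (0, 1):
        pat = serpentine(first)
        means = [itvs[order[pat == j]].mean() for j in (0, 1)]
        diff = abs(means[0] - means[1])
        if best is None or diff < best[0] - 1e-12:
            best = (diff, pat)
    assignment = np.empty(itvs.size, dtype=int)
    assignment[order] = best[1]
    return [arms[j] for j in assignment]


def _systematic_split(n_total: int, n_first: int) -> list[bool]:
    """Deterministic proportional interleave: True marks the first arm,
    spread evenly over the sorted sequence (largest-remainder walk)."""
    out, acc = [], 0.0
    frac = n_first / n_total
    for _ in range(n_total):
        acc += frac
        if acc >= 1.0 - 1e-12:
            out.append(True)
            acc -= 1.0
        else:
            out.append(False)
    return out


@dataclass(frozen=True)
class ClassPreset:
    """Treatment-effect settings guaranteed to land in one response class in
    the fully deterministic (zero-noise, zero rate-CV) regime."""

    name: str
    effect: TreatmentEffect
    growth_rate: float = 0.20


# Preset geometry (zero noise, g = 0.20/day, dosing day 1, cap 1200 mm^3):
#   PD1  mild early suppression: threshold crossed ~day 8 vs vehicle day 7
#        (TGD ~1.14 <= 1.5), no regression.
#   PD2  delayed-onset full cytostasis days 3-15: +82% by end of dosing but
#        crossing ~day 19 (TGD ~2.7 > 1.5).
#   SD   15% kill then full cytostasis through day 11: -15% at end of
#        dosing, no growth during the dosing window.
#   PR   70% kill, dormant a week: nadir ~37% of ITV (63% regression).
#   CR   95% kill, immediate regrowth: nadir ~6% of ITV but below 10% for
#        only ~2 days, under one vehicle doubling time (~3.5 days).
#   MCR  95% kill with cytostasis through day 25: sub-10% state sustained
#        for ~23 days, far beyond one doubling time.
PRESETS: dict[str, ClassPreset] = {
    p.name: p
    for p in [
        ClassPreset("PD1", TreatmentEffect(growth_suppression=0.20, suppression_days=5)),
        ClassPreset(
            "PD2",
            TreatmentEffect(growth_suppression=1.0, suppression_days=12, onset_day=2),
        ),
        ClassPreset(
            "SD",
            TreatmentEffect(
                kill_fraction=0.15,
                growth_suppression=1.0,
                suppression_days=12,
                onset_day=-1,
            ),
        ),
        ClassPreset(
            "PR",
            TreatmentEffect(
                kill_fraction=0.70, growth_suppression=1.0, suppression_days=6
            ),
        ),
        ClassPreset("CR", TreatmentEffect(kill_fraction=0.95)),
        ClassPreset(
            "MCR",
            TreatmentEffect(
                kill_fraction=0.95, growth_suppression=1.0, suppression_days=24
            ),
        ),
    ]
}


def simulate_cohort(
    preset: ClassPreset | str,
    n_treated: int,
    n_vehicle: int,
    noise_cv: float = 0.0,
    seed: int = 0,
    model_id: str | None = None,
    rate_cv: float | None = None,
    params: SimParams | None = None,
) -> tuple[CohortStudy, str]:
    """Simulate a full two-arm study under one class preset.

    Initial volumes are spread deterministically (evenly) over the
    randomization window, descending, and split between arms by serpentine
    randomization (or a proportional systematic walk when arm sizes differ
    by more than one).  ``noise_cv = 0`` selects the fully deterministic
    regime: the biological rate CV is also zeroed unless ``rate_cv`` is
    given explicitly.  Returns (study, ground-truth class name).
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValidationError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            ) from None
    if n_treated < 1 or n_vehicle < 1:
        raise ValidationError("simulate_cohort: need >= 1 animal per arm")
    if rate_cv is None:
        rate_cv = DEFAULT_RATE_CV if noise_cv > 0 else 0.0
    base = params or SimParams()
    base = replace(
        base,
        growth_rate=preset.growth_rate,
        effect=preset.effect,
        noise_cv=noise_cv,
        rate_cv=rate_cv,
        seed=seed,
    )
    model_id = model_id or f"SIM-{preset.name}"

    n = n_treated + n_vehicle
    lo, hi = base.randomization_window
    v0s = np.linspace(hi, lo, n)
    if abs(n_treated - n_vehicle) <= 1:
        arm_labels = randomize_arms(v0s)
        if arm_labels.count(TREATED) != n_treated:
            arm_labels = [
                VEHICLE if a == TREATED else TREATED for a in arm_labels
            ]
    else:
        marks = _systematic_split(n, n_treated)
        arm_labels = [TREATED if m else VEHICLE for m in marks]

    animals = []
    for i, (v0, arm) in enumerate(zip(v0s, arm_labels)):
        animals.append(
            simulate_animal(
                base,
                arm=arm,
                animal_id=f"{model_id}-{i + 1:03d}",
                model_id=model_id,
                v0=float(v0),
            )
        )
    study = CohortStudy(
        model_id=model_id,
        subtype_label=preset.name,
        animals=animals,
        cycle_schedule=base.cycles,
        thresholds=ResponseThresholds(),
    )
    return study, preset.name


def simulate_event_times(
    n_per_group: int,
    hazards: dict[str, float],
    censor_time: float | None = None,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Exponential event times per group with optional administrative
    censoring at ``censor_time``; seeded and deterministic."""
    if any(not h > 0 for h in hazards.values()):
        raise ValidationError("hazards must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(hazards):
        times = rng.exponential(1.0 / hazards[group], size=n_per_group)
        for t in times:
            if censor_time is not None and t > censor_time:
                records.append(SurvivalRecord(censor_time, False, group))
            else:
                records.append(SurvivalRecord(float(t), True, group))
    return records


def verify_presets() -> dict[str, str]:
    """Score every preset in the deterministic regime and return the map
    preset name -> model-level call (used as a build-time invariant)."""
    from .precist import score_study

    out = {}
    for name in PRESETS:
        study, truth = simulate_cohort(name, n_treated=3, n_vehicle=3, noise_cv=0.0,
                                       seed=0)
        _, summary = score_study(study)
        out[name] = summary["model_call"]
    return out
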