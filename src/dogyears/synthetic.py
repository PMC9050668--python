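"""Synthetic mortality registries with the structure the pipeline assumes.

The generator draws lifespans from a parametric age-specific hazard, attaches
them to birth dates drawn from a (possibly growing) birth process, and emits
a registry record only when the resulting death date falls inside the
observation window — the same deceased-only case definition the analysis
applies to real registries.  This makes every downstream stage testable with
no external data, and reproduces the *popularity-bias* mechanism: when the
birth process grows quickly, in-window deaths over-represent young animals
and the fitted life expectancy at age 0 is biased below the hazard's true
value.

Hazard forms
------------
``constant``
    rate λ; lifespans are exponential with mean 1/λ.
``gompertz_makeham``
    rate λ + a·e^{b t}: a baseline plus exponentially accelerating senescent
    mortality — the standard parametric shape for age-increasing mortality.
    Sampling is by exact inversion of the cumulative hazard (via the Lambert
    W function, evaluated in log space where the argument overflows).
``piecewise_interval``
    one death probability per year interval, uniform within the interval;
    the last interval must have probability 1.

The default demonstration schedule (λ = 0.01, a = 5e-4, b = 0.55) gives a
life expectancy at birth of about 11–12 years with a death-probability
profile that rises steeply after age 6, the shape seen in companion-dog
registries.  It is a demonstration configuration, not a fit to any dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, special

from .cohort import InclusionWindow
from .errors import ConfigurationError, DataError
from .records import DeathMechanism, DeathRecord, NeuterStatus, Sex

__all__ = [
    "HazardSchedule",
    "StratumSpec",
    "RegistryConfig",
    "sample_lifespans",
    "simulate_registry",
    "true_life_expectancy",
]


@dataclass(frozen=True)
class HazardSchedule:
    """Parametric or piecewise mortality model for one stratum."""

    form: str = "gompertz_makeham"  # constant | gompertz_makeham | piecewise_interval
    lam: float = 0.01       # baseline (Makeham) rate, per year
    a: float = 5e-4         # Gompertz level at age 0
    b: float = 0.55         # Gompertz slope, per year
    q: tuple[float, ...] = ()  # per-interval death probabilities (piecewise)
    label: str = "default"

    def __post_init__(self) -> None:
        if self.form not in ("constant", "gompertz_makeham", "piecewise_interval"):
            raise ConfigurationError(f"unknown hazard form {self.form!r}")
        if self.form == "piecewise_interval":
            if not self.q:
                raise ConfigurationError("piecewise schedule needs a q list")
            if any(not 0.0 <= qi <= 1.0 for qi in self.q):
                raise ConfigurationError("piecewise q values must lie in [0, 1]")
            if self.q[-1] != 1.0:
                raise ConfigurationError("last piecewise q must be 1 (everyone dies)")
        else:
            if self.lam < 0 or self.a < 0:
                raise ConfigurationError("hazard parameters must be non-negative")
            if self.form == "constant" and self.lam == 0:
                raise ConfigurationError("constant hazard must be positive")
            if self.form == "gompertz_makeham" and self.lam == 0 and self.a == 0:
                raise ConfigurationError("degenerate hazard: all components zero")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "constant":
            return np.full_like(t, self.lam)
        if self.form == "gompertz_makeham":
            return self.lam + self.a * np.exp(self.b * t)
        raise ConfigurationError("piecewise schedules have no continuous hazard")

    def cum_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "constant":
            return self.lam * t
        if self.form == "gompertz_makeham":
            if self.b == 0:
                return (self.lam + self.a) * t
            return self.lam * t + (self.a / self.b) * np.expm1(self.b * t)
        raise ConfigurationError("piecewise schedules have no continuous hazard")

    def survival(self, t):
        if self.form == "piecewise_interval":
            t = np.asarray(t, dtype=float)
            s = np.ones(len(self.q) + 1)
            s[1:] = np.cumprod(1.0 - np.asarray(self.q))
            k = np.clip(np.floor(t).astype(int), 0, len(self.q))
            frac = t - np.floor(t)
            qk = np.append(np.asarray(self.q), 0.0)[k]
            return s[k] * (1.0 - qk * frac)  # uniform deaths within interval
        return np.exp(-self.cum_hazard(t))


def _lambertw_safe(logz: np.ndarray) -> np.ndarray:
    """W(exp(logz)) for the principal branch, stable for huge logz."""
    logz = np.asarray(logz, dtype=float)
    w = np.empty_like(logz)
    small = logz < 50.0
    if small.any():
        w[small] = special.lambertw(np.exp(logz[small])).real
    big = ~small
    if big.any():
        # asymptotic start, then Newton on w + log w = logz
        lz = logz[big]
        wb = lz - np.log(lz)
        for _ in range(6):
            wb = wb - (wb + np.log(wb) - lz) / (1.0 + 1.0 / wb)
        w[big] = wb
    return w


def _invert_gm(u: np.ndarray, lam: float, a: float, b: float) -> np.ndarray:
    """Solve λt + (a/b)(e^{bt} − 1) = u for t ≥ 0."""
    if a == 0:
        return u / lam
    if b == 0:
        return u / (lam + a)
    c = a / b
    if lam == 0:
        return np.log1p(u / c) / b
    v = u + c
    logz = math.log(b * c / lam) + b * v / lam
    w = _lambertw_safe(logz)
    return v / lam - w / b


def sample_lifespans(
    schedule: HazardSchedule, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. lifespans from the schedule's survival law.

    Continuous-hazard forms invert the cumulative hazard at unit-exponential
    draws (exact inversion, no discretisation); the piecewise form draws the
    death interval from the interval probabilities and a uniform fraction
    within it, so the within-interval mean fraction is estimable.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if schedule.form == "piecewise_interval":
        q = np.asarray(schedule.q)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
        pmf = surv * q
        pmf = pmf / pmf.sum()  # q[-1] == 1 makes the law proper already
        k = rng.choice(len(q), size=n, p=pmf)
        return k + rng.random(n)
    u = rng.exponential(size=n)
    if schedule.form == "constant":
        return u / schedule.lam
    return _invert_gm(u, schedule.lam, schedule.a, schedule.b)


def true_life_expectancy(schedule: HazardSchedule, age: float = 0.0) -> float:
    """Analytic (or quadrature) expected residual life at ``age``.

    ``∫_age^∞ S(t) dt / S(age)``: closed form for the constant hazard
    (memorylessness gives 1/λ at every age), summation for piecewise
    schedules at integer ages, adaptive quadrature (absolute tolerance
    1e-8) for Gompertz–Makeham.
    """
    if age < 0:
        raise DataError("age must be >= 0")
    if schedule.form == "constant":
        return 1.0 / schedule.lam
    if schedule.form == "piecewise_interval":
        if age != int(age) or age >= len(schedule.q):
            raise DataError("piecewise expectancy is defined at integer ages in range")
        x = int(age)
        q = np.asarray(schedule.q)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
        pmf = surv * q
        num = sum(pmf[j] * (j + 0.5 - x) for j in range(x, len(q)))
        return float(num / surv[x])
    Hx = float(schedule.cum_hazard(age))

    def integrand(s: float) -> float:
        # cumulative hazard overflows for huge s; survival is then exactly 0
        with np.errstate(over="ignore"):
            dH = float(schedule.cum_hazard(age + s)) - Hx
        return math.exp(-dH) if np.isfinite(dH) else 0.0

    val, err = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200
    )
    if err > 1e-8:
        raise DataError(f"quadrature error {err:g} above tolerance")
    return float(val)


@dataclass(frozen=True)
class StratumSpec:
    """One simulated subpopulation: size, hazard and demographics."""

    name: str
    n: int
    schedule: HazardSchedule
    breed: str = ""
    female_prob: float = 0.5
    neutered_prob: float = 0.5


#: phrase families echoing the screening term lists, so simulated notes
#: contain true positives for the screen
_NOTE_PHRASES = (
    "euthanased at home with owner present",
    "PTS today, owner consent signed",
    "put to sleep peacefully this morning",
    "died at home overnight, owner informed us",
    "sadly deceased, condolence card sent",
    "owner collected ashes after cremation",
    "owner wishes to bury her at home",
)
_TREATMENT_PHRASES = (
    "euthatal 10ml iv",
    "pentobarbital injection",
    "cremation - individual",
    "beech casket ordered",
    "scatter tube",
)


@dataclass
class RegistryConfig:
    """Configuration of a simulated registry."""

    strata: list[StratumSpec]
    window: InclusionWindow = field(default_factory=InclusionWindow)
    birth_start: date = date(2000, 1, 1)
    birth_end: Optional[date] = None  # defaults to the window end
    growth_rate: float = 0.0  # per-year exponential growth of births
    missing_sex_rate: float = 0.0
    missing_date_rate: float = 0.0
    death_note_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ConfigurationError("registry config needs at least one stratum")
        for r in (self.missing_sex_rate, self.missing_date_rate, self.death_note_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"rate {r} outside [0, 1]")
        end = self.birth_end or self.window.end
        if self.birth_start >= end:
            raise ConfigurationError("birth_start must precede birth_end")


def _sample_birth_offsets(
    n: int, span_years: float, g: float, rng: np.random.Generator
) -> np.ndarray:
    """Birth times in years from the start of the birth span, density ∝ e^{g t}."""
    u = rng.random(n)
    if g == 0.0:
        return u * span_years
    return np.log1p(u * np.expm1(g * span_years)) / g


def simulate_registry(config: RegistryConfig) -> list[DeathRecord]:
    """Generate registry records; only in-window deaths are emitted.

    Deterministic under ``config.seed``.  Requested fractions of records get
    missing sex or a missing birth date; clinical notes and treatment lines
    carry phrases from the screening-term families.
    """
    rng = np.random.default_rng(config.seed)
    birth_end = config.birth_end or config.window.end
    span_years = (birth_end - config.birth_start).days / 365.25

    records: list[DeathRecord] = []
    serial = 0
    for spec in config.strata:
        births = _sample_birth_offsets(spec.n, span_years, config.growth_rate, rng)
        lifespans = sample_lifespans(spec.schedule, spec.n, rng)
        for i in range(spec.n):
            serial += 1
            birth = config.birth_start + timedelta(days=round(births[i] * 365.25))
            death = birth + timedelta(days=round(lifespans[i] * 365.25))
            if not config.window.contains(death):
                continue
            sex = Sex.FEMALE if rng.random() < spec.female_prob else Sex.MALE
            if rng.random() < config.missing_sex_rate:
                sex = Sex.UNKNOWN
            neuter = (
                NeuterStatus.NEUTERED
                if rng.random() < spec.neutered_prob
                else NeuterStatus.ENTIRE
            )
            birth_out: Optional[date] = birth
            if rng.random() < config.missing_date_rate:
                birth_out = None
            if rng.random() < config.death_note_rate:
                note = str(rng.choice(_NOTE_PHRASES))
                treatment = str(rng.choice(_TREATMENT_PHRASES))
                mech = (
                    DeathMechanism.EUTHANASED
                    if rng.random() < 0.85
                    else DeathMechanism.UNASSISTED
                )
            else:
                note, treatment, mech = "seen for routine vaccination", "", DeathMechanism.UNRECORDED
            records.append(
                DeathRecord(
                    animal_id=f"SIM{serial:07d}",
                    breed=spec.breed,
                    sex=sex,
                    neuter_status=neuter,
                    birth_date=birth_out,
                    death_date=death,
                    death_mechanism=mech,
                    clinical_note=note,
                    treatment_text=treatment,
                    insured=bool(rng.random() < 0.17),
                )
            )
    return records
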