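"""Cleaning, inclusion filtering, breed classification and stratification.

The analysis cohort is deceased-only: a record enters the cohort when its
death date lies inside the observation window (default 2016-01-01 to
2020-07-31), both dates are present, the lifespan is non-negative and sex is
recorded.  Exclusions are applied in a fixed order — outside window, negative
lifespan, missing birth/death information, missing sex — so exclusion logs
are reproducible; a record is counted once, under the first applicable
reason.

Lifespan is the day count between birth and death divided by 365.25, the
standard leap-safe epidemiological convention.

Breed handling is two-level: a breed recognised by any major kennel club is
"purebred" (everything else with a breed string is "crossbred"); purebred
breeds with a Kennel Club group assignment additionally carry that group
(Gundog, Hound, Pastoral, Terrier, Toy, Utility, Working), and recognised
breeds without one are "non-KC recognised".  The recognised-breed set and
group map are configuration, not code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ConfigurationError, DataError
from .records import CohortObservation, DeathRecord, Sex, UNCLASSIFIED

log = logging.getLogger(__name__)

__all__ = [
    "InclusionWindow",
    "ExclusionLog",
    "BreedLookup",
    "NON_KC_RECOGNISED",
    "compute_lifespan",
    "apply_inclusion_filters",
    "classify_breed",
    "load_breed_lookup",
    "default_breed_lookup",
    "stratify",
    "SCHEMES",
]

#: group label for purebred dogs whose breed has no Kennel Club group
NON_KC_RECOGNISED = "non-KC recognised"

#: supported stratification schemes
SCHEMES = ("overall", "sex", "sex_neuter", "kc_group", "breed")

#: reasons, in the fixed order they are applied
EXCLUSION_REASONS = (
    "outside_window",
    "negative_lifespan",
    "missing_birth_or_death",
    "missing_sex",
)


@dataclass(frozen=True)
class InclusionWindow:
    """Observation window for deaths; default is the 2016–2020 study window."""

    start: date = date(2016, 1, 1)
    end: date = date(2020, 7, 31)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"window start {self.start} after end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts plus a per-record reason list."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    reasons: list[tuple[str, str]] = field(default_factory=list)  # (animal_id, reason)
    n_input: int = 0
    n_included: int = 0

    def record(self, animal_id: str, reason: str) -> None:
        self.counts[reason] += 1
        self.reasons.append((animal_id, reason))

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def reconciles(self) -> bool:
        return self.n_included + self.n_excluded == self.n_input


def compute_lifespan(birth: date, death: date) -> float:
    """(death − birth) in days divided by 365.25; may be negative."""
    return (death - birth).days / 365.25


@dataclass(frozen=True)
class BreedLookup:
    """Recognised-breed set and breed→KC-group map (case-insensitive)."""

    recognised: frozenset[str]
    groups: Mapping[str, str]

    @staticmethod
    def _norm(breed: str) -> str:
        return " ".join(breed.split()).casefold()

    @classmethod
    def from_mapping(cls, recognised: Iterable[str], groups: Mapping[str, str]) -> "BreedLookup":
        return cls(
            recognised=frozenset(cls._norm(b) for b in recognised),
            groups={cls._norm(b): g for b, g in groups.items()},
        )


def load_breed_lookup(path: str | Path) -> BreedLookup:
    """Load a YAML breed classifier config with keys ``recognised_breeds``
    (list) and ``breed_groups`` (map breed → group)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "recognised_breeds" not in raw:
        raise ConfigurationError(f"breed lookup {path} must define recognised_breeds")
    recognised = raw["recognised_breeds"]
    groups = raw.get("breed_groups", {})
    if not isinstance(recognised, list) or not isinstance(groups, dict):
        raise ConfigurationError(f"malformed breed lookup {path}")
    return BreedLookup.from_mapping(recognised, groups)


def default_breed_lookup() -> BreedLookup:
    """The small packaged lookup covering the worked-example breeds."""
    return load_breed_lookup(str(resources.files("dogyears.data") / "breed_groups.yaml"))


def classify_breed(breed: str, lookup: BreedLookup) -> tuple[str, str]:
    """Classify a free-text breed into ``(purity, kc_group)``.

    purity ∈ {purebred, crossbred, unrecorded}; kc_group is a Kennel Club
    group, ``"non-KC recognised"`` for recognised breeds without a group, or
    ``"n/a"`` when there is no breed / the breed is crossbred.
    """
    key = BreedLookup._norm(breed)
    if not key:
        return "unrecorded", "n/a"
    if key in lookup.recognised:
        return "purebred", lookup.groups.get(key, NON_KC_RECOGNISED)
    return "crossbred", "n/a"


def _first_exclusion(rec: DeathRecord, window: InclusionWindow) -> Optional[str]:
    if rec.death_date is not None and not window.contains(rec.death_date):
        return "outside_window"
    if (
        rec.birth_date is not None
        and rec.death_date is not None
        and rec.death_date < rec.birth_date
    ):
        return "negative_lifespan"
    if rec.birth_date is None or rec.death_date is None:
        return "missing_birth_or_death"
    if rec.sex is Sex.UNKNOWN:
        return "missing_sex"
    return None


def apply_inclusion_filters(
    records: Sequence[DeathRecord],
    window: InclusionWindow = InclusionWindow(),
    lookup: Optional[BreedLookup] = None,
) -> tuple[list[CohortObservation], ExclusionLog]:
    """Apply the cleaning rules and build the analysis cohort.

    Survivors get a fractional lifespan and stratum labels (sex, neuter
    status, sex×neuter, breed purity, KC group, breed).  All problems become
    exclusions, never errors; the log reconciles exactly with the input size.
    """
    lookup = lookup or default_breed_lookup()
    excl = ExclusionLog(n_input=len(records))
    cohort: list[CohortObservation] = []
    for rec in records:
        reason = _first_exclusion(rec, window)
        if reason is not None:
            excl.record(rec.animal_id, reason)
            continue
        lifespan = compute_lifespan(rec.birth_date, rec.death_date)
        purity, kc_group = classify_breed(rec.breed, lookup)
        sex = rec.sex.value
        neuter = rec.neuter_status.value
        strata = {
            "overall": "all",
            "sex": sex,
            "neuter": neuter,
            "sex_neuter": (
                f"{sex}_{neuter}" if neuter != "unknown" else UNCLASSIFIED
            ),
            "purity": purity,
            "kc_group": kc_group if kc_group != "n/a" else UNCLASSIFIED,
            "breed": (
                rec.breed.strip()
                if purity == "purebred"
                else "crossbred" if purity == "crossbred" else UNCLASSIFIED
            ),
        }
        cohort.append(
            CohortObservation(
                animal_id=rec.animal_id, lifespan_years=lifespan, strata=strata
            )
        )
    excl.n_included = len(cohort)
    assert excl.reconciles(), "exclusion log must reconcile with input size"
    log.info(
        "cohort: %d included, %d excluded %s",
        excl.n_included,
        excl.n_excluded,
        excl.counts,
    )
    return cohort, excl


def stratify(
    cohort: Sequence[CohortObservation], schemes: Sequence[str]
) -> dict[str, dict[str, list[CohortObservation]]]:
    """Partition the cohort by each requested scheme.

    Within a scheme the labels are disjoint and their union is every animal
    carrying a usable label; animals labelled ``unknown``/``unclassified``
    (or ``non-KC recognised``-adjacent sentinels) stay in the cohort but are
    excluded from that scheme only.
    """
    out: dict[str, dict[str, list[CohortObservation]]] = {}
    for scheme in schemes:
        if scheme not in SCHEMES:
            raise ConfigurationError(
                f"unknown stratification scheme {scheme!r}; expected one of {SCHEMES}"
            )
        groups: dict[str, list[CohortObservation]] = {}
        for obs in cohort:
            label = obs.strata.get(scheme, UNCLASSIFIED)
            if label in (UNCLASSIFIED, "unknown"):
                continue
            groups.setdefault(label, []).append(obs)
        out[scheme] = groups
    return out
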