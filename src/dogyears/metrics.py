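"""Derived longevity metrics and cross-stratum comparison reports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import CohortObservation, LifeTable

__all__ = [
    "ThresholdCrossing",
    "age_when_e_below",
    "compare_strata",
    "demography_summary",
]


@dataclass(frozen=True)
class ThresholdCrossing:
    """First age interval at which life expectancy drops strictly below a
    threshold.  ``interval`` is the interval start ``x`` (the crossing lies
    in ``[x, x+1)``), or ``None`` when no row ever crosses."""

    threshold: float
    interval: Optional[int]

    @property
    def crossed(self) -> bool:
        return self.interval is not None

    def label(self) -> str:
        if self.interval is None:
            return "never"
        return f"{self.interval}–{self.interval + 1}"


def age_when_e_below(table: LifeTable, threshold: float = 1.5) -> ThresholdCrossing:
    """Earliest interval with ``e_x < threshold`` (strict: a tie does not
    cross).  1.5 years is the conventional default because published breed
    tables all end below that value, so a valid table always crosses."""
    for row in table.rows:
        if row.e_hat < threshold:
            return ThresholdCrossing(threshold=threshold, interval=row.x)
    return ThresholdCrossing(threshold=threshold, interval=None)


def compare_strata(
    tables: Mapping[str, LifeTable],
    ages: Sequence[int] = (),
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Cross-stratum comparison table, one row per stratum label.

    Columns: number of animals, ``e_0`` with its bounds, rank at age 0
    (1 = longest-lived), the table's last age and ``e`` there, the interval
    where ``e`` drops below ``threshold``, and ``e`` at each requested age
    (NaN where a table ends earlier).  Row order follows descending ``e_0``;
    the content is invariant to the order of ``tables``.
    """
    recs = []
    for label, tbl in tables.items():
        last = tbl.rows[-1]
        rec = {
            "label": label,
            "n": tbl.n_animals,
            "e0": tbl.e(0),
            "e0_lo": tbl.rows[0].e_lo,
            "e0_hi": tbl.rows[0].e_hi,
            "last_age": last.x,
            "e_last": last.e_hat,
            "below_threshold": age_when_e_below(tbl, threshold).label(),
        }
        for age in ages:
            rec[f"e{age}"] = tbl.e(age) if age <= tbl.final_open_start else float("nan")
        recs.append(rec)
    df = pd.DataFrame.from_records(recs).sort_values(
        ["e0", "label"], ascending=[False, True], kind="mergesort"
    )
    df["rank_e0"] = range(1, len(df) + 1)
    return df.set_index("label")


#: labels that drop an animal from a scheme's denominator
_EXCLUDED_LABELS = {
    "sex": {"unknown"},
    "neuter": {"unknown"},
    "sex_neuter": {"unclassified"},
    "purity": set(),  # 'unrecorded' is a reported category
    "kc_group": {"unclassified", "non-KC recognised"},
}


def demography_summary(
    cohort: Sequence[CohortObservation],
    schemes: Sequence[str] = ("sex", "neuter", "sex_neuter", "purity", "kc_group"),
) -> pd.DataFrame:
    """Counts and 1-dp percentages per stratum label.

    Percentages are taken within each scheme's reporting denominator: animals
    whose label in that scheme is a real category (e.g. KC-group percentages
    are among dogs of KC-grouped breeds only, while 'unrecorded' breed is
    itself reported within purity).  An empty cohort yields an empty frame.
    """
    recs = []
    for scheme in schemes:
        excluded = _EXCLUDED_LABELS.get(scheme, {"unknown", "unclassified"})
        labels = [
            obs.strata.get(scheme, "unclassified")
            for obs in cohort
            if obs.strata.get(scheme, "unclassified") not in excluded
        ]
        denom = len(labels)
        if denom == 0:
            continue
        counts = pd.Series(labels).value_counts().sort_index()
        for label, count in counts.items():
            recs.append(
                {
                    "scheme": scheme,
                    "label": label,
                    "count": int(count),
                    "denominator": denom,
                    "percent": round(100.0 * count / denom, 1),
                }
            )
    return pd.DataFrame.from_records(
        recs, columns=["scheme", "label", "count", "denominator", "percent"]
    )
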