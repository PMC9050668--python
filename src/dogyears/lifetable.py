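"""Complete cohort life tables with an open final interval.

The estimator works on exact ages at death of a fully-observed (deceased-only)
cohort.  Deaths are binned into one-year intervals ``[x, x+1)``; for each
interval the table records

* ``d_x``  — deaths in the interval,
* ``l_x``  — animals alive at exact age ``x`` (``l_x = sum_{i>=x} d_i``),
* ``q_x``  — conditional probability of dying in the interval, ``d_x / l_x``,
* ``a_x``  — mean fraction of the last year of life lived by those dying in
  the interval, ``mean(t - x)`` over their lifespans ``t``,
* ``L_x``  — animal-years lived in the interval, ``(l_x - d_x) + a_x * d_x``,
* ``T_x``  — animal-years lived beyond ``x`` (tail sum of ``L``),
* ``e_x``  — life expectancy at ``x``, ``T_x / l_x``.

The final interval ``[n, inf)`` is open: it pools every death at age ``n`` or
later, so ``l_n = d_n``, ``q_n = 1``, ``a_n = mean(t - n)`` (which may exceed
one year), ``L_n = a_n * d_n`` and ``e_n = a_n``.

A telescoping identity makes ``e_x`` exactly the mean residual lifespan of
survivors to ``x``: ``T_x = sum_{t >= x} (t - x)`` over all lifespans at
least ``x``, so ``e_0`` is the cohort mean age at death.

Strata are only published when they satisfy an eligibility rule: every closed
interval must contain at least ``min_per_interval`` deaths (default 3, so the
``a`` average has a denominator above 1) and the open interval at least
``min_last_interval`` deaths (default 11, stabilising the tail on which every
``e_x`` depends).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import DataError
from .records import CohortObservation, LifeTable, LifeTableRow

__all__ = [
    "EligibilityRule",
    "assign_intervals",
    "choose_final_interval",
    "build_life_table",
    "build_from_aggregates",
]


@dataclass(frozen=True)
class EligibilityRule:
    """Minimum death counts required for a stratum's table to be published."""

    min_per_interval: int = 3
    min_last_interval: int = 11

    def __post_init__(self) -> None:
        if self.min_per_interval < 1 or self.min_last_interval < 1:
            raise DataError("eligibility thresholds must be >= 1")


DEFAULT_RULE = EligibilityRule()


def _as_lifespans(cohort) -> np.ndarray:
    if len(cohort) and isinstance(cohort[0], CohortObservation):
        arr = np.asarray([c.lifespan_years for c in cohort], dtype=float)
    else:
        arr = np.asarray(cohort, dtype=float)
    if arr.size and arr.min() < 0:
        raise DataError(f"negative lifespan {arr.min()} reached the life-table builder")
    return arr


def assign_intervals(lifespans: Sequence[float]) -> dict[int, list[float]]:
    """Bin lifespans into one-year intervals, keeping within-interval fractions.

    A lifespan ``t`` falls in interval ``x = floor(t)`` with fraction
    ``t - x`` (half-open convention: integer lifespans carry fraction 0).
    """
    arr = _as_lifespans(lifespans)
    out: dict[int, list[float]] = {}
    for t in arr:
        x = int(math.floor(t))
        out.setdefault(x, []).append(t - x)
    return out


def choose_final_interval(
    counts: Mapping[int, int], rule: EligibilityRule = DEFAULT_RULE
) -> tuple[Optional[int], bool]:
    """Pick the start ``n`` of the open final interval and judge eligibility.

    ``n`` is the largest age such that the pooled tail ``sum_{i>=n} d_i``
    still holds at least ``rule.min_last_interval`` deaths.  The stratum is
    eligible iff such an ``n`` exists and every closed interval ``0..n-1``
    holds at least ``rule.min_per_interval`` deaths.

    Returns ``(n, eligible)``; when no tail reaches the floor, ``n`` falls
    back to the oldest observed interval and ``eligible`` is False.
    """
    if not counts:
        raise DataError("cannot choose a final interval from empty counts")
    x_max = max(counts)
    d = np.zeros(x_max + 1, dtype=int)
    for x, c in counts.items():
        if x < 0:
            raise DataError(f"negative age interval {x}")
        d[x] = c
    tail = d[::-1].cumsum()[::-1]
    meets = np.nonzero(tail >= rule.min_last_interval)[0]
    if meets.size == 0:
        return x_max, False
    n = int(meets[-1])
    eligible = bool((d[:n] >= rule.min_per_interval).all())
    return n, eligible


def _assemble(
    d: np.ndarray,
    a_sum: np.ndarray,
    a_defined: np.ndarray,
    n: int,
    stratum: Optional[dict[str, str]],
    eligible: bool,
) -> LifeTable:
    """Common table assembly from per-interval deaths and fraction sums.

    ``d`` and ``a_sum`` must already be pooled: length ``n + 1`` with the
    last entry the open interval, ``a_sum[x]`` the sum of ``(t - x)`` over
    its members.
    """
    l = d[::-1].cumsum()[::-1]
    n_animals = int(l[0])
    rows: list[LifeTableRow] = []
    L = np.empty(len(d), dtype=float)
    for x in range(len(d)):
        if x == n:  # open interval: l == d, everyone dies here
            L[x] = a_sum[x]
        elif a_defined[x]:
            L[x] = (l[x] - d[x]) + a_sum[x]
        else:  # no deaths: a undefined, everyone lives the full year
            L[x] = float(l[x])
    T = L[::-1].cumsum()[::-1]
    for x in range(len(d)):
        dx, lx = int(d[x]), int(l[x])
        q = dx / lx if lx > 0 else float("nan")
        if x == n:
            a = a_sum[x] / dx if dx > 0 else None
        else:
            a = a_sum[x] / dx if a_defined[x] and dx > 0 else None
        e = T[x] / lx if lx > 0 else float("nan")
        rows.append(
            LifeTableRow(x=x, d=dx, l=lx, q_hat=q, a_hat=a, L=float(L[x]), T=float(T[x]), e_hat=e)
        )
    return LifeTable(
        stratum=dict(stratum or {}),
        rows=rows,
        final_open_start=n,
        eligible=eligible,
        n_animals=n_animals,
    )


def build_life_table(
    cohort: Sequence[float] | Sequence[CohortObservation],
    rule: EligibilityRule = DEFAULT_RULE,
    stratum: Optional[dict[str, str]] = None,
) -> LifeTable:
    """Build the cohort life table from individual lifespans.

    An ineligible cohort still yields a table — flagged ``eligible=False`` —
    so callers (notably the bootstrap, which must judge eligibility per
    resample) need no exception handling; publication gates on the flag.
    """
    t = _as_lifespans(cohort)
    if t.size == 0:
        raise DataError("cannot build a life table from an empty cohort")
    x_all = np.floor(t).astype(int)
    counts = np.bincount(x_all)
    n, eligible = choose_final_interval(
        {x: int(c) for x, c in enumerate(counts) if c}, rule
    )
    # pool ages >= n into the open interval
    x_pooled = np.minimum(x_all, n)
    d = np.bincount(x_pooled, minlength=n + 1).astype(float)
    a_sum = np.bincount(x_pooled, weights=t - x_pooled, minlength=n + 1)
    a_defined = d > 0
    return _assemble(d, a_sum, a_defined, n, stratum, eligible)


def build_from_aggregates(
    d: Sequence[int],
    a_hat: Sequence[float],
    stratum: Optional[dict[str, str]] = None,
    rule: EligibilityRule = DEFAULT_RULE,
) -> LifeTable:
    """Rebuild a life table from published per-interval ``d`` and ``a``.

    The last entry is taken as the open final interval.  ``l``, ``q``, ``L``,
    ``T`` and ``e`` are derived exactly as in :func:`build_life_table`; this
    is the route for reproducing a printed table from its two primitive
    columns.
    """
    d_arr = np.asarray(d, dtype=float)
    a_arr = np.asarray(a_hat, dtype=float)
    if d_arr.shape != a_arr.shape:
        raise DataError(f"length mismatch: {d_arr.size} death counts vs {a_arr.size} a values")
    if d_arr.size == 0:
        raise DataError("cannot build a life table from empty aggregates")
    if (d_arr < 0).any():
        raise DataError("negative death count")
    if ((d_arr == 0) & ~np.isnan(a_arr)).any():
        raise DataError("a_hat supplied for an interval with d = 0")
    n = d_arr.size - 1
    a_defined = ~np.isnan(a_arr) & (d_arr > 0)
    a_sum = np.where(a_defined, a_arr * d_arr, 0.0)
    eligible = bool(
        (d_arr[:-1] >= rule.min_per_interval).all() and d_arr[-1] >= rule.min_last_interval
    )
    return _assemble(d_arr, a_sum, a_defined, n, stratum, eligible)
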