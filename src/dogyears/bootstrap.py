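"""Empirical bootstrap confidence intervals for life expectancy.

The resampling unit is the individual animal: each iteration draws ``n``
animals with replacement from the cohort, rebuilds the complete life table
(including its own open-final-interval choice) and is *accepted* only if the
rebuilt table satisfies the eligibility rule; rejected iterations are
discarded, not replaced (a top-up mode that redraws until the requested
number of accepted iterations is reached is available but off by default).
Per-age bounds are empirical quantiles of the accepted replicates of
``e_x``.  Gating presumes an eligible stratum: when the cohort's own
point-estimate table is ineligible the rule is evidently not in force for
it, so every iteration is kept (with a log note).

Because the life table depends on the resample only through the multiset of
lifespans, resampling individuals is distributionally identical to drawing a
multinomial over the distinct lifespan values with probabilities
proportional to their multiplicities.  The implementation exploits this:
replicate death counts and lifespan sums per age interval come from one
multinomial draw and two matrix products, which makes 10,000 iterations on a
30k-animal cohort a matter of seconds.

Replicate tables can end at an earlier age than the point-estimate table
(the open interval moves down when the resampled tail thins out).  Ages
present in fewer than half of the accepted replicates get no bounds —
quantiles over a vanishing support are not meaningful — with a log note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, EstimationError
from .lifetable import DEFAULT_RULE, EligibilityRule, build_life_table, _as_lifespans
from .records import LifeTable

log = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "percentile_bounds", "bootstrap_life_table"]

#: minimum fraction of accepted replicates in which an age must appear
#: for its quantile bounds to be reported
MIN_AGE_SUPPORT = 0.5


def percentile_bounds(samples: Sequence[float], level: float) -> tuple[float, float]:
    """Central ``level`` empirical interval of ``samples``.

    Quantile rule: linear interpolation between order statistics (the
    conventional "type 7" definition).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise DataError("cannot take percentile bounds of an empty sample")
    if not 0.0 < level < 1.0:
        raise DataError(f"confidence level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    """Accepted replicate trajectories of ``e_x`` plus per-age bounds."""

    ages: list[int]
    replicates: np.ndarray  # (accepted, n_ages), NaN where a replicate table ended
    e_lo: dict[int, Optional[float]]
    e_hi: dict[int, Optional[float]]
    iterations_attempted: int
    iterations_accepted: int
    seed: int
    level: float
    method: str = "percentile"
    point: Optional[LifeTable] = None
    unsupported_ages: list[int] = field(default_factory=list)

    def apply_to(self, table: LifeTable) -> LifeTable:
        """Attach the bounds to a table's rows in place (and return it)."""
        for row in table.rows:
            row.e_lo = self.e_lo.get(row.x)
            row.e_hi = self.e_hi.get(row.x)
        return table


def _replicate_tables(
    vals: np.ndarray,
    probs: np.ndarray,
    n: int,
    n_draw: int,
    rule: EligibilityRule,
    n_ages: int,
    rng: np.random.Generator,
    gate: bool,
) -> np.ndarray:
    """Draw ``n_draw`` bootstrap replicates; return an (n_draw, n_ages)
    array of ``e_x`` trajectories with NaN rows for rejected iterations and
    NaN beyond each replicate's own final interval."""
    intervals = np.floor(vals).astype(int)
    k_max = int(intervals.max())
    onehot = np.zeros((vals.size, k_max + 1))
    onehot[np.arange(vals.size), intervals] = 1.0

    counts = rng.multinomial(n, probs, size=n_draw).astype(float)
    D = counts @ onehot                      # deaths per interval
    S = (counts * vals) @ onehot             # summed lifespans per interval

    out = np.full((n_draw, n_ages), np.nan)
    for b in range(n_draw):
        d = D[b]
        tail = d[::-1].cumsum()[::-1]
        meets = np.nonzero(tail >= rule.min_last_interval)[0]
        if meets.size:
            nfin = int(meets[-1])
        elif gate:
            continue
        else:  # ungated fallback: open row starts at the oldest death
            nfin = int(np.nonzero(d)[0][-1])
        if gate and nfin > 0 and d[:nfin].min() < rule.min_per_interval:
            continue
        s = S[b]
        # pool ages >= nfin into the open row
        d_p = np.concatenate([d[:nfin], [tail[nfin]]])
        s_p = np.concatenate([s[:nfin], [s[nfin:].sum()]])
        l = d_p[::-1].cumsum()[::-1]
        x_idx = np.arange(nfin + 1, dtype=float)
        asum = s_p - x_idx * d_p
        L = (l - d_p) + asum
        L[-1] = asum[-1]
        T = L[::-1].cumsum()[::-1]
        e = T / l
        m = min(nfin + 1, n_ages)
        out[b, :m] = e[:m]
    return out


def bootstrap_life_table(
    cohort,
    rule: EligibilityRule = DEFAULT_RULE,
    iterations: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
    topup: bool = False,
) -> BootstrapResult:
    """Eligibility-gated bootstrap of the life table.

    Parameters
    ----------
    cohort
        Lifespans (or :class:`~dogyears.records.CohortObservation` list) of
        an eligible stratum.
    rule
        Eligibility rule applied to every replicate table.
    iterations, level, seed
        Number of resamples, central interval mass, RNG seed.  A fixed seed
        gives bit-reproducible bounds.
    method
        ``"percentile"`` (default) or ``"basic"`` (the pivotal interval
        ``2·ê − q_{1−α}``, ``2·ê − q_α``).
    topup
        If True, rejected iterations are redrawn until ``iterations``
        accepted replicates exist (capped at 10× the requested count).
    """
    if method not in ("percentile", "basic"):
        raise DataError(f"unknown CI method {method!r}")
    if iterations < 1:
        raise DataError("iterations must be >= 1")
    if not 0.0 < level < 1.0:
        raise DataError(f"confidence level must be in (0, 1), got {level}")

    t = _as_lifespans(cohort)
    if t.size == 0:
        raise DataError("cannot bootstrap an empty cohort")
    point = build_life_table(t, rule=rule)
    ages = point.ages
    n_ages = len(ages)

    vals, mult = np.unique(t, return_counts=True)
    probs = mult / t.size
    rng = np.random.default_rng(seed)

    # Per-iteration acceptance gating presumes the stratum satisfies the
    # rule in the first place; for an ineligible cohort the rule is not in
    # force and every iteration is kept.
    gate = point.eligible
    if not gate:
        log.info("point-estimate table ineligible: replicate gating disabled")

    reps = _replicate_tables(vals, probs, t.size, iterations, rule, n_ages, rng, gate)
    attempted = iterations
    accepted_mask = ~np.isnan(reps[:, 0])
    if topup:
        max_attempts = 10 * iterations
        while accepted_mask.sum() < iterations and attempted < max_attempts:
            extra = min(iterations - int(accepted_mask.sum()), max_attempts - attempted)
            more = _replicate_tables(vals, probs, t.size, extra, rule, n_ages, rng, gate)
            attempted += extra
            reps = np.vstack([reps, more])
            accepted_mask = ~np.isnan(reps[:, 0])

    accepted = reps[accepted_mask]
    n_acc = accepted.shape[0]
    if n_acc == 0:
        raise EstimationError(
            f"all {attempted} bootstrap iterations rejected by the eligibility rule"
        )
    if n_acc < attempted:
        log.info(
            "bootstrap: %d of %d iterations rejected as ineligible",
            attempted - n_acc,
            attempted,
        )

    alpha = (1.0 - level) / 2.0
    e_lo: dict[int, Optional[float]] = {}
    e_hi: dict[int, Optional[float]] = {}
    unsupported: list[int] = []
    for j, x in enumerate(ages):
        col = accepted[:, j]
        col = col[~np.isnan(col)]
        if col.size < MIN_AGE_SUPPORT * n_acc:
            e_lo[x] = e_hi[x] = None
            unsupported.append(x)
            continue
        qlo, qhi = np.quantile(col, [alpha, 1.0 - alpha], method="linear")
        if method == "basic":
            ehat = point.e(x)
            qlo, qhi = 2 * ehat - qhi, 2 * ehat - qlo
        e_lo[x], e_hi[x] = float(qlo), float(qhi)
        ehat = point.e(x)
        if not (e_lo[x] <= ehat <= e_hi[x]):
            log.warning(
                "bootstrap interval at age %d (%.4f, %.4f) excludes the point "
                "estimate %.4f",
                x, e_lo[x], e_hi[x], ehat,
            )
    if unsupported:
        log.info(
            "no bounds for ages %s: present in fewer than %d%% of accepted replicates",
            unsupported, int(MIN_AGE_SUPPORT * 100),
        )

    return BootstrapResult(
        ages=ages,
        replicates=accepted,
        e_lo=e_lo,
        e_hi=e_hi,
        iterations_attempted=attempted,
        iterations_accepted=n_acc,
        seed=seed,
        level=level,
        method=method,
        point=point,
    )
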