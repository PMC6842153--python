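"""One-way ANOVA and Bonferroni-adjusted pairwise comparisons of item weights.

Within a category, each accepted participant contributes a complete priority
vector, so every item (group) has the same number of percent-weight
replicates.  The analysis follows the classical fixed-effects recipe: a
one-way ANOVA F test across the k items, then all k(k-1)/2 pairwise
two-sided t tests using the pooled within-group (residual) variance, with
Bonferroni multiplication of the raw p-values.

Note that weights within one participant are compositional (they sum to
100) and therefore not truly independent across items; a warning to this
effect is emitted once per sample.  The analysis is nevertheless performed
as specified, treating participants as independent replicates per item.

Significance stars use strict thresholds on the adjusted p-value:
``****`` < 0.0001, ``***`` < 0.001, ``**`` < 0.01, ``*`` < 0.05, else ``ns``.
A p-value of exactly 0.05 is not significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .ahp import GroupWeightTable
from .exceptions import DegenerateDataError, ValidationError

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_for(adjusted_p: float) -> str:
    """Star code for an adjusted p-value (strict thresholds)."""
    if not 0.0 <= adjusted_p <= 1.0:
        raise ValidationError(f"p-value {adjusted_p} outside [0, 1]")
    for threshold, code in STAR_THRESHOLDS:
        if adjusted_p < threshold:
            return code
    return "ns"


@dataclass(frozen=True)
class WeightSample:
    """Per-participant percent weights for the k items of one category.

    ``weights[r, i]`` is replicate (participant) r's weight for item i; the
    design is balanced because every participant supplies a full vector.
    """

    category: str
    item_ids: tuple[str, ...]
    weights: np.ndarray  # (n_replicates, k)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(self.item_ids):
            raise ValidationError(
                f"weights shape {w.shape} does not match {len(self.item_ids)} items"
            )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @classmethod
    def from_table(cls, table: GroupWeightTable) -> "WeightSample":
        return cls(
            category=table.category,
            item_ids=table.item_ids,
            weights=table.participant_weights_pct,
        )

    @property
    def k(self) -> int:
        return len(self.item_ids)

    @property
    def n_replicates(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class ComparisonResult:
    item_a: str
    item_b: str
    mean_diff: float
    t_statistic: float
    raw_p: float
    adjusted_p: float
    stars: str


def _check_sample(sample: WeightSample) -> None:
    if sample.k < 2:
        raise ValidationError("need at least 2 items (groups) to compare")
    if sample.n_replicates < 2:
        raise ValidationError("need at least 2 replicates per item")
    if np.allclose(sample.weights.var(axis=0, ddof=1), 0.0):
        raise DegenerateDataError(
            "zero within-group variance in every group; F is undefined"
        )
    warnings.warn(
        "weights within a participant sum to 100 and are not independent "
        "across items; ANOVA treats them as independent replicates",
        stacklevel=3,
    )


def oneway_anova(sample: WeightSample) -> tuple[float, float]:
    """Classical one-way ANOVA over the k items.

    Returns (F, p) with (k-1, N-k) degrees of freedom, N = k * replicates.
    """
    _check_sample(sample)
    groups = [sample.weights[:, i] for i in range(sample.k)]
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def bonferroni_pairwise(
    sample: WeightSample, welch: bool = False
) -> list[ComparisonResult]:
    """All pairwise two-sided t tests with Bonferroni adjustment.

    By default each test uses the pooled within-group variance from the
    ANOVA residual with N-k degrees of freedom (the classical Bonferroni
    post-hoc).  ``welch=True`` switches to per-pair Welch tests instead.
    Adjusted p = min(1, raw_p * m) with m = k(k-1)/2.
    """
    _check_sample(sample)
    w = sample.weights
    k, n = sample.k, sample.n_replicates
    m = k * (k - 1) // 2
    means = w.mean(axis=0)
    if not welch:
        ssw = float(((w - means) ** 2).sum())
        df = k * n - k
        mse = ssw / df
    results = []
    for i, j in combinations(range(k), 2):
        if welch:
            t, raw_p = stats.ttest_ind(w[:, i], w[:, j], equal_var=False)
            t, raw_p = float(t), float(raw_p)
        else:
            se = np.sqrt(mse * (2.0 / n))
            t = float((means[i] - means[j]) / se)
            raw_p = float(2.0 * stats.t.sf(abs(t), df))
        adj = min(1.0, raw_p * m)
        results.append(
            ComparisonResult(
                item_a=sample.item_ids[i],
                item_b=sample.item_ids[j],
                mean_diff=float(means[i] - means[j]),
                t_statistic=t,
                raw_p=raw_p,
                adjusted_p=adj,
                stars=stars_for(adj),
            )
        )
    return results
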