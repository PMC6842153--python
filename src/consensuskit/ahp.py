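"""Analytic Hierarchy Process: priorities, consistency, and group aggregation.

Given a positive reciprocal pairwise comparison matrix (PCM) ``A`` with
entries on the Saaty 1-9 scale (a_ij = how many times more important item i
is than item j), the priority vector is the principal right eigenvector of
``A`` normalised to sum to 1, computed here by power iteration.  The
principal eigenvalue lambda_max >= n measures inconsistency through

    CI = (lambda_max - n) / (n - 1),      CR = CI / RI(n),

where RI(n) is the mean CI of random reciprocal matrices of size n (Saaty's
random-index table).  Matrices with CR < 0.1 are accepted; anything at or
above 0.1 is rejected as too inconsistent and excluded from group
aggregation.

Group priorities use aggregation of individual priorities (AIP): the
accepted participants' priority vectors are averaged item-wise on the
percent scale, which guarantees the per-category means sum to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .exceptions import ConvergenceError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

#: Saaty's random-index table, RI(n) for n = 1..15.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}
#: Flat extrapolation used for n = 16 when explicitly enabled.
RI_EXTRAPOLATED = 1.60

#: The admissible judgment values: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_SCALE = np.array(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)

CR_THRESHOLD = 0.1


def parse_judgment(value: float | int | str) -> float:
    """Parse a judgment given as a number or a fraction string like ``"1/3"``."""
    if isinstance(value, str):
        try:
            value = float(Fraction(value.strip()))
        except (ValueError, ZeroDivisionError) as exc:
            raise ValidationError(f"cannot parse judgment {value!r}") from exc
    return float(value)


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """One participant's reciprocal judgments over one category's items."""

    participant_id: str
    category: str
    item_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        m = validate_pcm(self.matrix)
        if m.shape[0] != len(self.item_ids):
            raise ValidationError(
                f"matrix is {m.shape[0]}x{m.shape[0]} but {len(self.item_ids)} "
                f"item ids were given"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.item_ids)


def validate_pcm(raw, reciprocity_rtol: float = 1e-9) -> np.ndarray:
    """Validate a square positive reciprocal matrix on the Saaty domain.

    Returns a float array with unit diagonal.  Entries must lie in
    [1/9, 9]; off-diagonal pairs must satisfy a_ji = 1/a_ij to within
    ``reciprocity_rtol`` relative tolerance.
    """
    m = np.asarray(raw, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"pairwise matrix must be square, got shape {m.shape}")
    n = m.shape[0]
    if n < 2:
        raise ValidationError("pairwise matrix needs at least 2 items")
    for i in range(n):
        for j in range(n):
            v = m[i, j]
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"non-positive entry at cell ({i + 1},{j + 1}): {v}")
            if not (1.0 / 9 - 1e-12 <= v <= 9.0 + 1e-12):
                raise ValidationError(
                    f"entry outside the Saaty domain [1/9, 9] at cell "
                    f"({i + 1},{j + 1}): {v}"
                )
    if not np.allclose(np.diag(m), 1.0, rtol=0, atol=1e-12):
        i = int(np.argmax(np.abs(np.diag(m) - 1.0)))
        raise ValidationError(f"diagonal entry at ({i + 1},{i + 1}) must be 1")
    for i in range(n):
        for j in range(i + 1, n):
            if abs(m[j, i] * m[i, j] - 1.0) > reciprocity_rtol * max(1.0, abs(m[j, i] * m[i, j])):
                raise ValidationError(
                    f"reciprocity violation at cell ({j + 1},{i + 1}): "
                    f"{m[j, i]} != 1/{m[i, j]}"
                )
    return m


def pcm_from_upper_triangle(
    values: Sequence[float | str], n: int | None = None
) -> np.ndarray:
    """Complete a reciprocal matrix from its strict upper triangle (row-major)."""
    vals = [parse_judgment(v) for v in values]
    if n is None:
        # solve k(k-1)/2 = len(vals)
        n = int(round((1 + np.sqrt(1 + 8 * len(vals))) / 2))
    if n * (n - 1) // 2 != len(vals):
        raise ValidationError(
            f"{len(vals)} judgments do not fill the upper triangle of any "
            f"square matrix (need n(n-1)/2)"
        )
    m = np.eye(n)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = vals[k]
            m[j, i] = 1.0 / vals[k]
            k += 1
    return validate_pcm(m)


@dataclass(frozen=True)
class PriorityVector:
    """Normalised item weights derived from one PCM."""

    item_ids: tuple[str, ...]
    weights: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {w.sum()}, expected 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def percent(self) -> np.ndarray:
        return self.weights * 100.0


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float
    accepted: bool


def derive_priorities(
    pcm: PairwiseComparisonMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    method: str = "eigenvector",
) -> tuple[PriorityVector, float]:
    """Derive the priority vector and lambda_max from a reciprocal matrix.

    ``method="eigenvector"`` (default) runs power iteration for the
    principal right eigenvector, declaring convergence when successive
    normalised iterates differ by less than ``tol`` in max norm.
    ``method="geometric_mean"`` uses normalised row geometric means instead
    (identical on perfectly consistent matrices, useful as a cross-check).
    lambda_max is estimated as the average of (A w)_i / w_i.
    """
    if isinstance(pcm, PairwiseComparisonMatrix):
        item_ids = pcm.item_ids
        a = pcm.matrix
    else:
        a = validate_pcm(pcm)
        item_ids = tuple(f"item-{i + 1}" for i in range(a.shape[0]))
    n = a.shape[0]
    if method == "geometric_mean":
        w = np.exp(np.mean(np.log(a), axis=1))
        w /= w.sum()
    elif method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = a @ w
            nxt /= nxt.sum()
            if np.max(np.abs(nxt - w)) < tol:
                w = nxt
                break
            w = nxt
        else:
            raise ConvergenceError(
                f"power iteration did not converge within {max_iter} iterations "
                f"(residual {np.max(np.abs((a @ w) / (a @ w).sum() - w)):.3e})"
            )
    else:
        raise ValidationError(f"unknown priority method {method!r}")
    lambda_max = float(np.mean((a @ w) / w))
    return PriorityVector(item_ids=item_ids, weights=w), lambda_max


def consistency(
    lambda_max: float, n: int, extrapolate_ri: bool = False
) -> ConsistencyReport:
    """Compute CI, RI, CR and the acceptance flag (CR strictly below 0.1)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if lambda_max < n - 1e-6:
        raise ValidationError(
            f"lambda_max ({lambda_max}) below n ({n}); not a reciprocal-matrix "
            f"principal eigenvalue"
        )
    if n <= 2:
        # 1x1 and 2x2 reciprocal matrices are always perfectly consistent
        return ConsistencyReport(lambda_max=lambda_max, n=n, ci=0.0,
                                 ri=0.0, cr=0.0, accepted=True)
    if n in RANDOM_INDEX:
        ri = RANDOM_INDEX[n]
    elif extrapolate_ri:
        ri = RI_EXTRAPOLATED
    else:
        raise ValidationError(
            f"no random index tabulated for n={n}; pass extrapolate_ri=True "
            f"to use the flat extrapolation {RI_EXTRAPOLATED}"
        )
    ci = (lambda_max - n) / (n - 1)
    cr = ci / ri
    return ConsistencyReport(
        lambda_max=float(lambda_max), n=n, ci=float(ci), ri=ri, cr=float(cr),
        accepted=bool(cr < CR_THRESHOLD),
    )


@dataclass(frozen=True)
class GroupWeightTable:
    """Per-item mean +/- SD importance weight (%) over accepted participants."""

    category: str
    item_ids: tuple[str, ...]
    mean_weight_pct: np.ndarray
    sd_weight_pct: np.ndarray
    n_accepted: int
    participant_weights_pct: np.ndarray  # (n_accepted, n_items)
    accepted_participants: tuple[str, ...] = ()
    rejected_participants: tuple[str, ...] = ()


def evaluate_participant(
    pcm: PairwiseComparisonMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    method: str = "eigenvector",
    extrapolate_ri: bool = False,
) -> tuple[PriorityVector, ConsistencyReport]:
    """Priorities plus consistency diagnostics for one participant's matrix."""
    vector, lam = derive_priorities(pcm, tol=tol, max_iter=max_iter, method=method)
    report = consistency(lam, pcm.n, extrapolate_ri=extrapolate_ri)
    return vector, report


def aggregate_group(
    vectors: Sequence[PriorityVector],
    reports: Sequence[ConsistencyReport],
    category: str = "",
    participant_ids: Sequence[str] | None = None,
) -> GroupWeightTable:
    """Aggregate accepted participants' priorities into mean +/- SD weights.

    Participants whose CR is at or above the threshold are excluded and
    logged.  The SD is the sample standard deviation (n-1 denominator),
    defined as 0 when only one participant is accepted.
    """
    if len(vectors) != len(reports):
        raise ValidationError("one consistency report is required per vector")
    if not vectors:
        raise ValidationError("no priority vectors supplied")
    item_ids = vectors[0].item_ids
    for v in vectors[1:]:
        if v.item_ids != item_ids:
            raise ValidationError("all priority vectors must cover identical items")
    if participant_ids is None:
        participant_ids = [f"participant-{i + 1}" for i in range(len(vectors))]
    accepted, rejected = [], []
    rows = []
    for pid, vec, rep in zip(participant_ids, vectors, reports):
        if rep.accepted:
            accepted.append(pid)
            rows.append(vec.percent)
        else:
            rejected.append(pid)
            logger.warning(
                "participant %s rejected: CR = %.3f >= %.1f", pid, rep.cr, CR_THRESHOLD
            )
    if not rows:
        raise DegenerateDataError(
            "all participants were rejected by the consistency filter; "
            "judgments must be re-elicited"
        )
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    return GroupWeightTable(
        category=category,
        item_ids=item_ids,
        mean_weight_pct=mean,
        sd_weight_pct=sd,
        n_accepted=mat.shape[0],
        participant_weights_pct=mat,
        accepted_participants=tuple(accepted),
        rejected_participants=tuple(rejected),
    )


def rank_items(table: GroupWeightTable) -> list[str]:
    """Item ids in descending order of mean weight; ties keep catalog order."""
    order = np.argsort(-table.mean_weight_pct, kind="stable")
    return [table.item_ids[i] for i in order]
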