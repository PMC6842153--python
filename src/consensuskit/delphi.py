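"""Delphi vote summarisation, a priori consensus classification, and round orchestration.

The engine implements the classical two-voting-round Delphi design used in
health-services consensus studies: a panel scores candidate items on a 1-9
agreement scale, per-item descriptive statistics (quartiles, IQR, band
percentages) are fed back, and a predefined rule decides whether each item
reaches consensus for inclusion, consensus for exclusion, or remains
equivocal and is carried into the next round.  After the final voting round
any still-equivocal item is reported as "no consensus".

Score bands
-----------
The 1-9 scale is partitioned into three bands:

* ``1-3``  disagreement (the item should be dropped),
* ``4-6``  partial / indecisive agreement,
* ``7-9``  agreement (the item should be kept).

The a priori rule classifies an item as

* **include** when the median lies in 7-9, the IQR is <= 2, and at least a
  supermajority (default 75%) of panelists voted in the 7-9 band;
* **exclude** when the mirror-image condition holds on the 1-3 band;
* **equivocal** otherwise.

Boundary values satisfy the rule: a median of exactly 7, an IQR of exactly
2, and an agreement share of exactly 75% together classify as include.

Round labels start at 2 by convention: in the study design this engine
mirrors, "round 1" is the qualitative item-generation stage, and the first
vote happens in the second Delphi round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Valid item-source codes: collected from the literature (L), from expert
#: interviews (I), or both (B).
SOURCES = ("literature", "interview", "both")
SOURCE_CODES = {"L": "literature", "I": "interview", "B": "both"}

QuartileConvention = Literal[
    "linear",            # linear interpolation, inclusive endpoints (spreadsheet default)
    "exclusive",         # (n+1)p positioning, endpoints excluded
    "nearest",
    "midpoint",
]
_NUMPY_METHOD = {
    "linear": "linear",
    "exclusive": "weibull",
    "nearest": "nearest",
    "midpoint": "midpoint",
}

ConsensusLabel = Literal["include", "exclude", "equivocal"]


@dataclass(frozen=True)
class ItemRecord:
    """One catalog entry: an opaque statement voted on by the panel."""

    item_id: str
    text: str
    category: str = "uncategorized"
    source: str = "both"

    def __post_init__(self) -> None:
        src = SOURCE_CODES.get(self.source, self.source)
        if src not in SOURCES:
            raise ValidationError(
                f"item {self.item_id!r}: source {self.source!r} not one of "
                f"{SOURCES} (codes L/I/B accepted)"
            )
        object.__setattr__(self, "source", src)


@dataclass(frozen=True)
class VoteMatrix:
    """Integer 1-9 scores of every panelist on every item in one round.

    ``scores[p, i]`` is the vote of ``panelist_ids[p]`` on ``item_ids[i]``.
    A value of 0 marks a missing vote and is only representable when
    ``allow_missing=True`` was passed (an explicit opt-in drop policy);
    otherwise every cell must be an integer in [1, 9].
    """

    round_label: int
    panelist_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    scores: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.round_label < 2:
            raise ValidationError(
                f"round_label must be >= 2 (the first voting round is the "
                f"second Delphi round), got {self.round_label}"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("duplicate item ids in vote matrix")
        if len(set(self.panelist_ids)) != len(self.panelist_ids):
            raise ValidationError("duplicate panelist ids in vote matrix")
        scores = np.asarray(self.scores)
        if scores.shape != (len(self.panelist_ids), len(self.item_ids)):
            raise ValidationError(
                f"scores shape {scores.shape} does not match "
                f"({len(self.panelist_ids)} panelists, {len(self.item_ids)} items)"
            )
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.floor(scores)):
                raise ValidationError("votes must be integers in [1, 9]")
            scores = scores.astype(np.int64)
        lo = 0 if self.allow_missing else 1
        if scores.size and (scores.min() < lo or scores.max() > 9):
            bad = np.argwhere((scores < lo) | (scores > 9))[0]
            raise ValidationError(
                f"vote out of range [1, 9]: panelist "
                f"{self.panelist_ids[bad[0]]!r} scored "
                f"{int(scores[bad[0], bad[1]])} on item {self.item_ids[bad[1]]!r}"
            )
        if not self.allow_missing and scores.size and (scores == 0).any():
            raise ValidationError("missing votes present without an explicit drop policy")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "panelist_ids", tuple(self.panelist_ids))
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_panelists(self) -> int:
        return len(self.panelist_ids)

    def item_scores(self, item_id: str) -> np.ndarray:
        """Non-missing scores for one item."""
        col = self.scores[:, self.item_ids.index(item_id)]
        return col[col > 0]


@dataclass(frozen=True)
class ItemSummary:
    """Descriptive statistics of one item's votes in one round.

    ``q1``/``q3`` are ``None`` when the summary was transcribed from a
    published table that prints only the median, IQR and agreement share
    (``provenance="summary"``); they are always set when computed from raw
    votes (``provenance="votes"``).
    """

    median: float
    iqr: float
    pct_agree: float
    pct_partial: float
    pct_disagree: float
    n_panelists: int
    q1: float | None = None
    q3: float | None = None
    provenance: str = "votes"

    def __post_init__(self) -> None:
        if self.n_panelists <= 0:
            raise ValidationError("n_panelists must be positive")
        if not 1 <= self.median <= 9:
            raise ValidationError(f"median {self.median} outside [1, 9]")
        if self.iqr < 0:
            raise ValidationError("iqr must be non-negative")
        if (self.q1 is None) != (self.q3 is None):
            raise ValidationError("q1 and q3 must be supplied together")
        if self.q1 is not None and self.q3 is not None:
            if not (self.q1 <= self.median <= self.q3):
                raise ValidationError("quartiles must satisfy q1 <= median <= q3")
            if abs((self.q3 - self.q1) - self.iqr) > 1e-9:
                raise ValidationError("iqr must equal q3 - q1")
        total = self.pct_agree + self.pct_partial + self.pct_disagree
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"band percentages sum to {total}, expected 100")

    @classmethod
    def from_triple(
        cls, median: float, iqr: float, pct_agree: float, n_panelists: int = 76
    ) -> "ItemSummary":
        """Build a summary from a printed (median, IQR, %agree) triple.

        The split of the remaining share between the partial and disagree
        bands is not published; it is booked entirely under ``pct_partial``.
        This is inconsequential for classification whenever the median is
        above 3 (the exclude rule cannot fire there).
        """
        return cls(
            median=median,
            iqr=iqr,
            pct_agree=pct_agree,
            pct_partial=100.0 - pct_agree,
            pct_disagree=0.0,
            n_panelists=n_panelists,
            provenance="summary",
        )


@dataclass(frozen=True)
class RuleConfig:
    """The a priori consensus rule thresholds."""

    include_median_band: tuple[float, float] = (7.0, 9.0)
    exclude_median_band: tuple[float, float] = (1.0, 3.0)
    iqr_cap: float = 2.0
    supermajority_pct: float = 75.0
    max_voting_rounds: int = 2
    agree_band: tuple[int, int] = (7, 9)
    partial_band: tuple[int, int] = (4, 6)
    disagree_band: tuple[int, int] = (1, 3)
    quartile_convention: QuartileConvention = "linear"

    def __post_init__(self) -> None:
        if self.iqr_cap <= 0 or self.supermajority_pct <= 0 or self.max_voting_rounds <= 0:
            raise ValidationError("rule thresholds must be strictly positive")
        bands = sorted([self.disagree_band, self.partial_band, self.agree_band])
        covered = [s for band in bands for s in range(band[0], band[1] + 1)]
        if covered != list(range(1, 10)):
            raise ValidationError("score bands must be disjoint and cover 1..9")


@dataclass(frozen=True)
class ConsensusDecision:
    item_id: str
    label: ConsensusLabel
    decided_in_round: int | None

    def __post_init__(self) -> None:
        if (self.decided_in_round is None) != (self.label == "equivocal"):
            raise ValidationError(
                "decided_in_round must be set exactly when a decision was reached"
            )


@dataclass(frozen=True)
class FeedbackPackage:
    """The controlled feedback one panelist receives about one equivocal item.

    Group statistics are identical across recipients; only ``own_score``
    differs.  ``comment_summary`` is pass-through text.
    """

    item_id: str
    panelist_id: str
    own_score: int
    group_median: float
    group_iqr: float
    comment_summary: str = ""


@dataclass(frozen=True)
class RoundResult:
    round_label: int
    summaries: dict[str, ItemSummary]
    decisions: dict[str, ConsensusDecision]
    carried_forward: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        labels = [d.label for d in self.decisions.values()]
        return {
            "include": labels.count("include"),
            "exclude": labels.count("exclude"),
            "equivocal": labels.count("equivocal"),
        }


@dataclass(frozen=True)
class DelphiOutcome:
    """Final status of every catalog item after all voting rounds."""

    included: dict[str, int]       # item_id -> round in which it was included
    excluded: dict[str, int]
    no_consensus: tuple[str, ...]
    rounds: tuple[RoundResult, ...] = field(default=())

    @property
    def n_items(self) -> int:
        return len(self.included) + len(self.excluded) + len(self.no_consensus)

    def consensus_pct(self) -> float:
        """Share of catalog items reaching consensus (either direction), in %."""
        return 100.0 * (len(self.included) + len(self.excluded)) / self.n_items


# ---------------------------------------------------------------------------
# operations

def summarize_item(
    scores: Sequence[int] | np.ndarray,
    quartile_convention: QuartileConvention = "linear",
) -> ItemSummary:
    """Compute Q1/median/Q3, IQR and band percentages for one item's votes.

    Parameters
    ----------
    scores
        Integer votes in [1, 9], one per panelist.
    quartile_convention
        How quartiles are interpolated.  The default ``"linear"`` is linear
        interpolation with inclusive endpoints, i.e. the spreadsheet
        QUARTILE.INC convention.
    """
    arr = np.asarray(scores)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty score list")
    if not np.all(arr == np.floor(arr)):
        raise ValidationError("votes must be integers")
    arr = arr.astype(np.int64)
    if arr.min() < 1 or arr.max() > 9:
        idx = int(np.argwhere((arr < 1) | (arr > 9))[0][0])
        raise ValidationError(
            f"vote out of range [1, 9]: position {idx} holds {int(arr[idx])}"
        )
    if quartile_convention not in _NUMPY_METHOD:
        raise ValidationError(f"unknown quartile convention {quartile_convention!r}")
    method = _NUMPY_METHOD[quartile_convention]
    q1, med, q3 = (
        float(np.percentile(arr, q, method=method)) for q in (25, 50, 75)
    )
    n = arr.size
    agree = 100.0 * np.count_nonzero(arr >= 7) / n
    disagree = 100.0 * np.count_nonzero(arr <= 3) / n
    return ItemSummary(
        median=med,
        iqr=q3 - q1,
        pct_agree=agree,
        pct_partial=100.0 - agree - disagree,
        pct_disagree=disagree,
        n_panelists=n,
        q1=q1,
        q3=q3,
    )


def classify_consensus(summary: ItemSummary, rules: RuleConfig = RuleConfig()) -> ConsensusLabel:
    """Apply the a priori consensus rule to one item summary.

    Returns ``"include"`` when the median lies in the include band, the IQR
    is at most the cap, and the agreement share reaches the supermajority;
    ``"exclude"`` under the mirror conditions on the disagree band; and
    ``"equivocal"`` otherwise (this catch-all also covers medians of 6 and
    any other configuration matching neither rule).  All comparisons are
    inclusive at the boundary.
    """
    lo, hi = rules.include_median_band
    if lo <= summary.median <= hi and summary.iqr <= rules.iqr_cap \
            and summary.pct_agree >= rules.supermajority_pct:
        return "include"
    lo, hi = rules.exclude_median_band
    if lo <= summary.median <= hi and summary.iqr <= rules.iqr_cap \
            and summary.pct_disagree >= rules.supermajority_pct:
        return "exclude"
    return "equivocal"


def run_round(
    votes: VoteMatrix,
    rules: RuleConfig = RuleConfig(),
    missing: Literal["error", "drop"] = "error",
) -> RoundResult:
    """Summarize and classify every item voted in one round."""
    summaries: dict[str, ItemSummary] = {}
    decisions: dict[str, ConsensusDecision] = {}
    carried: list[str] = []
    for item_id in votes.item_ids:
        col = votes.scores[:, votes.item_ids.index(item_id)]
        if (col == 0).any():
            if missing != "drop":
                raise ValidationError(
                    f"item {item_id!r} has missing votes and missing='error'"
                )
            logger.warning(
                "item %s: dropping %d missing votes; percentages use the "
                "reduced denominator", item_id, int((col == 0).sum()),
            )
            col = col[col > 0]
        summary = summarize_item(col, rules.quartile_convention)
        label = classify_consensus(summary, rules)
        summaries[item_id] = summary
        decisions[item_id] = ConsensusDecision(
            item_id=item_id,
            label=label,
            decided_in_round=None if label == "equivocal" else votes.round_label,
        )
        if label == "equivocal":
            carried.append(item_id)
    result = RoundResult(
        round_label=votes.round_label,
        summaries=summaries,
        decisions=decisions,
        carried_forward=tuple(carried),
    )
    logger.info("round %d: %s", votes.round_label, result.counts())
    return result


def classify_summaries(
    summaries: Mapping[str, ItemSummary],
    round_label: int,
    rules: RuleConfig = RuleConfig(),
) -> RoundResult:
    """Classify pre-computed summaries (e.g. transcribed from a published table).

    This is the summary-provenance twin of :func:`run_round` for studies
    whose raw votes were never published.
    """
    decisions = {}
    carried = []
    for item_id, summary in summaries.items():
        label = classify_consensus(summary, rules)
        decisions[item_id] = ConsensusDecision(
            item_id=item_id,
            label=label,
            decided_in_round=None if label == "equivocal" else round_label,
        )
        if label == "equivocal":
            carried.append(item_id)
    return RoundResult(
        round_label=round_label,
        summaries=dict(summaries),
        decisions=decisions,
        carried_forward=tuple(carried),
    )


def build_feedback(
    item: ItemRecord | str,
    prior: ItemSummary,
    prior_label: ConsensusLabel,
    own_scores: Mapping[str, int],
    comment_summary: str = "",
) -> list[FeedbackPackage]:
    """Assemble the per-panelist feedback for one equivocal item.

    Each package reminds the panelist of their own score and reports the
    group median, the group IQR, and a summary of the qualitative comments.
    Only items that remained equivocal in the prior round may receive
    feedback.
    """
    if prior_label != "equivocal":
        raise ValidationError(
            f"feedback is only built for equivocal items; item was {prior_label!r}"
        )
    item_id = item.item_id if isinstance(item, ItemRecord) else item
    return [
        FeedbackPackage(
            item_id=item_id,
            panelist_id=pid,
            own_score=int(score),
            group_median=prior.median,
            group_iqr=prior.iqr,
            comment_summary=comment_summary,
        )
        for pid, score in own_scores.items()
    ]


def _finalize(rounds: list[RoundResult]) -> DelphiOutcome:
    included: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for rr in rounds:
        for d in rr.decisions.values():
            if d.label == "include":
                included[d.item_id] = rr.round_label
            elif d.label == "exclude":
                excluded[d.item_id] = rr.round_label
    no_consensus = rounds[-1].carried_forward if rounds else ()
    outcome = DelphiOutcome(
        included=included,
        excluded=excluded,
        no_consensus=tuple(no_consensus),
        rounds=tuple(rounds),
    )
    logger.info(
        "orchestration complete: %d included, %d excluded, %d no-consensus "
        "(%.1f%% consensus)",
        len(included), len(excluded), len(no_consensus), outcome.consensus_pct(),
    )
    return outcome


def orchestrate(
    vote_rounds: Sequence[VoteMatrix],
    rules: RuleConfig = RuleConfig(),
    missing: Literal["error", "drop"] = "error",
) -> DelphiOutcome:
    """Run the iterative Delphi process over successive vote matrices.

    Round r+1 must cover exactly the items left equivocal in round r.  After
    the final supplied round (at most ``rules.max_voting_rounds``), any item
    still equivocal becomes ``no_consensus`` — no further round is conducted.
    """
    if not vote_rounds:
        raise ValidationError("at least one voting round is required")
    if len(vote_rounds) > rules.max_voting_rounds:
        raise ValidationError(
            f"{len(vote_rounds)} rounds supplied but the design allows "
            f"{rules.max_voting_rounds} voting rounds"
        )
    rounds: list[RoundResult] = []
    for votes in vote_rounds:
        if rounds:
            expected = set(rounds[-1].carried_forward)
            got = set(votes.item_ids)
            if got - expected:
                raise ValidationError(
                    f"round {votes.round_label} re-votes already-decided items: "
                    f"{sorted(got - expected)}"
                )
            if expected - got:
                raise ValidationError(
                    f"round {votes.round_label} is missing equivocal items: "
                    f"{sorted(expected - got)}"
                )
        rr = run_round(votes, rules, missing=missing)
        rounds.append(rr)
    return _finalize(rounds)


def orchestrate_summaries(
    summary_rounds: Sequence[Mapping[str, ItemSummary]],
    rules: RuleConfig = RuleConfig(),
    first_round_label: int = 2,
    on_missing: Literal["error", "retain"] = "error",
) -> DelphiOutcome:
    """Orchestrate from pre-computed per-round summaries.

    Later rounds may be supplied for a superset of items (as printed tables
    often are); only the items carried forward from the previous round are
    classified.  A carried item absent from a later round is an error by
    default; with ``on_missing="retain"`` it stays equivocal (its prior
    summary is carried along), ending as no-consensus if never re-voted.
    """
    if not summary_rounds:
        raise ValidationError("at least one round of summaries is required")
    rounds: list[RoundResult] = []
    label = first_round_label
    current: Mapping[str, ItemSummary] = summary_rounds[0]
    retained: dict[str, ItemSummary] = {}
    for i, full in enumerate(summary_rounds):
        if i > 0:
            carried = rounds[-1].carried_forward
            missing = [x for x in carried if x not in full]
            if missing and on_missing == "error":
                raise ValidationError(
                    f"round {label} summaries missing carried items: {missing}"
                )
            retained = {x: rounds[-1].summaries[x] for x in missing}
            current = {x: full[x] for x in carried if x in full}
        rr = classify_summaries(current, label, rules)
        if retained:
            logger.warning(
                "round %d: %d carried items were not re-voted and stay "
                "equivocal", label, len(retained),
            )
            decisions = dict(rr.decisions)
            summaries = dict(rr.summaries)
            for item_id, summary in retained.items():
                decisions[item_id] = ConsensusDecision(
                    item_id=item_id, label="equivocal", decided_in_round=None
                )
                summaries[item_id] = summary
            rr = RoundResult(
                round_label=label,
                summaries=summaries,
                decisions=decisions,
                carried_forward=rr.carried_forward + tuple(retained),
            )
        rounds.append(rr)
        if not rounds[-1].carried_forward:
            break
        label += 1
    return _finalize(rounds)
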