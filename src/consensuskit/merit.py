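"""Summaries of the 5-point Likert merit section of the panel survey.

Each statement asks the panel to rate a claimed merit of the system under
study on strongly agree / agree / neutral / disagree / strongly disagree.
The combined agreement share (strongly agree + agree) is the headline
statistic.  Displayed percentages are rounded half-away-from-zero to one
decimal; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import round_half_away
from .exceptions import ValidationError

LIKERT_LEVELS = ("strongly_agree", "agree", "neutral", "disagree", "strongly_disagree")
THEMES = ("patient_safety", "cost", "record_keeping", "workflow")


@dataclass(frozen=True)
class LikertItemCounts:
    """Response counts for one merit statement."""

    statement_id: str
    theme: str
    counts: tuple[int, int, int, int, int]  # SA, A, N, D, SD
    n_respondents: int
    text: str = ""
    comment_summary: str = ""

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise ValidationError(
                f"statement {self.statement_id!r}: theme {self.theme!r} "
                f"not one of {THEMES}"
            )
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 5 or any(c < 0 for c in counts):
            raise ValidationError("counts must be 5 non-negative integers")
        if self.n_respondents <= 0:
            raise ValidationError("n_respondents must be positive")
        if sum(counts) != self.n_respondents:
            raise ValidationError(
                f"statement {self.statement_id!r}: counts sum to {sum(counts)} "
                f"but n_respondents = {self.n_respondents}"
            )
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class MeritSummary:
    """Per-level and combined-agreement percentages for one statement."""

    statement_id: str
    theme: str
    pct_levels: tuple[float, float, float, float, float]
    agreement_pct: float
    comment_summary: str = ""

    def pct_levels_display(self) -> tuple[float, ...]:
        return tuple(round_half_away(p, 1) for p in self.pct_levels)

    @property
    def agreement_pct_display(self) -> float:
        return round_half_away(self.agreement_pct, 1)


def summarize_merit(item: LikertItemCounts) -> MeritSummary:
    n = item.n_respondents
    pct = tuple(100.0 * c / n for c in item.counts)
    agreement = 100.0 * (item.counts[0] + item.counts[1]) / n
    return MeritSummary(
        statement_id=item.statement_id,
        theme=item.theme,
        pct_levels=pct,
        agreement_pct=agreement,
        comment_summary=item.comment_summary,
    )


def summarize_merits(items: Sequence[LikertItemCounts]) -> list[MeritSummary]:
    """Summarize a batch of merit statements, preserving input order."""
    return [summarize_merit(item) for item in items]
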