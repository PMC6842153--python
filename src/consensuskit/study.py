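"""Recompute the packaged study's headline results from its fixture tables.

Every quantity here is derived at call time by running the package's own
classifiers and summarisers over the transcribed per-item statistics — the
counts are never stored, only the printed (median, IQR, %agree) triples.

One deliberate asymmetry: when rolling the two voting rounds forward, the
third-round rule is applied to consensus-table items only.  The published
no-consensus table prints third-round statistics for context, but those
items' final status is the published one (no consensus); one of its rows is
internally inconsistent with the stated rule, and this package does not
second-guess the study's adjudication of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_away
from .delphi import RuleConfig, RoundResult, classify_summaries, orchestrate_summaries
from .fixtures import CATEGORY_TITLES, StudyFixture, load_fixture
from .merit import MeritSummary, summarize_merits


@dataclass(frozen=True)
class StudyResults:
    """Everything the two-round roll-forward establishes."""

    round2: RoundResult
    n_items: int
    included_round2: int
    included_round3: int
    no_consensus: int

    @property
    def included_total(self) -> int:
        return self.included_round2 + self.included_round3

    @property
    def consensus_pct(self) -> float:
        return round_half_away(100.0 * self.included_total / self.n_items, 1)

    @property
    def carried_to_round3(self) -> int:
        return len(self.round2.carried_forward)


def classify_round2(
    fixture: StudyFixture | None = None, rules: RuleConfig = RuleConfig()
) -> RoundResult:
    """Apply the a priori rule to the printed round-2 triples of all items."""
    fx = fixture or load_fixture()
    return classify_summaries(fx.round_summaries(2), round_label=2, rules=rules)


def run_study(
    fixture: StudyFixture | None = None, rules: RuleConfig = RuleConfig()
) -> StudyResults:
    """Roll the two voting rounds forward from the printed summaries."""
    fx = fixture or load_fixture()
    consensus_ids = set(fx.consensus_items["item_id"])
    r3_consensus = {
        k: v for k, v in fx.round_summaries(3).items() if k in consensus_ids
    }
    outcome = orchestrate_summaries(
        [fx.round_summaries(2), r3_consensus], rules=rules, on_missing="retain"
    )
    r2 = outcome.rounds[0]
    return StudyResults(
        round2=r2,
        n_items=fx.n_items,
        included_round2=sum(1 for r in outcome.included.values() if r == 2),
        included_round3=sum(1 for r in outcome.included.values() if r == 3),
        no_consensus=len(outcome.no_consensus),
    )


def category_shares(fixture: StudyFixture | None = None) -> pd.DataFrame:
    """Per-category item counts and one-decimal shares of the consensus list."""
    fx = fixture or load_fixture()
    counts = fx.consensus_items["category"].value_counts()
    total = int(counts.sum())
    rows = [
        {
            "category": cat,
            "title": CATEGORY_TITLES[cat],
            "n_items": int(n),
            "pct_of_consensus": round_half_away(100.0 * n / total, 1),
        }
        for cat, n in counts.sort_values(ascending=False).items()
    ]
    return pd.DataFrame(rows)


def merit_results(fixture: StudyFixture | None = None) -> list[MeritSummary]:
    fx = fixture or load_fixture()
    return summarize_merits(fx.merit_counts)


def interview_completion_pct(fixture: StudyFixture | None = None) -> float:
    """Share of invited key contacts who completed an interview, in %."""
    fx = fixture or load_fixture()
    return round_half_away(
        100.0 * fx.recruitment["interview_completed"]
        / fx.recruitment["interview_invited"],
        1,
    )
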