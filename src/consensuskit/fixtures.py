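"""Packaged study fixture: the published per-item summary tables.

The study this package ships as its worked example published only summary
statistics — per-item median / IQR / %agree for each voting round, group
importance weights (mean and SD over the accepted AHP participants), Likert
merit counts, and recruitment accounting.  The raw votes and raw pairwise
matrices were never released.  These tables are packaged as CSV/JSON and
re-validated on every load:

* 122 candidate items: 110 in the consensus table (9 categories of sizes
  16, 16, 16, 14, 13, 12, 11, 9 and 3) and 12 in the no-consensus table;
* per-category mean importance weights summing to 100;
* all 12 merit statements with counts summing to the 76 respondents.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import json

import numpy as np
import pandas as pd

from .ahp import GroupWeightTable
from .delphi import ItemRecord, ItemSummary
from .exceptions import ValidationError
from .merit import LikertItemCounts

N_PANELISTS = 76
EXPECTED_CATEGORY_SIZES = {
    "demographic": 16,
    "prescribing": 16,
    "checking": 16,
    "identity": 14,
    "assessment": 13,
    "alerts_quality": 12,
    "admission_discharge": 11,
    "general": 9,
    "diagnosis": 3,
}

CATEGORY_TITLES = {
    "demographic": "Demographic characteristics of the patient",
    "prescribing": "Prescribing medications",
    "checking": "Checking prescriptions and alerts",
    "identity": "Patient's identity",
    "assessment": "Patient assessment",
    "alerts_quality": "Quality of alerts",
    "admission_discharge": "Admission and discharge of the patient",
    "general": "General features",
    "diagnosis": "Diseases and making diagnosis",
}


@dataclass(frozen=True)
class StudyFixture:
    """All packaged tables plus recruitment accounting."""

    consensus_items: pd.DataFrame
    no_consensus_items: pd.DataFrame
    merit_counts: list[LikertItemCounts]
    recruitment: dict[str, int]

    @property
    def all_items(self) -> pd.DataFrame:
        return pd.concat(
            [self.consensus_items, self.no_consensus_items], ignore_index=True
        )

    @property
    def n_items(self) -> int:
        return len(self.consensus_items) + len(self.no_consensus_items)

    def catalog(self) -> list[ItemRecord]:
        return [
            ItemRecord(
                item_id=row.item_id, text=row.text,
                category=row.category, source=row.source,
            )
            for row in self.all_items.itertuples()
        ]

    def round_summaries(self, round_label: int) -> dict[str, ItemSummary]:
        """Per-item summaries transcribed from the printed tables.

        Round 2 covers all items; round 3 covers only the items that were
        re-voted and have printed statistics.
        """
        if round_label not in (2, 3):
            raise ValidationError(f"no voting took place in round {round_label}")
        prefix = f"r{round_label}_"
        out = {}
        for row in self.all_items.itertuples():
            med = getattr(row, prefix + "median")
            if pd.isna(med):
                continue
            out[row.item_id] = ItemSummary.from_triple(
                median=float(med),
                iqr=float(getattr(row, prefix + "iqr")),
                pct_agree=float(getattr(row, prefix + "pct_agree")),
                n_panelists=N_PANELISTS,
            )
        return out

    def weight_table(self, category: str) -> GroupWeightTable:
        """Published group weights for one category (means and SDs only).

        The per-participant weight matrix was never released, so
        ``participant_weights_pct`` is empty and downstream ANOVA cannot be
        run on fixture weights — only on synthetic or newly elicited ones.
        """
        sub = self.consensus_items[self.consensus_items["category"] == category]
        if sub.empty:
            raise ValidationError(f"unknown category {category!r}")
        n = self.recruitment["ahp_participants"]
        return GroupWeightTable(
            category=category,
            item_ids=tuple(sub["item_id"]),
            mean_weight_pct=sub["weight_mean_pct"].to_numpy(float),
            sd_weight_pct=sub["weight_sd_pct"].to_numpy(float),
            n_accepted=n,
            participant_weights_pct=np.empty((0, len(sub))),
        )


def _validate(fx: StudyFixture) -> None:
    if fx.n_items != 122:
        raise ValidationError(f"fixture holds {fx.n_items} items, expected 122")
    if len(fx.consensus_items) != 110 or len(fx.no_consensus_items) != 12:
        raise ValidationError("fixture must split 110 consensus / 12 no-consensus")
    sizes = fx.consensus_items["category"].value_counts().to_dict()
    if sizes != EXPECTED_CATEGORY_SIZES:
        raise ValidationError(f"unexpected category sizes: {sizes}")
    for cat in EXPECTED_CATEGORY_SIZES:
        total = fx.consensus_items.loc[
            fx.consensus_items["category"] == cat, "weight_mean_pct"
        ].sum()
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"{cat}: weight means sum to {total}, expected 100")
    for item in fx.merit_counts:
        if item.n_respondents != N_PANELISTS:
            raise ValidationError(f"{item.statement_id}: expected 76 respondents")


def load_fixture() -> StudyFixture:
    """Load and validate the packaged study tables."""
    root = resources.files("consensuskit") / "data"
    with resources.as_file(root / "consensus_items.csv") as p:
        consensus = pd.read_csv(p)
    with resources.as_file(root / "no_consensus_items.csv") as p:
        no_consensus = pd.read_csv(p)
    with resources.as_file(root / "merit_statements.csv") as p:
        merits_df = pd.read_csv(p)
    recruitment = json.loads((root / "recruitment.json").read_text())
    merit_counts = [
        LikertItemCounts(
            statement_id=row.statement_id,
            theme=row.theme,
            counts=(
                row.strongly_agree, row.agree, row.neutral,
                row.disagree, row.strongly_disagree,
            ),
            n_respondents=row.n_respondents,
            text=row.text,
        )
        for row in merits_df.itertuples()
    ]
    fx = StudyFixture(
        consensus_items=consensus,
        no_consensus_items=no_consensus,
        merit_counts=merit_counts,
        recruitment=recruitment,
    )
    _validate(fx)
    return fx
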