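"""Render pipeline outputs in the published table layouts (CSV + markdown)."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_away
from .ahp import GroupWeightTable, rank_items
from .compare import ComparisonResult
from .config import RunConfig
from .delphi import DelphiOutcome
from .merit import LIKERT_LEVELS, MeritSummary

logger = logging.getLogger(__name__)


def consensus_table(
    outcome: DelphiOutcome,
    weights: Mapping[str, GroupWeightTable] | None = None,
) -> pd.DataFrame:
    """Per decided item: round statistics, decision, and (optionally) weights."""
    rows = []
    by_round = {rr.round_label: rr for rr in outcome.rounds}
    ranks: dict[str, int] = {}
    means: dict[str, tuple[float, float]] = {}
    if weights:
        for table in weights.values():
            for rank, item in enumerate(rank_items(table), 1):
                ranks[item] = rank
            for item, m, s in zip(
                table.item_ids, table.mean_weight_pct, table.sd_weight_pct
            ):
                means[item] = (m, s)
    for item, rnd in {**outcome.included, **outcome.excluded}.items():
        row: dict = {"item_id": item, "decision": "include" if item in outcome.included else "exclude",
                     "decided_in_round": rnd}
        for label, rr in by_round.items():
            if item in rr.summaries:
                s = rr.summaries[item]
                row[f"r{label}_median"] = s.median
                row[f"r{label}_iqr"] = s.iqr
                row[f"r{label}_pct_agree"] = round_half_away(s.pct_agree, 1)
        if item in means:
            row["weight_mean_pct"] = means[item][0]
            row["weight_sd_pct"] = means[item][1]
            row["rank_in_category"] = ranks[item]
        rows.append(row)
    return pd.DataFrame(rows)


def no_consensus_table(outcome: DelphiOutcome) -> pd.DataFrame | None:
    if not outcome.no_consensus:
        logger.info("no-consensus table omitted: every item reached a decision")
        return None
    rows = []
    by_round = {rr.round_label: rr for rr in outcome.rounds}
    for item in outcome.no_consensus:
        row: dict = {"item_id": item}
        for label, rr in by_round.items():
            if item in rr.summaries:
                s = rr.summaries[item]
                row[f"r{label}_median"] = s.median
                row[f"r{label}_iqr"] = s.iqr
                row[f"r{label}_pct_agree"] = round_half_away(s.pct_agree, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def merit_table(merits: Sequence[MeritSummary]) -> pd.DataFrame:
    rows = []
    for m in merits:
        row = {"statement_id": m.statement_id, "theme": m.theme}
        row.update(dict(zip(LIKERT_LEVELS, m.pct_levels_display())))
        row["agreement_pct"] = m.agreement_pct_display
        rows.append(row)
    return pd.DataFrame(rows)


def category_summary(
    outcome: DelphiOutcome, categories: Mapping[str, str]
) -> pd.DataFrame:
    """Included-item counts per category with one-decimal shares."""
    counts: dict[str, int] = {}
    for item in outcome.included:
        counts[categories.get(item, "uncategorized")] = (
            counts.get(categories.get(item, "uncategorized"), 0) + 1
        )
    total = sum(counts.values())
    return pd.DataFrame(
        [
            {"category": cat, "n_items": n,
             "pct_of_consensus": round_half_away(100.0 * n / total, 1)}
            for cat, n in sorted(counts.items(), key=lambda kv: -kv[1])
        ]
    )


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item_a": r.item_a, "item_b": r.item_b,
                "mean_diff": r.mean_diff, "t": r.t_statistic,
                "raw_p": r.raw_p, "adjusted_p": r.adjusted_p, "stars": r.stars,
            }
            for r in results
        ]
    )


def write_report(
    outdir: str | Path,
    outcome: DelphiOutcome,
    categories: Mapping[str, str] | None = None,
    weights: Mapping[str, GroupWeightTable] | None = None,
    merits: Sequence[MeritSummary] | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the full report bundle; returns the paths written.

    The resolved configuration is always emitted so the run can be
    reproduced bit-for-bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    emit("consensus_table", consensus_table(outcome, weights))
    nct = no_consensus_table(outcome)
    if nct is not None:
        emit("no_consensus_table", nct)
    if categories:
        emit("category_summary", category_summary(outcome, categories))
    if merits is not None:
        emit("merit_table", merit_table(merits))
    cfg = config or RunConfig()
    cfg_path = outdir / "run_config.json"
    cfg.to_json(cfg_path)
    written["run_config"] = cfg_path

    md = outdir / "report.md"
    lines = ["# Consensus report", ""]
    lines.append(
        f"{len(outcome.included)} items included, {len(outcome.excluded)} "
        f"excluded, {len(outcome.no_consensus)} without consensus "
        f"({round_half_away(outcome.consensus_pct(), 1)}% consensus)."
    )
    for name, path in written.items():
        if path.suffix == ".csv":
            lines.append(f"- `{path.name}`")
    md.write_text("\n".join(lines) + "\n")
    written["report_md"] = md
    return written
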