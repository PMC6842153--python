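"""Readers and writers for the package's CSV/JSON dialects.

All CSV files are comma-separated UTF-8 with a mandatory header row and "."
as the decimal separator.  Errors name the offending row (1-based, counting
the header as row 1).

* votes (long form): ``panelist_id,item_id,round,score``
* item catalog: ``item_id,text,category,source`` with source codes L/I/B
* pairwise matrices (JSON): list of objects with ``participant_id``,
  ``category``, ``item_ids`` and either ``upper_triangle`` (row-major, values
  as numbers or fraction strings like ``"1/3"``) or a full square ``matrix``
* merit counts: ``statement_id,theme,strongly_agree,...,n_respondents``

Writing then reading any object reproduces it exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ahp import PairwiseComparisonMatrix, parse_judgment, pcm_from_upper_triangle
from .delphi import ItemRecord, VoteMatrix
from .exceptions import ValidationError
from .merit import LIKERT_LEVELS, LikertItemCounts

VOTE_COLUMNS = ["panelist_id", "item_id", "round", "score"]
CATALOG_COLUMNS = ["item_id", "text", "category", "source"]
_SOURCE_TO_CODE = {"literature": "L", "interview": "I", "both": "B"}


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_votes(path: str | Path) -> list[VoteMatrix]:
    """Read long-form votes, returning one VoteMatrix per round in round order."""
    df = _read_csv(path, VOTE_COLUMNS)
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            rnd = int(row["round"])
            score = int(row["score"])
        except ValueError as exc:
            raise ValidationError(f"{path} row {line}: non-integer round/score") from exc
        if not 1 <= score <= 9:
            raise ValidationError(
                f"{path} row {line}: score {score} outside [1, 9] "
                f"(panelist {row['panelist_id']!r}, item {row['item_id']!r})"
            )
        if rnd < 2:
            raise ValidationError(f"{path} row {line}: round must be >= 2")
    df = df.astype({"round": int, "score": int})
    matrices = []
    for rnd, grp in df.groupby("round", sort=True):
        dup = grp.duplicated(subset=["panelist_id", "item_id"])
        if dup.any():
            line = grp.index[dup][0] + 2
            raise ValidationError(f"{path} row {line}: duplicate (panelist, item) vote")
        wide = grp.pivot(index="panelist_id", columns="item_id", values="score")
        if wide.isna().any().any():
            pid = wide.index[wide.isna().any(axis=1)][0]
            raise ValidationError(
                f"{path}: round {rnd}: panelist {pid!r} is missing votes for "
                f"some items (every panelist must score every item)"
            )
        # preserve first-appearance order of panelists and items
        panelists = list(dict.fromkeys(grp["panelist_id"]))
        items = list(dict.fromkeys(grp["item_id"]))
        wide = wide.loc[panelists, items]
        matrices.append(
            VoteMatrix(
                round_label=int(rnd),
                panelist_ids=tuple(panelists),
                item_ids=tuple(items),
                scores=wide.to_numpy(dtype=np.int64),
            )
        )
    return matrices


def write_votes(matrices: Sequence[VoteMatrix], path: str | Path) -> None:
    rows = []
    for vm in matrices:
        for p, pid in enumerate(vm.panelist_ids):
            for i, iid in enumerate(vm.item_ids):
                rows.append((pid, iid, vm.round_label, int(vm.scores[p, i])))
    pd.DataFrame(rows, columns=VOTE_COLUMNS).to_csv(path, index=False)


def read_catalog(path: str | Path) -> list[ItemRecord]:
    df = _read_csv(path, CATALOG_COLUMNS)
    records = []
    seen = set()
    for idx, row in df.iterrows():
        line = idx + 2
        if row["item_id"] in seen:
            raise ValidationError(f"{path} row {line}: duplicate item_id {row['item_id']!r}")
        seen.add(row["item_id"])
        try:
            records.append(
                ItemRecord(
                    item_id=row["item_id"],
                    text=row["text"],
                    category=row["category"],
                    source=row["source"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {line}: {exc}") from exc
    return records


def write_catalog(records: Sequence[ItemRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.item_id, r.text, r.category, _SOURCE_TO_CODE[r.source]) for r in records],
        columns=CATALOG_COLUMNS,
    ).to_csv(path, index=False)


def read_pcms(path: str | Path) -> list[PairwiseComparisonMatrix]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    payload = json.loads(path.read_text())
    if isinstance(payload, dict):
        payload = [payload]
    out = []
    for k, entry in enumerate(payload):
        try:
            item_ids = tuple(entry["item_ids"])
            if "upper_triangle" in entry:
                matrix = pcm_from_upper_triangle(entry["upper_triangle"], len(item_ids))
            else:
                matrix = np.array(
                    [[parse_judgment(v) for v in row] for row in entry["matrix"]]
                )
            out.append(
                PairwiseComparisonMatrix(
                    participant_id=str(entry["participant_id"]),
                    category=str(entry.get("category", "")),
                    item_ids=item_ids,
                    matrix=matrix,
                )
            )
        except (KeyError, ValidationError) as exc:
            raise ValidationError(f"{path} entry {k}: {exc}") from exc
    return out


def write_pcms(pcms: Sequence[PairwiseComparisonMatrix], path: str | Path) -> None:
    payload = []
    for pcm in pcms:
        n = pcm.n
        upper = [pcm.matrix[i, j] for i in range(n) for j in range(i + 1, n)]
        payload.append(
            {
                "participant_id": pcm.participant_id,
                "category": pcm.category,
                "item_ids": list(pcm.item_ids),
                "upper_triangle": upper,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_merits(path: str | Path) -> list[LikertItemCounts]:
    df = _read_csv(path, ["statement_id", "theme", *LIKERT_LEVELS, "n_respondents"])
    items = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            items.append(
                LikertItemCounts(
                    statement_id=row["statement_id"],
                    theme=row["theme"],
                    counts=tuple(int(row[lvl]) for lvl in LIKERT_LEVELS),
                    n_respondents=int(row["n_respondents"]),
                    text=row.get("text", ""),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {line}: {exc}") from exc
    return items


def write_merits(items: Sequence[LikertItemCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "statement_id": it.statement_id,
                "theme": it.theme,
                "text": it.text,
                **dict(zip(LIKERT_LEVELS, it.counts)),
                "n_respondents": it.n_respondents,
            }
            for it in items
        ]
    ).to_csv(path, index=False)
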