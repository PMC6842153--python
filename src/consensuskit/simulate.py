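"""Synthetic panels with known ground truth for every pipeline stage.

Nothing about real expert panels is downloadable for studies that publish
only summary tables, so end-to-end testing relies on generators whose
*design is the truth*:

* **Votes** — each item is assigned a behavioural archetype: a probability
  mass over the 1-9 scale for the first voting round plus a conformity
  probability governing how readily dissenting panelists move toward the
  group median after feedback.  ``strong_include`` (all mass on 7-9) and
  ``strong_exclude`` (all mass on 1-3) force their classification
  analytically; ``equivocal`` (uniform on 1-9) almost surely never reaches
  a 75% supermajority; ``converging`` starts short of the supermajority and
  crosses it in the next round when enough dissenters conform.
* **Pairwise matrices** — judgments are the true weight ratios perturbed
  multiplicatively, a_ij = (w_i / w_j) * exp(eps_ij) with
  eps_ij ~ N(0, sigma^2) on the upper triangle and reciprocals enforced,
  optionally snapped to the discrete Saaty scale.  sigma = 0 without
  snapping yields perfectly consistent matrices that reproduce the latent
  weights exactly; inconsistency grows with sigma.
* **Likert counts** — plain multinomial draws.

All generators are pure functions of (parameters, seed): the same seed
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import round_half_away
from .ahp import SAATY_SCALE, PairwiseComparisonMatrix, PriorityVector
from .delphi import FeedbackPackage, RuleConfig, VoteMatrix, run_round
from .exceptions import ValidationError
from .merit import LikertItemCounts

SCORES = np.arange(1, 10)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A named voting behaviour: first-round score distribution + conformity."""

    name: str
    round2_distribution: tuple[float, ...]  # probability mass over scores 1..9
    conformity_prob: float = 0.5

    def __post_init__(self) -> None:
        dist = tuple(float(p) for p in self.round2_distribution)
        if len(dist) != 9 or any(p < 0 for p in dist):
            raise ValidationError("round2_distribution must be 9 non-negative masses")
        if abs(sum(dist) - 1.0) > 1e-9:
            raise ValidationError(f"distribution sums to {sum(dist)}, expected 1")
        if not 0.0 <= self.conformity_prob <= 1.0:
            raise ValidationError("conformity_prob must lie in [0, 1]")
        object.__setattr__(self, "round2_distribution", dist)


def _uniform_on(scores: Sequence[int]) -> tuple[float, ...]:
    mass = [0.0] * 9
    for s in scores:
        mass[s - 1] = 1.0 / len(scores)
    return tuple(mass)


#: Built-in archetypes keyed by name.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "strong_include": ArchetypeSpec("strong_include", _uniform_on([7, 8, 9])),
    "strong_exclude": ArchetypeSpec("strong_exclude", _uniform_on([1, 2, 3])),
    "equivocal": ArchetypeSpec("equivocal", _uniform_on(list(range(1, 10)))),
    # short of the 75% supermajority in round 2 (P(7-9) = 0.70) but with a
    # median of 7, so conforming dissenters push it over in round 3
    "converging": ArchetypeSpec(
        "converging",
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.30, 0.30, 0.25, 0.15),
        conformity_prob=0.5,
    ),
}


@dataclass(frozen=True)
class PanelDesign:
    """Which archetype each item follows, plus panel size and seed.

    The default panel size of 76 mirrors the typical headcount of a
    hospital-wide expert panel (physicians, nurses, hospital pharmacists,
    IT specialists) in the consensus studies this generator emulates.
    """

    items: tuple[tuple[str, str], ...]  # (item_id, archetype name)
    n_panelists: int = 76
    seed: int = 0
    archetypes: Mapping[str, ArchetypeSpec] = field(default_factory=lambda: dict(ARCHETYPES))

    def __post_init__(self) -> None:
        items = tuple((str(i), str(a)) for i, a in self.items)
        if len({i for i, _ in items}) != len(items):
            raise ValidationError("duplicate item ids in panel design")
        for item_id, arch in items:
            if arch not in self.archetypes:
                raise ValidationError(
                    f"item {item_id!r}: unknown archetype {arch!r}"
                )
        if self.n_panelists <= 0:
            raise ValidationError("n_panelists must be positive")
        object.__setattr__(self, "items", items)

    def archetype_of(self, item_id: str) -> ArchetypeSpec:
        for iid, arch in self.items:
            if iid == item_id:
                return self.archetypes[arch]
        raise KeyError(item_id)


def gen_votes(design: PanelDesign) -> VoteMatrix:
    """Draw the first voting round (round 2): i.i.d. scores per archetype."""
    rng = np.random.default_rng([design.seed, 2])
    item_ids = tuple(i for i, _ in design.items)
    panelists = tuple(f"p{p + 1:03d}" for p in range(design.n_panelists))
    cols = []
    for _, arch in design.items:
        dist = design.archetypes[arch].round2_distribution
        cols.append(rng.choice(SCORES, size=design.n_panelists, p=dist))
    scores = np.column_stack(cols)
    return VoteMatrix(
        round_label=2, panelist_ids=panelists, item_ids=item_ids, scores=scores
    )


def gen_round3(
    round2: VoteMatrix,
    feedback: Sequence[FeedbackPackage],
    design: PanelDesign,
    rules: RuleConfig = RuleConfig(),
) -> VoteMatrix:
    """Re-vote the equivocal items under the conformity model.

    Every panelist whose round-2 score lies outside the agree band moves to
    the (rounded) group median with the item archetype's conformity
    probability, and otherwise keeps their score.  Items present in the
    feedback set must be exactly those left equivocal in round 2.
    """
    result = run_round(round2, rules)
    equivocal = set(result.carried_forward)
    fb_items = {f.item_id for f in feedback}
    stray = fb_items - equivocal
    if stray:
        raise ValidationError(
            f"feedback provided for items not in the equivocal set: {sorted(stray)}"
        )
    medians = {f.item_id: f.group_median for f in feedback}
    for item_id in fb_items:
        expected = result.summaries[item_id].median
        if abs(medians[item_id] - expected) > 1e-9:
            raise ValidationError(
                f"feedback median for {item_id!r} ({medians[item_id]}) does not "
                f"match the round-2 group median ({expected})"
            )
    rng = np.random.default_rng([design.seed, 3])
    item_ids = tuple(i for i in round2.item_ids if i in fb_items)
    lo, hi = rules.agree_band
    cols = []
    for item_id in item_ids:
        col = round2.scores[:, round2.item_ids.index(item_id)].copy()
        target = int(np.clip(round_half_away(medians[item_id], 0), 1, 9))
        p = design.archetype_of(item_id).conformity_prob
        outside = (col < lo) | (col > hi)
        move = outside & (rng.random(col.size) < p)
        col[move] = target
        cols.append(col)
    scores = np.column_stack(cols) if cols else np.empty((round2.n_panelists, 0), int)
    return VoteMatrix(
        round_label=3,
        panelist_ids=round2.panelist_ids,
        item_ids=item_ids,
        scores=scores,
    )


@dataclass(frozen=True)
class PcmNoiseModel:
    """Latent-weight generative model for pairwise comparison matrices."""

    true_weights: PriorityVector
    sigma: float = 0.0
    discretize: bool = False
    n_participants: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")


def snap_to_saaty(value: float) -> float:
    """Nearest admissible Saaty value in log space; ties go to the larger."""
    logs = np.log(SAATY_SCALE)
    d = np.abs(np.log(value) - logs)
    best = d.min()
    candidates = SAATY_SCALE[d <= best + 1e-12]
    return float(candidates.max())


def gen_pcms(
    model: PcmNoiseModel, category: str = "synthetic"
) -> list[PairwiseComparisonMatrix]:
    """Generate one reciprocal judgment matrix per participant."""
    rng = np.random.default_rng([model.seed, 17])
    w = model.true_weights.weights
    n = w.size
    ratio = np.log(w[:, None]) - np.log(w[None, :])
    if not model.discretize and np.exp(np.abs(ratio)).max() > 9.0 + 1e-9:
        raise ValidationError(
            "true weight ratios exceed the Saaty domain [1/9, 9]; the "
            "generated matrices could not be valid judgments"
        )
    out = []
    for p in range(model.n_participants):
        eps = rng.normal(0.0, model.sigma, size=(n, n)) if model.sigma > 0 else np.zeros((n, n))
        m = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v = float(np.exp(ratio[i, j] + eps[i, j]))
                if model.discretize:
                    v = snap_to_saaty(min(max(v, 1.0 / 9), 9.0))
                else:
                    v = min(max(v, 1.0 / 9), 9.0)
                m[i, j] = v
                m[j, i] = 1.0 / v
        out.append(
            PairwiseComparisonMatrix(
                participant_id=f"participant-{p + 1}",
                category=category,
                item_ids=model.true_weights.item_ids,
                matrix=m,
            )
        )
    return out


def gen_likert(
    probs: Sequence[float],
    n: int,
    seed: int,
    statement_id: str = "synthetic",
    theme: str = "patient_safety",
) -> LikertItemCounts:
    """Draw multinomial response counts for one 5-level Likert statement."""
    p = np.asarray(probs, dtype=float)
    if p.size != 5 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("probs must be 5 non-negative values summing to 1")
    rng = np.random.default_rng([seed, 29])
    counts = rng.multinomial(n, p)
    return LikertItemCounts(
        statement_id=statement_id,
        theme=theme,
        counts=tuple(int(c) for c in counts),
        n_respondents=n,
    )
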