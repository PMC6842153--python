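# Methods

This note documents the statistical procedures the package implements, the
choices made where the methodology literature leaves options open, and what
the synthetic generators do and do not emulate.

## Delphi vote analysis

Votes are integers on a 1–9 agreement scale, partitioned into disagree
(1–3), partial (4–6) and agree (7–9) bands. Per item and round we report
Q1, median, Q3, IQR = Q3 − Q1 and the three band shares (percentages of the
voting panel).

**Quartile convention.** Quartiles use linear interpolation on the sorted
sample with inclusive endpoints — the spreadsheet `QUARTILE.INC` rule,
`numpy.percentile(..., method="linear")` — because panel studies of this
kind are overwhelmingly analysed in spreadsheets. The convention is
configurable (`exclusive`, `nearest`, `midpoint`) and recorded in output
metadata, since the include/exclude decision of a borderline item can
depend on it.

**The a priori rule.** An item is *included* when median ∈ [7, 9] AND
IQR ≤ 2 AND at least 75% of panelists voted in the agree band, *excluded*
under the mirror conditions on the disagree band, and *equivocal*
otherwise. Three reading decisions deserve note:

* The rule is a three-way conjunction; the supermajority is checked on the
  band matching the median's side. All boundaries are inclusive (median
  exactly 7, IQR exactly 2, agreement exactly 75% → include); this is the
  only reading consistent with published tables in which items at exactly
  75% agreement are included.
* A median of 6 (or any configuration matching neither rule) falls through
  to equivocal via the catch-all; the bands alone would leave it undefined.
* The exclusion branch is rarely exercised in practice (strongly worded
  candidate items are seldom voted down); it is implemented symmetrically
  with `pct_disagree ≥ 75`.

**Rounds and feedback.** Round labels start at 2 (the qualitative
item-collection stage is conventionally "round 1"). Equivocal items are
carried into the next round with a feedback package per panelist: own
score, group median, group IQR, and a pass-through comment summary — group
statistics identical across recipients. After `max_voting_rounds` (default
2) remaining equivocal items become *no consensus*; no further round is
conducted. Orchestration enforces that a later round re-votes exactly the
carried set; with summary-provenance inputs a carried item absent from the
next table can optionally be retained as equivocal (`on_missing="retain"`),
which is how studies that stop re-voting some items are reproduced.

**Missing votes.** A hard error by default. An explicit opt-in policy
(`missing="drop"`) drops the panelist for that item and recomputes
percentages on the reduced denominator, with a loud log line.

**Display rounding.** All reported percentages are rounded
half-away-from-zero to one decimal (spreadsheet tie behaviour, not
banker's rounding); full precision is kept internally. Published in-text
figures that conflict with this rounding of their own tables (truncation
artefacts) are not chased.

## AHP priorities and consistency

Judgments form positive reciprocal matrices on the Saaty domain
a_ij ∈ [1/9, 9] with a_ii = 1; upper-triangle input is completed by
reciprocals. Priorities are the principal right eigenvector, computed by
power iteration from the uniform vector, convergence when successive
sum-normalised iterates differ by < 1e-12 in max norm (the Perron
eigenvalue of a positive matrix is simple, so the iteration converges
linearly; non-convergence within 10 000 iterations raises). λ_max is
estimated as the mean of (A w)_i / w_i. The row-geometric-mean method is
available as a cross-check flag; the two coincide on consistent matrices.

Consistency uses CI = (λ_max − n)/(n − 1) and CR = CI/RI with Saaty's
random indices RI(1..15) = 0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45,
1.49, 1.51, 1.48, 1.56, 1.57, 1.59. Sizes 1–2 are always perfectly
consistent (CR defined as 0). n = 16 — the largest category size arising
in practice here — has no tabulated value; a flat extrapolation RI = 1.60
is available behind an explicit flag rather than silently. Acceptance is
strict: CR < 0.1; a matrix at exactly 0.1 is rejected and logged, not
repaired (consistency-improvement algorithms are out of scope).

**Group aggregation** follows aggregation of individual priorities (AIP):
the accepted participants' percent weights are averaged item-wise, which
guarantees category means sum to 100 exactly — matching how published
group tables close to 100%. The SD is the sample standard deviation (n − 1
denominator, the spreadsheet default; the alternative is not
distinguishable from published tables), defined as 0 for a single accepted
participant. Zero accepted participants is an error instructing
re-elicitation. Ranking is by descending mean weight with ties broken by
catalog order, so output is deterministic.

## Weight comparisons

One-way fixed-effects ANOVA treats the k items of a category as groups and
the accepted participants' weights as replicates (balanced by
construction, since every participant contributes a full vector). The
post-hoc is the classical Bonferroni procedure: two-sided t tests on all
k(k−1)/2 pairs using the pooled residual variance with N − k degrees of
freedom, raw p multiplied by the number of comparisons and capped at 1.
Per-pair Welch tests are available as an option. Stars encode the adjusted
p with strict thresholds (`*` < 0.05, `**` < 0.01, `***` < 0.001,
`****` < 0.0001; exactly 0.05 is ns).

A caveat is enforced as a runtime warning: weights within one participant
are compositional (they sum to 100), so replicates are not independent
across items. The classical analysis is performed regardless because it is
the field's standard reporting; the warning keeps users honest about what
the p-values mean.

## Synthetic data

The generators exist so that every stage has inputs with known ground
truth; they are first-class, tested code.

**Votes.** Each item follows an archetype — a probability mass over 1–9
for the first voting round plus a conformity probability. Built-ins:
`strong_include` (uniform on 7–9; inclusion is analytically forced:
median ≥ 7, IQR ≤ 2, 100% agreement), `strong_exclude` (mirror),
`equivocal` (uniform on 1–9; the agree count is Binomial(n, 1/3), so a 75%
supermajority has vanishing probability at n = 76), and `converging`
(mass 0.30/0.30/0.25/0.15 on 6/7/8/9: ~70% agreement in round 2 — short of
the supermajority — with median 7, so that conforming dissenters cross the
threshold in round 3). The default panel size is 76, the headcount of the
packaged study's panel.

**Conformity model.** After feedback, each panelist whose score lies
outside the agree band moves to the rounded group median with probability
p (per-item archetype parameter, default 0.5) and otherwise keeps their
score. This is deliberately the *minimal* mechanism that reproduces the
observed round-to-round convergence pattern; it does not model anchoring,
attrition (the emulated study had 100% response), or any panelist-level
heterogeneity. Passing tests therefore show the pipeline is correct under
i.i.d. archetype voting with move-to-median updating — not that real
expert panels behave this way.

**Pairwise matrices.** a_ij = (w_i/w_j)·exp(ε_ij) with ε_ij ~ N(0, σ²)
i.i.d. on the upper triangle, reciprocals enforced, values clamped to
[1/9, 9]. σ = 0 without discretisation yields exactly consistent matrices
that recover the latent weights to 1e-8 with CR = 0; mean CR rises
monotonically with σ. Optional discretisation snaps each entry to the
nearest Saaty value in log space, ties to the larger value; snapping alone
introduces (bounded) inconsistency, which is why the zero-noise identity
is stated for the non-discretised case. Latent weight vectors whose ratios
exceed 9 are rejected rather than silently clamped.

**Likert counts** are multinomial draws. All generators take an explicit
seed and derive their streams from `numpy.random.default_rng` seeded with
(seed, stream-id), so vote, matrix and Likert draws are independent and
the same seed reproduces outputs bit-for-bit.

## The packaged study fixture

The fixture transcribes a published two-round study: per-item
(median, IQR, %agree) for round 2 (all 122 items) and round 3 (the 45
re-voted items), group weight means/SDs per category, Likert merit counts
(12 statements × 76 respondents), and recruitment accounting (25 invited,
19 interviewed, 76 panelists, 10 AHP participants). Load-time assertions
check the 110/12 split, the category sizes (16, 16, 16, 14, 13, 12, 11, 9,
3) and the 100% weight closure per category.

Because only summaries were published, summary-provenance classification
builds `ItemSummary` objects from the printed triples; the unknown split
between the partial and disagree bands is booked under "partial", which
cannot affect any decision when the median exceeds 3 (the exclusion branch
is unreachable there). The study roll-forward applies the round-3 rule to
consensus-table items only and retains the remainder as no-consensus: one
printed no-consensus row carries round-3 statistics that would satisfy the
stated rule, and this package reproduces the study's published
adjudication rather than re-litigating it (the raw votes that could settle
the discrepancy were never released). The published round-3 share "27.1%"
likewise does not equal one-decimal rounding of 33/122 and is not
reproduced. Per-item weight values and the supplementary p-values depend
on unpublished raw matrices, so they are covered by property-based tests
on synthetic data instead of numeric reproduction.

## Problem sizes and tolerances in the test suite

Oracle comparisons use 1000 random panels for quartiles (brute-force
sort-and-interpolate oracle, tolerance 1e-12), 100+ random reciprocal
matrices of sizes 3–9 against a dense eigensolver (tolerance 1e-8),
400-replicate Monte-Carlo for the conformity model (3-sigma binomial
bands), 100 seeds for archetype recovery (forced labels exact, equivocal
≥ 95%), and 200 matrices per noise level for the CR monotonicity check.
These sizes keep the full suite to a few seconds while leaving the
statistical checks far from their decision boundaries.
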