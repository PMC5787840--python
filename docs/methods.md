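# Methods

## Study design the package models

The workflow compares cultivar pairs with shared ancestry but contrasting
drought tolerance. Each pair contributes six conditions — {tolerant,
sensitive} × {day 0, day 6, day 10 of drought} — with three biological
replicates each. Day 0 is the pre-stress control; day 6 corresponds to the
peak of the ABA-marker response and day 10 to an extended-drought state with
a weaker marker signal. All statistics operate on gene-level expression
obtained by summing the normalized values of a gene's splicing isoforms.

## Normalization and aggregation

Counts are library-normalized before testing. The default is counts per
million (CPM); median-of-ratios size factors (per-sample median of
count/geometric-mean-reference over features with no zero count) are
selectable. The normalized matrix records the method and the per-sample
scale `c_j` with `raw_count = value × c_j`, so count-based variance models
stay exact on the normalized scale at any library depth.

Isoform aggregation sums transcript values per gene and conserves
per-sample totals exactly. The pipeline normalizes transcript values first
and then aggregates (the order used in the emulated study); the opposite
order is supported via `SelectionConfig.aggregate_after_normalize=False`
and is logged in the run's preprocessing record. Under CPM the two orders
give identical gene values; they differ only for median-of-ratios factors
estimated at transcript vs gene level.

CPM carries the usual composition caveat: if a large fraction of the
library is differentially expressed, normalization transfers part of the
effect onto null genes. At the default planting density (1% of genes,
8-fold) the transfer is ~7% on cross-cultivar contrasts and does not move
the error rates measurably; median-of-ratios is the robust alternative.

## The count model and test

Counts are modelled as negative binomial with gene-wise dispersion α
(variance = μ + αμ²). For a contrast of groups A and B the test is a Wald
test on the difference of log means: the group means are taken on the
normalized scale, the variance of each group mean is the model-based
`μ·Σ(1/c_j)/n² + αμ²/n`, mapped to the log scale by the delta method, and
the two-sided p-value comes from the normal reference. Fold changes use a
pseudocount, FC = (m_A + c)/(m_B + c) with c = 0.5 by default, so zero
means stay finite; genes with zero counts everywhere get p = 1 and no
direction call. Benjamini–Hochberg adjustment is applied within each
contrast family; `q ≥ p` always.

### Dispersion estimation

With three replicates a gene-wise method-of-moments estimate
`max(0, (s² − μ)/μ²)` has ~4 residual degrees of freedom and is far too
noisy to test with, and its truncation at zero biases it upward exactly for
low-dispersion genes. The working dispersion therefore comes from a
mean–dispersion trend `α(μ) = a0 + a1/μ` fitted across all genes on the
*untruncated* moment excesses by weighted least squares with
inverse-variance weights ∝ μ² (the sampling variance of the excess scales
as 1/μ², so unweighted fitting lets a handful of low-mean genes swing the
1/μ coefficient wildly). Coefficients are clamped at zero; a
`shrink_weight` parameter blends the gene-wise estimate back in for users
who want gene-specific dispersion, with 0 (trend only) as the default —
the standard choice for 3-replicate designs. Trend-only dispersion
underfits genuine dispersion outliers; that is a known trade-off at this
replication level.

Calibration under a Poisson null (2,000 genes, lognormal means around 100,
n = 3 per group) gives rejection rates of 0.036–0.056 at the nominal 0.05
across seeds; under a true NB with α = 0.05 the trend intercept is
recovered at ≈ 0.052.

## The selection cascade

Round 1 applies three criteria per cultivar pair, each on its own DE table:

1. **Day-0 equivalence** — tolerant vs sensitive at day 0 must be
   *insignificant* (unadjusted p ≥ α) **and** |log2FC| < 1. The raw p-value
   is used because "failing to reject" is the filter the design prescribes;
   the fold-change guard keeps low-power genes from passing on noise alone.
2. **Temporal response** — tolerant cultivar day 0→6 or 0→10 with q < α.
3. **Cross-cultivar separation** — tolerant vs sensitive at day 6 or day 10
   with q < α (OR over days; the design text admits either day).

Direction labels (up/down) follow the sign of the tolerant-vs-sensitive
log2FC on the significant drought day(s); genes significant on both days
with opposite signs are recorded as ambiguous and excluded. α defaults to
0.05.

Round 2 scores survivors by max(|log2FC day 6|, |log2FC day 10|) of the
cross-cultivar contrast and keeps the top k, ties broken by the smaller
q-value then lexicographic gene id. k defaults to ⌈25% of round 1⌉, echoing
the ratio such pipelines typically pass to confirmation.

Round 3 derives a per-day direction profile from the tolerant cultivar's
temporal contrasts — up/down if |log2FC| ≥ 0.25, else none — and keeps a
gene only if the orthogonal platform's profile matches on *every* drought
day; `none` on either side never matches. No significance requirement is
imposed here because the orthogonal platform (semi-quantitative RT-PCR)
yields direction calls, not calibrated p-values. Candidates without an
orthogonal profile are dropped with a warning and logged.

The overall selected set is the union of per-pair round-3 sets; a gene
selected in several pairs is counted once.

**Stable (reference) genes** are selected independently: for every cultivar
and every drought day the pseudocounted ratio mean(day d)/mean(day 0) must
lie strictly inside (0.8, 1.2); genes with an all-zero day-0 mean in any
cultivar are excluded. The window is strict — a ratio of exactly 1.2
excludes the gene.

## Cross-species concordance bookkeeping

Homologue direction calls use a closed six-symbol alphabet relative to the
potato gene's response: same_up (↗), same_down (↘), no_change (–), no_data
(nd), no_homologue, opposite (≠). The four primary categories — conserved
in all three species, rice only, Arabidopsis only, no-data-or-no-change —
partition the calls: a species "conserves" the response iff its symbol is
same_up or same_down. `opposite_any` counts genes with ≥ 1 opposite symbol
and deliberately overlaps the single-species categories: a gene opposite in
Arabidopsis and concordant in rice counts under both conserved_rice_only
and opposite_any. This is the only convention under which the published
per-category counts (6, 9, 1, 2 over 23 genes) are simultaneously
consistent with the printed symbol table, and the packaged transcription of
that table reproduces them.

## Physiology

RWC = (FW − DW)/(SW − DW) × 100 — the standard definition from fresh,
saturated and dry weights; it is invariant to the mass unit and bounded in
[0, 100] whenever DW ≤ FW ≤ SW, which the record parser enforces. Time
courses are rescaled to percent of the day-0 value.

The Mann-Whitney U test enumerates all C(n+m, n) rank assignments when
n + m ≤ 12 and the pooled sample has no ties, and reports the exact
two-sided p = P(|U − nm/2| ≥ |u_obs − nm/2|); otherwise midranks with the
tie-corrected normal approximation (no continuity correction) are used, and
the result records which path ran. The cutoff of 12 keeps the worst case at
924 assignments; it is configurable.

## Synthetic data

The generator reproduces the study's shape at desk scale: 2 pairs × 2
cultivars × 3 days × 3 replicates, ~10⁶ reads per library (the real
libraries ran ~40× deeper; the cascade is depth-invariant under library
normalization, so tests run at reduced scale), with ~5% lognormal
depth jitter matching the narrow depth range of the emulated libraries.
Gene baselines are lognormal (median ≈ 300 after rescaling library totals);
counts are NB with dispersion 0.05. Each gene is emitted as 1–3 isoforms
whose means partition the gene mean (Dirichlet(5) shares), so aggregation
is exercised everywhere.

Planted responsive genes (20 per pair by default, one shared across pairs)
receive a multiplicative effect in their pair's tolerant cultivar only, on
drought days only: 2^±3 at day 6 and 2^±1.8 at day 10 (the day-10 exponent
is damped to 0.6× the day-6 peak, mirroring the weaker late-drought marker
response), half up / half down. Planted stable genes emulate housekeeping
references: high baseline (pinned at 2000 pre-rescaling) and low
dispersion (0.005). The low dispersion is not cosmetic: with α = 0.05 and
n = 3 the ratio of two replicate means has CV ≈ 0.18, the strict
(0.8, 1.2) window would be passed per cell only ~73% of the time, and no
screen could recover such genes — real reference genes are precisely the
high-expression low-variability ones.

Orthogonal profiles copy each responsive gene's true direction per day with
probability `concordance_rate` (default 1), otherwise flip or zero it;
non-responsive genes read `none`. Leaf-weight triples are built backwards
from a target RWC (normal noise, rejection outside (0.5, 99.5)) with
DW = 0.2·SW, so the weight-ordering invariant holds by construction.

What the generator does *not* emulate: gene–gene correlation, GC/length
biases, batch effects, outlier replicates, and sensitive-cultivar partial
responses (effects are tolerant-only by default). Passing tests therefore
demonstrate correctness of the cascade's logic and calibration under the
assumed NB model, not robustness to every artefact of real RNA-seq.

## Validation at study scale

The acceptance checks (tests/test_acceptance.py, scripts/acceptance.py)
run: the packaged 23-gene concordance tally; exact-Mann-Whitney agreement
with an independent exact-distribution oracle for all n, m ≤ 6; type-I
error of the NB test on a 2,000-gene Poisson null (0.05 ± 0.02); and 20
replicate simulations (2,000 genes, 20 planted responsive per pair at
|log2FC| = 3, α = 0.05, n = 3) where round-1 mean sensitivity is ≈ 0.95
(floor 0.9), empirical FDR ≈ 0.02–0.04 (ceiling 0.1) and stable-gene
recall 1.0 (floor 0.9). Sensitivity is bounded near 0.95 by design: the
day-0 equivalence criterion rejects truly equivalent genes at its own
type-I rate (~5%), an intrinsic cost of filtering on insignificance. These
problem sizes keep the full suite under ~10 s on one CPU.

## Numerical and degenerate-input conventions

- Pseudocount 0.5 guards every fold change and log-mean variance.
- All-zero genes: α = 0 with a degenerate flag; p = 1; direction none.
- Round-2 ties: smaller q, then gene id (total order, deterministic runs).
- Reports serialize with sorted keys and sorted gene lists; rerunning a
  manifest reproduces outputs byte-identically, and permuting input sample
  order leaves the report unchanged.
- A single CLI seed is recorded in every manifest; stage generators derive
  their streams from fixed-offset `SeedSequence` children so stage-level
  reruns reproduce.
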