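# droughtdex

Selection of drought-responsive genes from paired drought-tolerant /
drought-sensitive cultivar transcriptomes.

## The problem

A robust way to find genes that matter for drought tolerance — rather than
genes that merely react to drying — is to compare closely related cultivar
pairs in which one member tolerates water shortage and the other does not
(e.g. the potato pairs Gwiazda/Oberon and Tajfun/Owacja), sampled over a
drought time course (days 0, 6 and 10, three biological replicates). A gene
is a credible tolerance candidate when it starts from the *same* expression
level in both cultivars before stress, responds to drought in the tolerant
cultivar, and separates the tolerant from the sensitive cultivar once the
stress is on.

`droughtdex` implements that comparative workflow end to end for bulk
RNA-seq counts, plus the physiological and cross-species companions such a
study needs, and a synthetic-data generator with ground truth so the whole
cascade can be validated without any sequencing data.

## What is in the box

- **`droughtdex.expression`** — count-matrix / design / transcript-map TSV
  I/O, isoform-to-gene aggregation (per-sample totals conserved exactly) and
  library normalization (CPM, or median-of-ratios size factors).
- **`droughtdex.diffexp`** — per-gene negative-binomial Wald test
  (variance mu + alpha mu^2, method-of-moments dispersion with a weighted
  mean-dispersion trend fit), pseudocounted fold changes
  FC = (m_a + c)/(m_b + c) with c = 0.5, Benjamini-Hochberg adjustment.
- **`droughtdex.selection`** — the three-round cascade:
  1. keep genes with day-0 equivalence across the pair (unadjusted p >= 0.05
     and |log2FC| < 1), a significant temporal response in the tolerant
     cultivar (day 0->6 or 0->10, q < 0.05), and a significant
     tolerant-vs-sensitive difference on a drought day (q < 0.05);
  2. rank by the largest tolerant-vs-sensitive |log2FC| over drought days
     and keep the top k (default: top quarter);
  3. confirm the per-day direction of change against an orthogonal platform
     (RT-PCR-like profiles).
  Plus the stable-reference-gene selector: genes with every per-cultivar
  day-vs-day-0 fold change strictly inside (0.8, 1.2).
- **`droughtdex.concordance`** — platform direction concordance and
  cross-species (potato / Arabidopsis / rice) direction-concordance
  categories, including the published 23-gene symbol table as a packaged
  worked example.
- **`droughtdex.physiology`** — relative water content
  RWC = (FW − DW)/(SW − DW) × 100 from leaf weight triples, percent-of-day-0
  scaling, and a Mann-Whitney U test that is exact (full enumeration of all
  C(n+m, n) rank assignments) for small untied samples.
- **`droughtdex.simulate`** — synthetic experiments with planted responsive
  genes, planted housekeeping-like stable genes, isoform structure and NB
  noise; orthogonal-platform profiles; leaf-weight records.
- **`droughtdex.cli`** — `droughtdex simulate | select | concordance | rwc`,
  each writing a JSON manifest (config snapshot, input hashes, seed) so runs
  reproduce byte-identically.

## Worked example

```bash
python examples/run_selection_pipeline.py
```

```
P1: round1  19 genes (9 up / 10 down, 19/20 planted recovered) -> round2 19 -> round3 19
P2: round1  20 genes (13 up / 7 down, 19/20 planted recovered) -> round2 20 -> round3 19
stable reference candidates: 542 (all 8 planted stable genes included: True)
overall selected: 37 (per-pair round-3 sum 38; genes selected in both pairs are counted once)
```

Two simulated cultivar pairs, 2,000 genes, 20 planted drought-responsive
genes per pair (one planted in *both* pairs): round 1 recovers 19/20 planted
genes per pair at roughly one false positive; the orthogonal-platform round
removes candidates whose direction of change does not reproduce; and the
overall set counts the gene shared by both pairs once (38 selections, 37
genes). The stable-gene list is a superset of the 8 planted housekeeping
genes — many null genes are also flat, which is exactly what a
reference-gene screen on real data looks like.

The other examples print the cross-species concordance tallies for the
published 23-gene table (`cross_species_concordance.py`: 6 conserved in all
three species, 9 in rice only, 1 in Arabidopsis only, 2 opposite), an
annotated NB test on a toy matrix (`differential_testing.py`), and an RWC
group comparison with the exact Mann-Whitney test (`rwc_comparison.py`:
fully separated 3-vs-3 groups give the minimum attainable two-sided
p = 0.1).

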