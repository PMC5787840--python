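"""Synthetic drought-transcriptome experiments with ground truth.

The generator emulates the study design behind the pipeline: two pairs of
drought-tolerant/drought-sensitive potato cultivars sampled at days 0, 6 and
10 of drought with three biological replicates each, sequenced to a desk-scale
depth of ~1e6 reads per library (the real experiment ran ~40x deeper; the
filter logic is depth-invariant under library normalization, so tests run at
reduced scale).

Counts are negative binomial around gene baselines drawn from a log-normal;
planted drought-responsive genes get a multiplicative effect in the tolerant
cultivar of their pair on drought days only (the day-10 effect is a damped
version of the day-6 peak, mirroring the weaker late-drought response of ABA
markers). Planted stable genes emulate housekeeping references: high
baseline, low dispersion, no condition effect. Each gene is emitted as 1-3
splicing isoforms whose means partition the gene mean, so isoform
aggregation is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import (
    ExpressionMatrix,
    SampleDesign,
    TranscriptGeneMap,
    TRANSCRIPT,
    TOLERANT,
    SENSITIVE,
)
from .physiology import RWCRecord

RESPONSIVE_UP = "responsive_up"
RESPONSIVE_DOWN = "responsive_down"
STABLE = "stable"
NULL = "null"


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults mirror the emulated experiment: 2 cultivar pairs, days 0/6/10,
    3 replicates, 1e6 reads/library with ~5% depth jitter (the real libraries
    spanned a ~10% range), NB dispersion 0.05, 20 planted responsive genes
    per pair at a day-6 peak of |log2FC| = 3 with the day-10 effect damped to
    0.6x on the log2 scale, half up / half down, tolerant cultivar only.
    Planted stable genes are housekeeping-like (high mean, dispersion 0.005).
    """

    n_genes: int = 2000
    n_pairs: int = 2
    days: tuple[int, ...] = (0, 6, 10)
    replicates: int = 3
    library_size: float = 1e6
    depth_jitter_sd: float = 0.05  # lognormal sigma on per-sample depth
    baseline_meanlog: float = math.log(100.0)
    baseline_sdlog: float = 1.0
    dispersion: float = 0.05
    n_responsive: int = 20  # per pair
    responsive_log2fc: float = 3.0
    up_fraction: float = 0.5
    day10_factor: float = 0.6
    tolerant_only: bool = True
    n_stable: int = 8
    stable_mean: float = 2000.0
    stable_dispersion: float = 0.005
    n_shared: int = 1  # responsive genes planted in every pair
    max_isoforms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_pairs * self.n_responsive - (self.n_pairs - 1) * self.n_shared
        if planted + self.n_stable > self.n_genes:
            raise ValueError("more planted genes than genes in the experiment")
        if self.n_shared > self.n_responsive:
            raise ValueError("n_shared cannot exceed n_responsive")
        if not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must be in [0, 1]")
        if self.days[0] != 0:
            raise ValueError("first day must be 0 (control)")


@dataclass
class GroundTruth:
    """Per-gene truth labels written alongside every simulated dataset."""

    table: pd.DataFrame  # index gene_id; columns: class, pair_id, shared
    seed: int

    def genes(self, cls: str, pair_id: str | None = None) -> list[str]:
        t = self.table
        mask = t["class"] == cls
        if pair_id is not None:
            mask &= t["pair_id"].str.contains(pair_id, regex=False)
        return sorted(t.index[mask])

    def responsive(self, pair_id: str | None = None) -> list[str]:
        return sorted(
            set(self.genes(RESPONSIVE_UP, pair_id)) | set(self.genes(RESPONSIVE_DOWN, pair_id))
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha mu^2; Poisson when alpha == 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, TranscriptGeneMap, SampleDesign, GroundTruth]:
    """Draw one full synthetic experiment.

    Returns a transcript-level count matrix, the isoform->gene map, the
    sample design and the ground truth. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes = [f"g{idx:05d}" for idx in range(cfg.n_genes)]

    # assign classes: shared responsive first, then per-pair responsive, then stable
    pair_ids = [f"P{i + 1}" for i in range(cfg.n_pairs)]
    order = rng.permutation(cfg.n_genes)
    cursor = 0

    def _take(k):
        nonlocal cursor
        sel = [genes[i] for i in order[cursor : cursor + k]]
        cursor += k
        return sel

    shared = _take(cfg.n_shared)
    per_pair = {p: shared + _take(cfg.n_responsive - cfg.n_shared) for p in pair_ids}
    stable_genes = _take(cfg.n_stable)

    direction: dict[str, int] = {}
    for p in pair_ids:
        for g in per_pair[p]:
            if g not in direction:
                direction[g] = 1 if rng.random() < cfg.up_fraction else -1

    truth_rows = []
    for g in genes:
        if g in direction:
            cls = RESPONSIVE_UP if direction[g] > 0 else RESPONSIVE_DOWN
            membership = "+".join(p for p in pair_ids if g in per_pair[p])
        elif g in stable_genes:
            cls, membership = STABLE, ""
        else:
            cls, membership = NULL, ""
        truth_rows.append(
            {"gene_id": g, "class": cls, "pair_id": membership, "shared": g in shared}
        )
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows).set_index("gene_id"), seed=cfg.seed
    )

    # baselines: lognormal, stable genes pinned high, rescaled to library depth
    baseline = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_genes)
    base = pd.Series(baseline, index=genes)
    base[stable_genes] = cfg.stable_mean
    base *= cfg.library_size / base.sum()

    # isoform structure
    n_iso = rng.integers(1, cfg.max_isoforms + 1, cfg.n_genes)
    transcripts, t_gene, t_share = [], [], []
    for g, k in zip(genes, n_iso):
        shares = rng.dirichlet(np.full(k, 5.0))
        for j in range(k):
            transcripts.append(f"{g}.{j + 1}")
            t_gene.append(g)
            t_share.append(shares[j])
    tmap = TranscriptGeneMap(pd.Series(t_gene, index=transcripts))
    share = np.asarray(t_share)
    t_base = base.reindex(t_gene).to_numpy() * share

    # design
    design_rows = []
    for i, p in enumerate(pair_ids):
        for cls, tag in ((TOLERANT, "T"), (SENSITIVE, "S")):
            cultivar = f"{tag}{i + 1}"
            for d in cfg.days:
                for r in range(1, cfg.replicates + 1):
                    design_rows.append(
                        {
                            "sample_id": f"{cultivar}_d{d}_r{r}",
                            "cultivar": cultivar,
                            "pair_id": p,
                            "tolerance_class": cls,
                            "day": d,
                            "replicate": r,
                        }
                    )
    design = SampleDesign(pd.DataFrame(design_rows))

    # effect per (gene, cultivar, day) on log2 scale
    day_damp = {d: (1.0 if d == cfg.days[1] else cfg.day10_factor) for d in cfg.days[1:]}
    alpha_per_t = np.where(
        pd.Series(t_gene).isin(stable_genes).to_numpy(),
        cfg.stable_dispersion,
        cfg.dispersion,
    )

    counts = {}
    for row in design.table.itertuples():
        depth = float(np.exp(rng.normal(0.0, cfg.depth_jitter_sd)))
        mean = t_base * depth
        if row.day != 0:
            affected = per_pair.get(row.pair_id, [])
            if affected and (row.tolerance_class == TOLERANT or not cfg.tolerant_only):
                eff = np.ones(len(transcripts))
                idx = pd.Series(t_gene).isin(affected).to_numpy()
                signs = np.array([direction.get(g, 0) for g in t_gene])
                lfc = cfg.responsive_log2fc * day_damp[row.day] * signs
                eff[idx] = 2.0 ** lfc[idx]
                mean = mean * eff
        col = np.empty(len(transcripts), dtype=np.int64)
        # draw per-dispersion-class to keep a single vectorized call each
        for a in np.unique(alpha_per_t):
            sel = alpha_per_t == a
            col[sel] = _nb_draw(rng, mean[sel], float(a))
        counts[row.sample_id] = col
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(transcripts, name="feature_id"), dtype=float),
        level=TRANSCRIPT,
    )
    return matrix, tmap, design, truth


def simulate_orthogonal(
    truth: GroundTruth,
    concordance_rate: float = 1.0,
    seed: int = 0,
    days: tuple[int, ...] = (6, 10),
) -> dict[str, pd.DataFrame]:
    """Orthogonal-platform (RT-PCR-like) direction profiles per pair.

    Each responsive gene's true direction is reproduced independently per day
    with probability ``concordance_rate``; otherwise it is flipped or zeroed
    (half/half). Non-responsive genes read ``none`` on every day.
    """
    if not 0 <= concordance_rate <= 1:
        raise ValueError("concordance_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    pair_ids = sorted(
        {p for cell in truth.table["pair_id"] if cell for p in cell.split("+")}
    ) or ["P1"]
    out = {}
    for pair in pair_ids:
        rows = {}
        responsive = set(truth.responsive(pair))
        up_genes = set(truth.genes(RESPONSIVE_UP, pair))
        for gene in truth.table.index:
            if gene in responsive:
                true_dir = "up" if gene in up_genes else "down"
                calls = []
                for _ in days:
                    if rng.random() < concordance_rate:
                        calls.append(true_dir)
                    elif rng.random() < 0.5:
                        calls.append("down" if true_dir == "up" else "up")
                    else:
                        calls.append("none")
                rows[gene] = calls
            else:
                rows[gene] = ["none"] * len(days)
        out[pair] = pd.DataFrame.from_dict(rows, orient="index", columns=list(days))
    return out


def simulate_rwc(
    groups: dict[str, tuple[float, int]],
    noise_sd: float = 3.0,
    seed: int = 0,
    day: int = 0,
    saturated_weight: float = 1.0,
    dry_fraction: float = 0.2,
) -> list[RWCRecord]:
    """Leaf weight triples whose implied RWC follows the requested group means.

    ``groups`` maps a label to ``(mean_rwc_percent, n_leaves)``. RWC values
    are drawn Normal(mean, noise_sd) and rejected outside (0.5, 99.5); the
    triple is built as DW = dry_fraction * SW and FW = DW + RWC/100*(SW-DW),
    which satisfies DW <= FW <= SW by construction.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    records = []
    for label, (mean_rwc, n) in sorted(groups.items()):
        for i in range(n):
            rwc = rng.normal(mean_rwc, noise_sd)
            while not 0.5 < rwc < 99.5:
                rwc = rng.normal(mean_rwc, noise_sd)
            sw = saturated_weight * float(np.exp(rng.normal(0, 0.05)))
            dw = dry_fraction * sw
            fw = dw + rwc / 100.0 * (sw - dw)
            records.append(
                RWCRecord(label=f"{label}_{i + 1}", fw=fw, sw=sw, dw=dw, day=day, genotype=label)
            )
    return records


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")


def read_truth(path, seed: int = 0) -> GroundTruth:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={"pair_id": str})
    frame["pair_id"] = frame["pair_id"].fillna("")
    return GroundTruth(table=frame, seed=seed)
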