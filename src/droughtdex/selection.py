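"""Three-round drought-gene selection cascade and stable-gene selector.

For each tolerant/sensitive cultivar pair the cascade runs on five per-gene
contrast tables:

* round 1 keeps genes that (i) start from the same expression level at day 0
  across the pair (equivalence: unadjusted p >= alpha AND |log2FC| below a
  bound), (ii) change significantly over time in the tolerant cultivar
  (day 0 -> 6 or 0 -> 10, q < alpha), and (iii) differ significantly between
  tolerant and sensitive on at least one drought day (q < alpha);
* round 2 ranks survivors by the largest tolerant-vs-sensitive |log2FC| over
  the drought days and keeps the top k;
* round 3 keeps only genes whose direction of change versus day 0 agrees with
  an orthogonal platform (RT-PCR-like) on every drought day.

Genes selected in several pairs are counted once in the overall set.
Separately, genes whose expression stays within a strict fold-change window
(default 0.8 < FC < 1.2) versus day 0 in every cultivar on every drought day
are reported as candidate reference (normalization-control) genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import concordance as conc
from .diffexp import (
    DispersionEstimate,
    estimate_dispersion,
    fold_change,
    test_two_groups,
    UP,
    DOWN,
    NONE,
)
from .expression import (
    ExpressionMatrix,
    SampleDesign,
    TranscriptGeneMap,
    aggregate_isoforms,
    normalize,
    GENE,
    TRANSCRIPT,
    TOLERANT,
    SENSITIVE,
)


class SelectionError(ValueError):
    """Raised for inconsistent selection inputs."""


@dataclass
class SelectionConfig:
    """Tunable thresholds of the cascade.

    alpha: significance level for the q-value cuts and the day-0 equivalence
    p-cut. equivalence_log2fc: |log2FC| guard for day-0 equivalence (prevents
    low-power pass-through). stable_low/high: strict fold-change window for
    reference genes. round2_k: number of genes kept in round 2; ``None`` keeps
    ``ceil(round2_fraction * |round 1|)``. round3_min_log2fc: |log2FC| floor
    below which a temporal change counts as no change when calling platform
    directions. norm_method / aggregate_after_normalize control the
    preprocessing order (isoform values are normalized, then summed per gene).
    """

    alpha: float = 0.05
    equivalence_log2fc: float = 1.0
    stable_low: float = 0.8
    stable_high: float = 1.2
    round2_k: int | None = None
    round2_fraction: float = 0.25
    round3_min_log2fc: float = 0.25
    pseudocount: float = 0.5
    norm_method: str = "cpm"
    aggregate_after_normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise SelectionError("alpha must be in (0, 1)")
        if not self.stable_low < 1 < self.stable_high:
            raise SelectionError("stable window must bracket 1")


@dataclass
class PairSelection:
    """Selection outcome for one cultivar pair."""

    pair_id: str
    round1_up: list[str]
    round1_down: list[str]
    round1_ambiguous: list[str]
    round2: list[str]
    round3: list[str]
    audit: pd.DataFrame

    @property
    def round1(self) -> list[str]:
        return sorted(self.round1_up + self.round1_down)


@dataclass
class SelectionReport:
    """Full cascade outcome: per-pair rounds, stable genes, cross-pair union."""

    pairs: dict[str, PairSelection]
    stable_genes: list[str]
    overall_selected: list[str]
    config: SelectionConfig
    seed: int | None = None
    preprocessing: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "seed": self.seed,
            "preprocessing": self.preprocessing,
            "stable_genes": sorted(self.stable_genes),
            "overall_selected": sorted(self.overall_selected),
            "pairs": {
                pid: {
                    "round1_up": sorted(p.round1_up),
                    "round1_down": sorted(p.round1_down),
                    "round1_ambiguous": sorted(p.round1_ambiguous),
                    "round2": list(p.round2),
                    "round3": sorted(p.round3),
                }
                for pid, p in sorted(self.pairs.items())
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_universe(tables: list[pd.DataFrame]) -> pd.Index:
    universe = tables[0].index
    for t in tables[1:]:
        if not universe.equals(t.index):
            raise SelectionError("DE tables cover different gene universes")
    return universe


def round1_filter(
    de_day0_cross: pd.DataFrame,
    de_tolerant_0v6: pd.DataFrame,
    de_tolerant_0v10: pd.DataFrame,
    de_cross_day6: pd.DataFrame,
    de_cross_day10: pd.DataFrame,
    cfg: SelectionConfig,
) -> dict:
    """Triple-criterion round-1 filter.

    Returns ``{"up": [...], "down": [...], "ambiguous": [...], "audit": frame}``.
    Direction labels follow the sign of the tolerant-vs-sensitive log2FC on
    the significant drought day(s); genes significant on both days with
    opposite signs are flagged ambiguous and excluded.
    """
    tables = [de_day0_cross, de_tolerant_0v6, de_tolerant_0v10, de_cross_day6, de_cross_day10]
    universe = _check_universe(tables)

    eq_day0 = (de_day0_cross["p_value"] >= cfg.alpha) & (
        de_day0_cross["log2fc"].abs() < cfg.equivalence_log2fc
    )
    temporal = (de_tolerant_0v6["q_value"] < cfg.alpha) | (
        de_tolerant_0v10["q_value"] < cfg.alpha
    )
    sig6 = de_cross_day6["q_value"] < cfg.alpha
    sig10 = de_cross_day10["q_value"] < cfg.alpha
    cross = sig6 | sig10

    passed = eq_day0 & temporal & cross

    sign6 = np.sign(de_cross_day6["log2fc"])
    sign10 = np.sign(de_cross_day10["log2fc"])
    # direction from the significant day(s) only
    dir6 = sign6.where(sig6, 0)
    dir10 = sign10.where(sig10, 0)
    conflict = (dir6 * dir10) < 0
    combined = dir6 + dir10  # same sign doubles, one-sided passes through

    up = passed & ~conflict & (combined > 0)
    down = passed & ~conflict & (combined < 0)
    ambiguous = passed & (conflict | (combined == 0))

    audit = pd.DataFrame(
        {
            "day0_equivalent": eq_day0,
            "temporal_significant": temporal,
            "cross_significant": cross,
            "round1_pass": (up | down),
            "ambiguous": ambiguous,
            "direction": np.where(up, UP, np.where(down, DOWN, NONE)),
        },
        index=universe,
    )
    return {
        "up": sorted(universe[up]),
        "down": sorted(universe[down]),
        "ambiguous": sorted(universe[ambiguous]),
        "audit": audit,
    }


def select_stable_genes(
    m: ExpressionMatrix, design: SampleDesign, cfg: SelectionConfig | None = None
) -> list[str]:
    """Genes whose mean expression stays strictly within the stability window.

    For every cultivar and every drought day d the pseudocounted ratio
    mean(d)/mean(day 0) must lie strictly inside (stable_low, stable_high).
    Genes whose day-0 mean is all zero in any cultivar are excluded.
    """
    cfg = cfg or SelectionConfig()
    if m.level != GENE:
        raise SelectionError("stable-gene selection expects a gene-level matrix")
    day0 = min(design.days)
    drought_days = [d for d in design.days if d != day0]
    keep = pd.Series(True, index=m.data.index)
    for cultivar in design.cultivars:
        base = m.data[design.samples(cultivar=cultivar, day=day0)].mean(axis=1)
        keep &= base > 0
        for d in drought_days:
            mean_d = m.data[design.samples(cultivar=cultivar, day=d)].mean(axis=1)
            fc, _ = fold_change(mean_d.to_numpy(), base.to_numpy(), cfg.pseudocount)
            keep &= pd.Series(
                (fc > cfg.stable_low) & (fc < cfg.stable_high), index=m.data.index
            )
    return sorted(m.data.index[keep])


def round2_rank(
    round1_genes: list[str],
    de_cross_day6: pd.DataFrame,
    de_cross_day10: pd.DataFrame,
    cfg: SelectionConfig,
    k: int | None = None,
) -> list[str]:
    """Rank round-1 genes by the largest cross-cultivar |log2FC| over drought days.

    Ties are broken by the smaller q-value (minimum over the two days), then
    by gene id. Returns the top ``k`` in score order.
    """
    if not round1_genes:
        return []
    if k is None:
        k = cfg.round2_k
    if k is None:
        k = int(np.ceil(cfg.round2_fraction * len(round1_genes)))
    if k <= 0:
        raise SelectionError("round-2 cutoff k must be positive")
    genes = pd.Index(sorted(round1_genes))
    score = pd.concat(
        [de_cross_day6.loc[genes, "log2fc"].abs(), de_cross_day10.loc[genes, "log2fc"].abs()],
        axis=1,
    ).max(axis=1)
    qmin = pd.concat(
        [de_cross_day6.loc[genes, "q_value"], de_cross_day10.loc[genes, "q_value"]], axis=1
    ).min(axis=1)
    order = pd.DataFrame({"score": score, "q": qmin, "gene": genes}).sort_values(
        ["score", "q", "gene"], ascending=[False, True, True]
    )
    return order["gene"].head(k).tolist()


def round3_confirm(
    round2_genes: list[str],
    rnaseq_profiles: pd.DataFrame,
    orthogonal_profiles: pd.DataFrame,
) -> dict:
    """Keep genes whose per-day direction agrees between platforms.

    Profiles are frames indexed by gene, one column per drought day, values
    in {"up", "down", "none"}. A gene with no orthogonal profile is dropped
    with a warning (recorded in the audit).
    """
    confirmed, dropped = [], []
    for gene in round2_genes:
        if gene not in orthogonal_profiles.index:
            warnings.warn(f"no orthogonal profile for {gene}; dropped from round 3")
            dropped.append(gene)
            continue
        if conc.platform_concordant(
            rnaseq_profiles.loc[gene], orthogonal_profiles.loc[gene]
        ):
            confirmed.append(gene)
    return {"confirmed": sorted(confirmed), "missing_orthogonal": sorted(dropped)}


def direction_profile_from_de(
    de_tolerant_0v6: pd.DataFrame,
    de_tolerant_0v10: pd.DataFrame,
    min_log2fc: float = 0.25,
    days: tuple[int, int] = (6, 10),
) -> pd.DataFrame:
    """Per-day direction of the tolerant cultivar's change vs day 0.

    The temporal contrasts are day-d vs day-0, so a positive log2FC means
    higher on the drought day. Changes below ``min_log2fc`` in magnitude are
    called ``none``.
    """

    def _call(t):
        return np.where(
            t["log2fc"] >= min_log2fc, UP, np.where(t["log2fc"] <= -min_log2fc, DOWN, NONE)
        )

    return pd.DataFrame(
        {days[0]: _call(de_tolerant_0v6), days[1]: _call(de_tolerant_0v10)},
        index=de_tolerant_0v6.index,
    )


def pair_contrasts(
    m: ExpressionMatrix, design: SampleDesign, pair_id: str, cfg: SelectionConfig
) -> dict[str, pd.DataFrame]:
    """The five DE tables of one cultivar pair.

    Keys: ``day0_cross``, ``tolerant_0v6``, ``tolerant_0v10``, ``cross_day6``,
    ``cross_day10``. Cross contrasts are tolerant (group A) vs sensitive
    (group B); temporal contrasts are drought day (A) vs day 0 (B) within the
    tolerant cultivar, so positive log2FC = induced by drought.
    """
    day0 = min(design.days)
    drought = sorted(d for d in design.days if d != day0)
    if len(drought) != 2:
        raise SelectionError(f"expected two drought days, got {drought}")
    d6, d10 = drought
    tol = design.cultivar_of(pair_id, TOLERANT)
    sen = design.cultivar_of(pair_id, SENSITIVE)

    def _t(group_a, group_b):
        return test_two_groups(
            m, group_a, group_b, pseudocount=cfg.pseudocount, alpha_level=cfg.alpha
        )

    s = design.samples
    return {
        "day0_cross": _t(s(cultivar=tol, day=day0), s(cultivar=sen, day=day0)),
        "tolerant_0v6": _t(s(cultivar=tol, day=d6), s(cultivar=tol, day=day0)),
        "tolerant_0v10": _t(s(cultivar=tol, day=d10), s(cultivar=tol, day=day0)),
        "cross_day6": _t(s(cultivar=tol, day=d6), s(cultivar=sen, day=d6)),
        "cross_day10": _t(s(cultivar=tol, day=d10), s(cultivar=sen, day=d10)),
    }


def run_pipeline(
    counts: ExpressionMatrix,
    design: SampleDesign,
    tmap: TranscriptGeneMap | None = None,
    orthogonal: dict[str, pd.DataFrame] | pd.DataFrame | None = None,
    cfg: SelectionConfig | None = None,
    seed: int | None = None,
) -> SelectionReport:
    """Run the full cascade: normalize, aggregate, DE, rounds 1-3, union.

    ``orthogonal`` maps pair_id to a direction-profile frame (or one frame
    shared by all pairs); ``None`` skips round 3 (round 3 = round 2). The run
    is deterministic given the inputs; ``seed`` is recorded for provenance.
    """
    cfg = cfg or SelectionConfig()
    missing = set(design.table["sample_id"]) - set(counts.sample_ids)
    if missing:
        raise SelectionError(f"design samples absent from matrix: {sorted(missing)}")

    preprocessing = {"norm_method": cfg.norm_method}
    m = counts
    if m.level == TRANSCRIPT and tmap is None:
        raise SelectionError("transcript-level matrix requires a transcript->gene map")
    if cfg.aggregate_after_normalize:
        if not m.normalized:
            m = normalize(m, cfg.norm_method)
        if m.level == TRANSCRIPT:
            m = aggregate_isoforms(m, tmap)
            preprocessing["order"] = "normalize_then_aggregate"
    else:
        if m.level == TRANSCRIPT:
            m = aggregate_isoforms(m, tmap)
            preprocessing["order"] = "aggregate_then_normalize"
        if not m.normalized:
            m = normalize(m, cfg.norm_method)
    # restrict to designed samples, order-independently
    m = ExpressionMatrix(
        m.data[sorted(design.table["sample_id"])].sort_index(),
        level=m.level,
        normalized=m.normalized,
        norm_method=m.norm_method,
        sample_scales=m.sample_scales,
    )

    stable = select_stable_genes(m, design, cfg)

    pairs: dict[str, PairSelection] = {}
    for pair_id in design.pair_ids:
        de = pair_contrasts(m, design, pair_id, cfg)
        r1 = round1_filter(
            de["day0_cross"],
            de["tolerant_0v6"],
            de["tolerant_0v10"],
            de["cross_day6"],
            de["cross_day10"],
            cfg,
        )
        r1_genes = sorted(r1["up"] + r1["down"])
        r2 = (
            round2_rank(r1_genes, de["cross_day6"], de["cross_day10"], cfg)
            if r1_genes
            else []
        )
        if orthogonal is None:
            r3 = sorted(r2)
        else:
            ortho = orthogonal[pair_id] if isinstance(orthogonal, dict) else orthogonal
            rnaseq_prof = direction_profile_from_de(
                de["tolerant_0v6"], de["tolerant_0v10"], cfg.round3_min_log2fc
            )
            r3 = round3_confirm(r2, rnaseq_prof, ortho)["confirmed"]
        pairs[pair_id] = PairSelection(
            pair_id=pair_id,
            round1_up=r1["up"],
            round1_down=r1["down"],
            round1_ambiguous=r1["ambiguous"],
            round2=r2,
            round3=r3,
            audit=r1["audit"],
        )

    overall = sorted(set().union(*(p.round3 for p in pairs.values())) if pairs else set())
    return SelectionReport(
        pairs=pairs,
        stable_genes=stable,
        overall_selected=overall,
        config=cfg,
        seed=seed,
        preprocessing=preprocessing,
    )
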