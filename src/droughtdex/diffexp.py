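"""Per-gene two-group testing on count data.

The model is the negative binomial with gene-wise dispersion ``alpha``
(variance = mu + alpha * mu**2). Group means are compared with a Wald test on
the difference of log means, using the model-based variance of each group
mean. With only a handful of replicates per group the gene-wise
method-of-moments dispersion is noisy, so estimates are shrunk toward a
mean-dispersion trend fitted across all genes, as is standard for small-n
RNA-seq designs.

Fold changes use a pseudocount (default 0.5) so zero means stay finite:
FC = (mean_a + c) / (mean_b + c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

DE_COLUMNS = ["mean_a", "mean_b", "log2fc", "p_value", "q_value", "direction"]

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class DispersionEstimate:
    """Gene-wise NB dispersions with an audit of how they were obtained."""

    alpha: pd.Series            # final (possibly shrunk) dispersion per gene
    alpha_raw: pd.Series        # untruncated-mean method-of-moments estimate
    degenerate: pd.Series       # True where the gene was all zero
    trend: tuple[float, float] | None = None  # (a0, a1) of alpha ~ a0 + a1/mu


def fold_change(mean_a, mean_b, pseudocount: float = 0.5):
    """Pseudocounted fold change and its log2.

    Returns ``(fc, log2fc)`` with ``fc = (mean_a + c) / (mean_b + c)``.
    Accepts scalars or arrays.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("means must be non-negative")
    fc = (a + pseudocount) / (b + pseudocount)
    out = fc, np.log2(fc)
    if np.isscalar(mean_a) and np.isscalar(mean_b):
        return float(fc), float(np.log2(fc))
    return out


def estimate_dispersion(
    values: pd.DataFrame,
    groups: list[list[str]],
    scales: pd.Series | None = None,
    shrink: str | None = "trend",
    shrink_weight: float = 0.0,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion pooled across groups.

    ``values`` are (scale-corrected) counts, genes x samples; ``groups`` are
    disjoint sample-id lists, each with >= 2 replicates. For each gene the
    pooled residual variance ``s2`` and grand mean ``mu`` give the gene-wise
    estimate ``alpha_raw = max(0, (s2 - mu) / mu**2)``.

    With only 2-4 residual degrees of freedom the gene-wise estimate is very
    noisy and its truncation at zero biases it upward for
    low-dispersion genes, so with ``shrink="trend"`` (the default) a
    hyperbolic trend ``alpha(mu) = a0 + a1/mu`` is fitted across genes on the
    *untruncated* moment estimates (whose sampling noise averages out) and
    the working dispersion is the blend
    ``max(0, shrink_weight * untruncated + (1 - shrink_weight) * trend)``.
    The default ``shrink_weight = 0`` uses the trend alone, the usual choice
    for 3-replicate designs. All-zero genes get ``alpha = 0`` and are
    flagged degenerate.
    """
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 replicates for dispersion estimation")
    flat = [s for g in groups for s in g]
    if len(set(flat)) != len(flat):
        raise ValueError("groups overlap")
    y = values[flat].to_numpy(dtype=float)
    if scales is not None:
        y = y / scales.reindex(flat).to_numpy()

    n_total = y.shape[1]
    ss = np.zeros(y.shape[0])
    start = 0
    for g in groups:
        block = y[:, start : start + len(g)]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        start += len(g)
    df = n_total - len(groups)
    s2 = ss / df
    mu = y.mean(axis=1)

    degenerate = mu == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(degenerate, 0.0, (s2 - mu) / np.square(mu))
    alpha_raw = np.maximum(0.0, excess)

    index = values.index
    trend = None
    alpha = alpha_raw.copy()
    if shrink == "trend":
        ok = ~degenerate
        if ok.sum() >= 10:
            # weighted least squares of the untruncated excess on [1, 1/mu].
            # Var(excess) scales like 1/mu^2, so inverse-variance weights are
            # mu^2; without them low-mean genes dominate the 1/mu coefficient.
            X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
            w = np.square(mu[ok])
            Xw = X * w[:, None]
            try:
                coef = np.linalg.solve(X.T @ Xw, Xw.T @ excess[ok])
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(Xw, w * excess[ok], rcond=None)
            a0, a1 = max(0.0, float(coef[0])), max(0.0, float(coef[1]))
            trend = (a0, a1)
            fitted = np.where(degenerate, 0.0, a0 + a1 / np.where(degenerate, 1.0, mu))
            alpha = np.maximum(0.0, shrink_weight * excess + (1.0 - shrink_weight) * fitted)
    elif shrink is not None:
        raise ValueError(f"unknown shrink mode {shrink!r}")

    return DispersionEstimate(
        alpha=pd.Series(alpha, index=index),
        alpha_raw=pd.Series(alpha_raw, index=index),
        degenerate=pd.Series(degenerate, index=index),
        trend=trend,
    )


def test_two_groups(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    dispersion: DispersionEstimate | pd.Series | None = None,
    pseudocount: float = 0.5,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test of group A vs group B for every gene.

    Returns a table indexed by gene with columns mean_a, mean_b, log2fc,
    p_value, q_value (Benjamini-Hochberg within this contrast) and direction
    (sign of log2fc for genes with q < ``alpha_level``, else ``none``).
    Group means are taken on the matrix's (normalized) scale; the variance
    model uses the per-sample count scales the matrix records, so the NB
    variance stays correct after library normalization.
    """
    a, b = sorted(group_a), sorted(group_b)
    if not a or not b:
        raise ValueError("groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    missing = (set(a) | set(b)) - set(m.sample_ids)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")

    if dispersion is None:
        # matrix values are already on the scale-corrected (normalized) scale
        dispersion = estimate_dispersion(m.data, [a, b])
    alpha = dispersion.alpha if isinstance(dispersion, DispersionEstimate) else dispersion
    alpha = alpha.reindex(m.data.index).fillna(0.0).to_numpy()

    scales = m.scales()
    ya = m.data[a].to_numpy(dtype=float)
    yb = m.data[b].to_numpy(dtype=float)
    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)

    fc, log2fc = fold_change(mean_a, mean_b, pseudocount)
    log_diff = np.log(fc)

    # Var(group mean) on the normalized scale: counts K_j ~ NB(c_j mu, alpha),
    # value = K_j / c_j, so Var(mean) = mu * sum(1/c_j)/n^2 + alpha mu^2 / n
    def _var_log_mean(mean, samples):
        c = scales.reindex(samples).to_numpy(dtype=float)
        n = len(samples)
        mu = mean + pseudocount
        var_mean = mu * np.sum(1.0 / c) / n**2 + alpha * mu**2 / n
        return var_mean / mu**2  # delta method onto the log scale

    se2 = _var_log_mean(mean_a, a) + _var_log_mean(mean_b, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_diff / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    allzero = (mean_a == 0) & (mean_b == 0)
    p[allzero] = 1.0
    log2fc = np.where(allzero, 0.0, log2fc)

    q = adjust_fdr(p)
    direction = np.where(
        (q < alpha_level) & ~allzero,
        np.where(log2fc > 0, UP, DOWN),
        NONE,
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        },
        index=m.data.index.rename("gene_id"),
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True)
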