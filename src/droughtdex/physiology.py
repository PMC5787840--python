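"""Relative water content and its nonparametric group comparison.

RWC = (FW - DW) / (SW - DW) * 100, from the fresh (FW), saturated (SW) and
dry (DW) weights of a detached leaf; it measures hydration relative to full
turgor and is unit-free (grams and milligrams give the same value). Drought
time courses are usually reported as a percentage of the day-0 RWC.

Group differences are assessed with the Mann-Whitney U test. For small
samples without ties the two-sided p-value is exact, obtained by enumerating
all C(n+m, n) assignments of the pooled ranks; larger or tied samples use
midranks with the tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PhysiologyError(ValueError):
    """Raised for impossible weight records or degenerate samples."""


@dataclass(frozen=True)
class RWCRecord:
    """One leaf's weight triple (any consistent mass unit)."""

    label: str
    fw: float
    sw: float
    dw: float
    day: int = 0
    genotype: str = ""

    def __post_init__(self) -> None:
        if min(self.fw, self.sw, self.dw) <= 0:
            raise PhysiologyError(f"{self.label}: weights must be positive")
        if not self.dw <= self.fw <= self.sw:
            raise PhysiologyError(
                f"{self.label}: expected DW <= FW <= SW, got "
                f"DW={self.dw}, FW={self.fw}, SW={self.sw}"
            )


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney outcome; ``exact`` records which path computed the p-value."""

    u: float
    p_value: float
    exact: bool

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise PhysiologyError("p-value must be in (0, 1]")


def compute_rwc(r: RWCRecord) -> float:
    """Relative water content in percent: (FW - DW)/(SW - DW) * 100."""
    if r.sw == r.dw:
        raise PhysiologyError(f"{r.label}: SW == DW, RWC undefined")
    return (r.fw - r.dw) / (r.sw - r.dw) * 100.0


def rwc_percent_of_day0(series: dict[int, float] | pd.Series) -> pd.Series:
    """Rescale a day -> RWC series so day 0 maps to 100."""
    s = pd.Series(dict(series)).sort_index()
    if 0 not in s.index:
        raise PhysiologyError("day-0 value required for percent-of-day-0 scaling")
    base = s[0]
    if base <= 0:
        raise PhysiologyError("day-0 RWC must be positive")
    return s * 100.0 / base


def mann_whitney_u(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``u`` is the U statistic of ``x``. When n + m <= ``exact_max_n`` and the
    pooled sample has no ties, the p-value is exact: the fraction of all
    C(n+m, n) rank assignments whose U is at least as far from the null mean
    nm/2 as the observed one. Otherwise midranks and the tie-corrected
    normal approximation are used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PhysiologyError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    u = float(ranks[:n].sum() - n * (n + 1) / 2)

    if n + m <= exact_max_n and not has_ties:
        center = n * m / 2
        observed = abs(u - center)
        total = math.comb(n + m, n)
        hits = 0
        all_ranks = np.arange(1, n + m + 1)
        base = n * (n + 1) / 2
        for combo in itertools.combinations(range(n + m), n):
            u_perm = all_ranks[list(combo)].sum() - base
            if abs(u_perm - center) >= observed - 1e-12:
                hits += 1
        return TestResult(u=u, p_value=hits / total, exact=True)

    # normal approximation with tie correction on midranks
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u=u, p_value=1.0, exact=False)
    z = (u - n * m / 2.0) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(u=u, p_value=max(p, np.finfo(float).tiny), exact=False)


def read_rwc_records(path) -> list[RWCRecord]:
    """Read weight records from TSV with columns label, fw, sw, dw[, day, genotype]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = ["label", "fw", "sw", "dw"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PhysiologyError(f"weight table missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            RWCRecord(
                label=str(row["label"]),
                fw=float(row["fw"]),
                sw=float(row["sw"]),
                dw=float(row["dw"]),
                day=int(row["day"]) if "day" in frame.columns else 0,
                genotype=str(row["genotype"]) if "genotype" in frame.columns else "",
            )
        )
    return records
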