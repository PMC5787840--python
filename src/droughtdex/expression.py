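"""Count-matrix containers, TSV I/O, isoform aggregation and library normalization.

The pipeline starts from feature-level read counts (features x samples).
Transcript-level matrices are collapsed to gene level by summing all splicing
isoforms of a gene, and libraries are put on a common scale either as counts
per million (CPM) or with median-of-ratios size factors.

All TSV files are tab-separated UTF-8 with a header row; lines starting with
``#`` are ignored; no quoting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSCRIPT = "transcript"
GENE = "gene"

_DESIGN_COLUMNS = ["sample_id", "cultivar", "pair_id", "tolerance_class", "day", "replicate"]
TOLERANT = "tolerant"
SENSITIVE = "sensitive"


class ExpressionError(ValueError):
    """Raised for malformed matrices, designs or maps."""


@dataclass
class ExpressionMatrix:
    """Expression values for features (rows) across samples (columns).

    Parameters
    ----------
    data
        Non-negative matrix, index = feature ids, columns = sample ids.
    level
        ``"transcript"`` or ``"gene"``.
    normalized
        Whether values are on a normalized scale rather than raw counts.
    norm_method
        Audit tag recording how the matrix was normalized (e.g. ``"cpm"``).
    sample_scales
        Per-sample factor ``c_j`` such that ``raw_count = value * c_j``.
        Recorded by :func:`normalize` so count-based variance models remain
        valid on the normalized scale. ``None`` means all ones.
    """

    data: pd.DataFrame
    level: str = GENE
    normalized: bool = False
    norm_method: str | None = None
    sample_scales: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.level not in (TRANSCRIPT, GENE):
            raise ExpressionError(f"unknown feature level {self.level!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise ExpressionError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionError("matrix body must be numeric")
        if np.isnan(values).any():
            raise ExpressionError("matrix contains missing cells")
        if (values < 0).any():
            raise ExpressionError("matrix contains negative values")
        if self.normalized and self.norm_method is None:
            raise ExpressionError("normalized matrix must record its method")
        if self.sample_scales is not None:
            self.sample_scales = self.sample_scales.reindex(self.data.columns)
            if self.sample_scales.isna().any():
                raise ExpressionError("sample_scales missing entries for some samples")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def scales(self) -> pd.Series:
        """Per-sample count scale; ones when the matrix holds raw counts."""
        if self.sample_scales is None:
            return pd.Series(1.0, index=self.data.columns)
        return self.sample_scales


@dataclass
class SampleDesign:
    """Per-sample metadata: cultivar, pair, tolerance class, drought day, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ExpressionError(f"design missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ExpressionError("duplicate sample_id in design")
        bad_class = set(t["tolerance_class"]) - {TOLERANT, SENSITIVE}
        if bad_class:
            raise ExpressionError(f"unknown tolerance_class values: {sorted(bad_class)}")
        if (t["day"].astype(int) < 0).any():
            raise ExpressionError("negative day in design")
        self.table = t = t.assign(day=t["day"].astype(int), replicate=t["replicate"].astype(int))
        for pair_id, sub in t.groupby("pair_id"):
            classes = sub.groupby("cultivar")["tolerance_class"].first()
            counts = classes.value_counts()
            if counts.get(TOLERANT, 0) != 1 or counts.get(SENSITIVE, 0) != 1:
                raise ExpressionError(
                    f"pair {pair_id!r} must contain exactly one tolerant and one "
                    f"sensitive cultivar, got {classes.to_dict()}"
                )
        reps = t.groupby(["cultivar", "day"])["sample_id"].count()
        thin = reps[reps < 2]
        if len(thin):
            raise ExpressionError(
                f"need >=2 replicates per (cultivar, day) for variance estimation; "
                f"short cells: {thin.index.tolist()}"
            )

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.table["pair_id"].unique())

    @property
    def days(self) -> list[int]:
        return sorted(self.table["day"].unique())

    @property
    def cultivars(self) -> list[str]:
        return sorted(self.table["cultivar"].unique())

    def cultivar_of(self, pair_id: str, tolerance_class: str) -> str:
        sub = self.table[
            (self.table["pair_id"] == pair_id)
            & (self.table["tolerance_class"] == tolerance_class)
        ]
        return sub["cultivar"].iloc[0]

    def samples(
        self,
        cultivar: str | None = None,
        day: int | None = None,
        pair_id: str | None = None,
        tolerance_class: str | None = None,
    ) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if cultivar is not None:
            mask &= t["cultivar"] == cultivar
        if day is not None:
            mask &= t["day"] == day
        if pair_id is not None:
            mask &= t["pair_id"] == pair_id
        if tolerance_class is not None:
            mask &= t["tolerance_class"] == tolerance_class
        return sorted(t.loc[mask, "sample_id"])


@dataclass
class TranscriptGeneMap:
    """Many-to-one transcript -> gene mapping."""

    mapping: pd.Series  # index: transcript_id, values: gene_id

    def __post_init__(self) -> None:
        if self.mapping.index.duplicated().any():
            dup = self.mapping.index[self.mapping.index.duplicated()].unique().tolist()
            raise ExpressionError(f"transcripts mapped more than once: {dup[:5]}")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "TranscriptGeneMap":
        return cls(pd.Series(d, dtype=object))

    def gene_of(self, transcript_id: str) -> str:
        return self.mapping[transcript_id]

    def __len__(self) -> int:
        return len(self.mapping)


def _read_tsv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=object)
    except pd.errors.EmptyDataError:
        raise ExpressionError(f"empty file: {path}") from None
    if frame.empty and frame.columns.size == 0:
        raise ExpressionError(f"empty file: {path}")
    return frame


def read_counts(path, level: str | None = None) -> ExpressionMatrix:
    """Read a features x samples count TSV (first column feature ids).

    ``level`` defaults to a filename-free heuristic: ids containing ``"."``
    (isoform suffixes) are taken as transcripts, otherwise genes.
    """
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise ExpressionError(f"count matrix needs at least one sample column: {path}")
    frame = frame.set_index(frame.columns[0])
    try:
        body = frame.astype(float)
    except ValueError as exc:
        raise ExpressionError(f"non-numeric value in count matrix {path}: {exc}") from None
    if level is None:
        level = TRANSCRIPT if _looks_transcript(body.index) else GENE
    return ExpressionMatrix(body, level=level)


def _looks_transcript(index: pd.Index) -> bool:
    return bool(len(index)) and all("." in str(i) for i in index[: min(len(index), 50)])


def write_counts(m: ExpressionMatrix, path) -> None:
    out = m.data.copy()
    if not m.normalized and np.allclose(out.to_numpy(), np.round(out.to_numpy())):
        out = out.astype(np.int64)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> SampleDesign:
    frame = _read_tsv(path)
    return SampleDesign(frame)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_transcript_map(path) -> TranscriptGeneMap:
    frame = _read_tsv(path)
    if frame.shape[1] != 2:
        raise ExpressionError(f"transcript map must have 2 columns, got {frame.shape[1]}")
    return TranscriptGeneMap(pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values))


def write_transcript_map(tmap: TranscriptGeneMap, path) -> None:
    frame = tmap.mapping.rename("gene_id").rename_axis("transcript_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def aggregate_isoforms(m: ExpressionMatrix, tmap: TranscriptGeneMap) -> ExpressionMatrix:
    """Sum all splicing isoforms of each gene into a gene-level matrix.

    Per-sample totals are conserved exactly. Raises if any transcript in the
    matrix is absent from the map.
    """
    if m.level != TRANSCRIPT:
        raise ExpressionError("aggregate_isoforms expects a transcript-level matrix")
    missing = m.data.index.difference(tmap.mapping.index)
    if len(missing):
        raise ExpressionError(
            f"{len(missing)} transcripts absent from the map: {missing[:5].tolist()}"
        )
    genes = tmap.mapping.reindex(m.data.index)
    collapsed = m.data.groupby(genes.values, sort=True).sum()
    collapsed.index.name = "feature_id"
    return ExpressionMatrix(
        collapsed,
        level=GENE,
        normalized=m.normalized,
        norm_method=m.norm_method,
        sample_scales=m.sample_scales,
    )


def normalize(m: ExpressionMatrix, method: str = "cpm") -> ExpressionMatrix:
    """Scale libraries to a common depth.

    ``cpm``: value * 1e6 / library size. ``median_of_ratios``: per-sample size
    factor = median over features of count / geometric-mean reference, where
    features with any zero count are excluded from factor estimation; values
    are counts divided by the size factor.
    """
    if m.normalized:
        raise ExpressionError("matrix is already normalized")
    totals = m.data.sum(axis=0)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise ExpressionError(f"samples with zero total count: {empty}")
    if method == "cpm":
        scales = totals / 1e6
    elif method == "median_of_ratios":
        positive = m.data[(m.data > 0).all(axis=1)]
        if positive.empty:
            raise ExpressionError("no feature with all-positive counts for size factors")
        log_ref = np.log(positive).mean(axis=1)
        scales = np.exp(np.log(positive).sub(log_ref, axis=0).median(axis=0))
    else:
        raise ExpressionError(f"unknown normalization method {method!r}")
    values = m.data.div(scales, axis=1)
    return ExpressionMatrix(
        values,
        level=m.level,
        normalized=True,
        norm_method=method,
        sample_scales=pd.Series(scales, index=m.data.columns),
    )
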