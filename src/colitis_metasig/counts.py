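"""Gene-level count matrices: loading, presence flagging, global-scaling normalization.

Raw gene expression is taken as read counts summarized at the gene level.
Normalization is a two-stage global scaling: each sample is first scaled to
the median library size (total mapped reads), then to a common 75% quartile
of gene-level counts, so that after normalization every sample's upper
quartile (over its present-flagged genes) is identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "CountFormatError",
    "NormalizationError",
    "read_counts",
    "write_counts",
    "flag_presence",
    "normalize",
]

DEFAULT_MIN_READS = 10
DEFAULT_QUANTILE = 0.75

NormMode = Literal["sequential", "library_only", "uq_only"]
QuantileGenes = Literal["present", "nonzero", "all"]


class CountFormatError(ValueError):
    """Raised when a count matrix violates the integer/non-negative/unique-gene contract."""


class NormalizationError(ValueError):
    """Raised when a sample cannot be normalized (e.g. no present genes)."""


@dataclasses.dataclass
class CountMatrix:
    """Gene x sample integer read counts with optional per-sample group labels.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``groups`` maps sample id -> condition label (may be None for ungrouped
    matrices). Library size of a sample is its column sum.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise CountFormatError(f"duplicate gene ids: {dupes}")
        if c.columns.duplicated().any():
            raise CountFormatError("duplicate sample ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountFormatError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise CountFormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.array_equal(arr, np.round(arr)):
                g, s = np.argwhere(arr != np.round(arr))[0]
                raise CountFormatError(
                    f"non-integer count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
                )
            self.counts = c.astype(np.int64)
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = [s for s in c.columns if s not in self.groups.index]
            if missing:
                raise CountFormatError(f"samples without group label: {missing}")
            self.groups = self.groups.loc[c.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Total mapped reads per sample (column sums)."""
        return self.counts.sum(axis=0)


def read_counts(path: str | Path, groups: pd.Series | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from TSV/CSV (gene ids in the first column)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        return CountMatrix(df, groups=groups)
    except CountFormatError as e:
        raise CountFormatError(f"{path}: {e}") from e


def write_counts(m: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    m.counts.to_csv(path, sep=sep, index_label="gene")


def flag_presence(m: CountMatrix, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Boolean gene x sample presence mask: count >= ``min_reads`` (inclusive).

    A gene with fewer than ``min_reads`` mapped reads in a sample is flagged
    absent there; the default threshold of 10 marks the count below which
    quantitation is considered unreliable.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return m.counts >= min_reads


@dataclasses.dataclass
class NormalizationFactors:
    """Per-sample scale factors from the two normalization stages.

    ``stage1`` matches library sizes to the median library size;
    ``stage2`` matches each sample's 75% quartile (over its present genes,
    computed on stage-1 scaled values) to the cross-sample median quartile.
    ``combined = stage1 * stage2`` is what multiplies each raw column.
    """

    stage1: pd.Series
    stage2: pd.Series
    target_library_size: float
    target_uq: float

    @property
    def combined(self) -> pd.Series:
        return self.stage1 * self.stage2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage1": self.stage1, "stage2": self.stage2, "combined": self.combined}
        )


def _sample_quantile(
    raw: pd.Series,
    scaled: pd.Series,
    min_reads: int,
    q: float,
    which: QuantileGenes,
) -> float:
    if which == "present":
        sel = raw >= min_reads
    elif which == "nonzero":
        sel = raw > 0
    else:
        sel = pd.Series(True, index=raw.index)
    if not sel.any():
        raise NormalizationError(
            f"sample {raw.name!r} has no genes eligible for quantile normalization"
        )
    # linear-interpolation quantile; dialect matters, so it is pinned here
    return float(np.quantile(scaled[sel].to_numpy(), q))


def normalize(
    m: CountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    mode: NormMode = "sequential",
    quantile: float = DEFAULT_QUANTILE,
    quantile_genes: QuantileGenes = "present",
) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Two-stage global scaling normalization.

    Stage 1 multiplies each column by ``median(library sizes) / library size``;
    stage 2 then multiplies by ``target_uq / uq_s`` where ``uq_s`` is the
    sample's 75th percentile of stage-1 scaled counts over its present genes
    and ``target_uq`` is the median of those percentiles across samples.
    Applying the quartile stage last makes the quartile constraint hold
    exactly in the output. ``mode`` can restrict to either single stage.
    """
    if m.counts.shape[1] < 2:
        raise NormalizationError("need at least 2 samples to normalize")
    lib = m.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise NormalizationError(f"samples with empty libraries: {bad}")

    target_lib = float(np.median(lib.to_numpy()))
    if mode in ("sequential", "library_only"):
        stage1 = target_lib / lib
    else:
        stage1 = pd.Series(1.0, index=m.samples)
    x1 = m.counts.astype(float) * stage1

    if mode in ("sequential", "uq_only"):
        uqs = pd.Series(
            {
                s: _sample_quantile(m.counts[s], x1[s], min_reads, quantile, quantile_genes)
                for s in m.samples
            }
        )
        if (uqs <= 0).any():
            bad = uqs.index[uqs <= 0].tolist()
            raise NormalizationError(f"samples with non-positive upper quartile: {bad}")
        target_uq = float(np.median(uqs.to_numpy()))
        stage2 = target_uq / uqs
    else:
        target_uq = float("nan")
        stage2 = pd.Series(1.0, index=m.samples)

    normalized = x1 * stage2
    factors = NormalizationFactors(
        stage1=stage1, stage2=stage2, target_library_size=target_lib, target_uq=target_uq
    )
    return normalized, factors
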