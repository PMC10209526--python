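"""Genome rebinning and pairwise correlation of peak files.

Peak files from different callers are hard to compare directly because
their score scales differ. Rebinning standardizes them: the genome is
tiled into fixed-width bins and each sample becomes a per-bin intensity
vector (binary occupancy, or the max strength-column value among peaks
touching the bin). Correlation between those vectors (Spearman by
default, robust to scale) then quantifies genome-wide similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromSizes, PeakSet, require_shared_build
from .io import infer_strength_column


@dataclass
class BinMatrix:
    """Bins x samples intensity matrix over a fixed genome tiling."""

    bin_index: pd.MultiIndex  # (chrom, bin start bp)
    values: pd.DataFrame      # rows = bins, columns = sample labels
    bin_width: int

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (chrom, start, sample, value) rows for nonzero bins."""
        long = self.values.stack()
        long = long[long != 0]
        out = long.reset_index()
        out.columns = ["chrom", "start", "sample", "value"]
        return out


def rebin_peaks(
    peaksets: Sequence[PeakSet],
    chrom_sizes: ChromSizes,
    bin_width: int = 1000,
    value_mode: str = "score",
) -> BinMatrix:
    """Tile every chromosome into ``bin_width`` bins and score each sample.

    A bin's value for a sample is 0 when no peak touches it; otherwise 1
    in ``binary`` mode, or in ``score`` mode the maximum strength-column
    value among the peaks intersecting the bin (1 when the sample has no
    strength column). Peaks crossing bin boundaries contribute to every
    bin they touch. Raises if a peak's chromosome is missing from
    ``chrom_sizes``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if value_mode not in ("binary", "score"):
        raise ValueError(f"unknown value_mode {value_mode!r}")
    require_shared_build(peaksets)

    chroms = sorted(chrom_sizes)
    offsets: dict[str, int] = {}
    total = 0
    for chrom in chroms:
        offsets[chrom] = total
        total += math.ceil(chrom_sizes[chrom] / bin_width)

    index = pd.MultiIndex.from_tuples(
        [(chrom, b * bin_width)
         for chrom in chroms
         for b in range(math.ceil(chrom_sizes[chrom] / bin_width))],
        names=["chrom", "start"])

    matrix = np.zeros((total, len(peaksets)))
    for col, ps in enumerate(peaksets):
        strength_col = ps.strength_column or infer_strength_column(ps)
        for iv in ps:
            if iv.chrom not in chrom_sizes:
                raise ValueError(
                    f"chromosome {iv.chrom!r} in {ps.label!r} absent from chrom sizes")
            first = iv.start // bin_width
            last = (min(iv.end, chrom_sizes[iv.chrom]) - 1) // bin_width
            if value_mode == "binary":
                value = 1.0
            else:
                raw = getattr(iv, strength_col) if strength_col else None
                value = 1.0 if raw is None else float(raw)
            rows = slice(offsets[iv.chrom] + first, offsets[iv.chrom] + last + 1)
            np.maximum(matrix[rows, col], value, out=matrix[rows, col])

    values = pd.DataFrame(matrix, index=index,
                          columns=[ps.label for ps in peaksets])
    return BinMatrix(index, values, bin_width)


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: pd.DataFrame  # square symmetric, diagonal 1, NaN for constants
    method: str

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()


def compute_corr(
    bins: BinMatrix,
    method: str = "spearman",
    drop_empty_bins: bool = True,
) -> CorrelationMatrix:
    """Pairwise correlation between the samples of a bin matrix.

    Bins where every sample is 0 are dropped first (on by default —
    genome-scale tilings are overwhelmingly empty and would otherwise
    dominate every coefficient). A constant column yields NaN against all
    partners; the diagonal is exactly 1.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    data = bins.values
    if data.shape[1] < 2:
        raise ValueError("need at least two samples to correlate")
    if drop_empty_bins:
        data = data.loc[(data != 0).any(axis=1)]
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 bins left after dropping empty bins")

    labels = list(data.columns)
    n = len(labels)
    mat = np.eye(n)
    arr = data.to_numpy()
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = arr[:, i], arr[:, j]
            if np.array_equal(xi, xj):
                # identical profiles correlate perfectly even when constant
                # (a duplicated binary sample survives empty-bin dropping
                # as an all-ones column)
                coef = 1.0
            elif np.all(xi == xi[0]) or np.all(xj == xj[0]):
                coef = np.nan
            else:
                coef = float(corr_fn(xi, xj)[0])
            mat[i, j] = mat[j, i] = coef
    return CorrelationMatrix(
        labels, pd.DataFrame(mat, index=labels, columns=labels), method)
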