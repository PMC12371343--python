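"""Turn cell-level expression into per-branch binned, scaled time series.

Cells are partitioned by branch label, collected into half-open pseudotime
bins of fixed width, averaged per gene, and the resulting series are jointly
rescaled to the model's working range [0.1, 0.9] — jointly, so that
between-branch expression differences survive the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset

__all__ = ["BinnedTimeSeries", "bin_pseudotime", "scale_joint", "normalize_times"]


@dataclass(frozen=True)
class BinnedTimeSeries:
    """Per-branch time series: genes x bins matrix at bin-centre times."""

    branch_id: str
    times: np.ndarray  # strictly increasing bin centres
    values: np.ndarray  # genes x bins
    n_cells_per_bin: np.ndarray
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.times):
            raise ValueError("values column count must equal number of bins")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("bin times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned values must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for gi, g in enumerate(self.gene_names or range(self.values.shape[0])):
            cols[str(g)] = self.values[gi]
        return pd.DataFrame(cols)

    @staticmethod
    def from_frame(df: pd.DataFrame, branch_id: str) -> "BinnedTimeSeries":
        genes = tuple(c for c in df.columns if c != "time")
        return BinnedTimeSeries(
            branch_id=branch_id,
            times=df["time"].to_numpy(dtype=float),
            values=df[list(genes)].to_numpy(dtype=float).T,
            n_cells_per_bin=np.ones(len(df), dtype=int),
            gene_names=genes,
        )


def bin_pseudotime(
    data: ExpressionDataset, width: float = 0.1, aggregator: str = "mean"
) -> list[BinnedTimeSeries]:
    """Bin cells into half-open pseudotime intervals, one series per branch.

    Bin k covers ``[k*width, (k+1)*width)`` with centre ``(k + 0.5)*width``;
    a cell exactly on a boundary goes to the bin it opens. Empty bins are
    dropped. Aggregation within a bin is the per-gene mean (median behind the
    flag for robustness to outlier cells).
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if data.n_cells == 0:
        raise ValueError("dataset has no cells")
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    agg = np.mean if aggregator == "mean" else np.median
    out: list[BinnedTimeSeries] = []
    branches = pd.unique(pd.Series(data.branch))
    for b in branches:
        sel = np.asarray(data.branch) == b
        t = data.times[sel]
        vals = data.values[:, sel]
        k = np.floor(t / width + 1e-12).astype(int)
        centres = []
        cols = []
        counts = []
        for kk in np.unique(k):
            members = k == kk
            centres.append((kk + 0.5) * width)
            cols.append(agg(vals[:, members], axis=1))
            counts.append(int(members.sum()))
        out.append(
            BinnedTimeSeries(
                branch_id=str(b),
                times=np.array(centres),
                values=np.column_stack(cols),
                n_cells_per_bin=np.array(counts),
                gene_names=tuple(data.gene_names),
            )
        )
    if not out:
        raise ValueError("all bins empty")
    return out


def scale_joint(
    series_list: Sequence[BinnedTimeSeries], lo: float = 0.1, hi: float = 0.9
) -> list[BinnedTimeSeries]:
    """Affinely map expression values to [lo, hi] using the global min/max.

    The extremes are taken over *all* series jointly, so the branch holding
    the global maximum reaches ``hi`` while other branches stay strictly
    below it. Times are untouched. Constant data cannot be scaled.
    """
    if not series_list:
        raise ValueError("need at least one series")
    gmin = min(float(s.values.min()) for s in series_list)
    gmax = max(float(s.values.max()) for s in series_list)
    if gmax <= gmin:
        raise ValueError("cannot scale constant data (global max == global min)")
    scale = (hi - lo) / (gmax - gmin)
    return [
        replace(s, values=lo + (s.values - gmin) * scale) for s in series_list
    ]


def normalize_times(
    series_list: Sequence[BinnedTimeSeries], t_max: float
) -> list[BinnedTimeSeries]:
    """Divide all bin times by ``t_max`` so model time runs over [0, 1].

    Keeps the fitted timescale tau comparable across datasets with different
    simulation horizons.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return [replace(s, times=s.times / t_max) for s in series_list]
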