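"""Coverage-uniformity diagnostics for low-coverage single-cell data.

Read depth is summarized in fixed windows (100 kb by default); each window's
depth is normalized by the genome-wide mean so an unbiased library sits at 1.
A Poisson reference (lambda = 30, normalized draws) provides the no-bias
benchmark, windows are stratified by GC content (>50 % HighGC, <35 % LowGC),
repeat or other regions get their own normalized-depth distributions, and
pairwise Pearson correlations of per-window profiles quantify reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import overlap_lengths

TRACK_COLUMNS = ["chrom", "start", "end", "depth"]
DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class DepthTrack:
    """Per-window mean depth: chrom, start, end (0-based half-open), depth[, gc]."""

    windows: pd.DataFrame
    nominal_width: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.windows.columns)
        if missing:
            raise ValueError(f"depth track missing columns {sorted(missing)}")
        if (self.windows["depth"] < 0).any():
            raise ValueError("negative depth")
        for _, grp in self.windows.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
                raise ValueError("windows must be sorted and non-overlapping")
        object.__setattr__(self, "windows", self.windows.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def widths(self) -> np.ndarray:
        return (self.windows["end"] - self.windows["start"]).to_numpy()


@dataclass(frozen=True)
class PoissonReference:
    """Normalized draws from Poisson(lambda), the no-bias depth benchmark."""

    lam: float
    n_draws: int
    normalized: np.ndarray


@dataclass(frozen=True)
class GCStrataConfig:
    high_cutoff: float = 0.50
    low_cutoff: float = 0.35

    def __post_init__(self) -> None:
        if not self.low_cutoff < self.high_cutoff:
            raise ValueError("low cutoff must be below high cutoff")


def _retained(track: DepthTrack, drop_short: bool, autosomes_only: bool) -> pd.DataFrame:
    frame = track.windows
    if drop_short:
        widths = frame["end"] - frame["start"]
        frame = frame[widths >= track.nominal_width / 2]
    if autosomes_only:
        is_auto = frame["chrom"].str.removeprefix("chr").str.isdigit()
        frame = frame[is_auto]
    if frame.empty:
        raise ValueError("no windows retained")
    return frame


def genome_mean_depth(track: DepthTrack, drop_short: bool = True,
                      autosomes_only: bool = False) -> float:
    """Width-weighted mean depth over retained windows."""
    frame = _retained(track, drop_short, autosomes_only)
    widths = (frame["end"] - frame["start"]).to_numpy(dtype=float)
    return float(np.average(frame["depth"].to_numpy(dtype=float), weights=widths))


def normalized_depth(
    track: DepthTrack,
    drop_short: bool = True,
    autosomes_only: bool = False,
) -> pd.DataFrame:
    """Windows with depth divided by the genome-wide (width-weighted) mean.

    Windows shorter than half the nominal width are dropped (edge windows at
    chromosome ends). The width-weighted mean of the output is exactly 1.
    """
    frame = _retained(track, drop_short, autosomes_only).copy()
    mean = genome_mean_depth(track, drop_short, autosomes_only)
    if mean <= 0:
        raise ValueError("genome mean depth is zero")
    frame["normalized_depth"] = frame["depth"] / mean
    return frame.reset_index(drop=True)


def poisson_reference(lam: float = 30.0, n_draws: int = 1000, seed: int = 0) -> PoissonReference:
    """i.i.d. Poisson(lambda) draws divided by lambda."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(lam, size=n_draws)
    return PoissonReference(lam=float(lam), n_draws=int(n_draws),
                            normalized=draws / lam)


def cumulative_depth_distribution(depths, thresholds) -> np.ndarray:
    """Fraction of positions/windows with depth >= t for each threshold t."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    thresholds = np.asarray(thresholds)
    if np.any(thresholds < 0):
        raise ValueError("negative threshold")
    return np.array([(depths >= t).mean() for t in thresholds])


def gc_stratify(track: DepthTrack, config: GCStrataConfig = GCStrataConfig()) -> np.ndarray:
    """Label windows HighGC (> high cutoff), LowGC (< low cutoff), else MiddleGC.

    Inequalities are strict; windows exactly at a cutoff are MiddleGC.
    """
    if "gc" not in track.windows.columns:
        raise ValueError("track has no gc column")
    gc = track.windows["gc"].to_numpy(dtype=float)
    if np.isnan(gc).any():
        raise ValueError("missing gc values")
    labels = np.full(len(gc), "MiddleGC", dtype="U8")
    labels[gc > config.high_cutoff] = "HighGC"
    labels[gc < config.low_cutoff] = "LowGC"
    return labels


def region_normalized_depth(track: DepthTrack, regions: pd.DataFrame) -> np.ndarray:
    """Overlap-weighted mean depth of each region divided by the genome mean.

    ``regions`` is a BED-like frame (chrom, start, end). One value per region.
    """
    if regions.empty:
        raise ValueError("empty region set")
    if ((regions["end"] - regions["start"]) <= 0).any():
        raise ValueError("zero-length region")
    mean = genome_mean_depth(track, drop_short=False)
    if mean <= 0:
        raise ValueError("genome mean depth is zero")
    frame = track.windows
    out = np.empty(len(regions))
    for k, row in enumerate(regions.itertuples()):
        sub = frame[frame["chrom"] == row.chrom]
        ov = overlap_lengths(
            sub["start"].to_numpy(), sub["end"].to_numpy(), row.start, row.end
        )
        total = ov.sum()
        if total == 0:
            out[k] = np.nan
            continue
        out[k] = np.average(sub["depth"].to_numpy(dtype=float), weights=ov) / mean
    return out


def mapping_summary(records) -> tuple[float, float]:
    """(mapping ratio, duplication ratio) from (mapped, duplicate) read flags.

    Duplication ratio is duplicates over *mapped* reads.
    """
    frame = pd.DataFrame(records, columns=["mapped", "duplicate"])
    if frame.empty:
        raise ValueError("no read records")
    total = len(frame)
    mapped = int(frame["mapped"].sum())
    if mapped == 0:
        raise ValueError("duplication ratio undefined with zero mapped reads")
    dups = int((frame["mapped"] & frame["duplicate"]).sum())
    return mapped / total, dups / mapped


def pairwise_reproducibility(vectors) -> np.ndarray:
    """Symmetric Pearson correlation matrix of >= 2 equal-length profiles."""
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least two vectors")
    if mat.shape[1] < 3:
        raise ValueError("vectors must have length >= 3")
    if np.any(np.ptp(mat, axis=1) == 0):
        raise ValueError("zero-variance vector")
    corr = np.corrcoef(mat)
    np.fill_diagonal(corr, 1.0)
    return corr
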