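"""Binned copy-number pipeline: binning, spike-in, normalization, circular
binary segmentation, mode anchoring, CNV calling and overlap scoring.

The workflow mirrors low-coverage single-cell CNV practice: read positions are
counted in ~10,000 genome-wide bins (equal-width, or equal mappable-position
quota when weights are supplied), counts are GC-corrected and scaled to mean
one, a circular-binary-segmentation scan cuts the per-bin ratio into segments,
the modal autosomal segment ratio is anchored to copy number two, and calls of
at least 1 Mb are scored against a control call set by overlap length:

    sensitivity = L_T / L_C        "specificity" = L_T / L

where L and L_C are the total CNV length (bp) called in the single cell and in
the control, and L_T the length of their intersection. The second quantity is
precision-like; the historical name is retained.

Spike-in follows Ks = Kr x R with R = N/2: the raw count of every bin overlapped
by a simulated copy-number-N region is scaled by the (length-weighted) ratio R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, intersect_length, merge_intervals, overlap_lengths

BIN_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class BinScheme:
    """Ordered, non-overlapping genomic bins (0-based half-open)."""

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(BIN_COLUMNS) - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns {sorted(missing)}")
        if len(self.bins) == 0:
            raise ValueError("empty bin scheme")
        for _, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
                raise ValueError("bins must be sorted and non-overlapping")
        object.__setattr__(self, "bins", self.bins.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()


@dataclass(frozen=True)
class BinnedCounts:
    """Per-bin read counts Kr for one sample."""

    counts: np.ndarray
    sample: str = "sample"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("negative bin count")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SpikeInRegion:
    """Simulated CNV region with integer copy number N; ratio R = N/2."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")

    @property
    def ratio(self) -> float:
        return self.copy_number / 2.0


@dataclass
class SegmentProfile:
    """Piecewise-constant summary of the per-bin ratio vector.

    ``segments`` has columns chrom, start_bin, end_bin (half-open bin index
    range), mean_ratio and, after mode normalization, copy_number.
    """

    segments: pd.DataFrame
    n_bins: int
    mode_ratio: float | None = None

    def per_bin_ratio(self) -> np.ndarray:
        out = np.empty(self.n_bins)
        for row in self.segments.itertuples():
            out[row.start_bin:row.end_bin] = row.mean_ratio
        return out

    def per_bin_copy_number(self) -> np.ndarray:
        if "copy_number" not in self.segments.columns:
            raise ValueError("profile is not mode-normalized")
        out = np.empty(self.n_bins)
        for row in self.segments.itertuples():
            out[row.start_bin:row.end_bin] = row.copy_number
        return out


@dataclass(frozen=True)
class CNVEvaluation:
    """Overlap-length scoring of single-cell calls against control calls."""

    L: int
    L_C: int
    L_T: int

    def __post_init__(self) -> None:
        if self.L_T > min(self.L, self.L_C):
            raise ValueError("intersection exceeds an operand")

    @property
    def sensitivity(self) -> float | None:
        return self.L_T / self.L_C if self.L_C > 0 else None

    @property
    def specificity(self) -> float | None:
        """L_T / L; precision-like, name retained from the field."""
        return self.L_T / self.L if self.L > 0 else None


def make_bins(
    layout: GenomeLayout,
    n_bins: int = 10_000,
    weights: dict[str, np.ndarray] | None = None,
) -> BinScheme:
    """Partition the genome into ``n_bins`` bins that never cross chromosomes.

    Without weights, bins within a chromosome are equal-width. With per-
    chromosome weight tracks (uniform sub-intervals of arbitrary resolution,
    e.g. mappable-position counts), bin boundaries are weight quantiles so
    every bin holds an equal share of total weight, deserts being absorbed
    into flanking bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if layout.total_length < n_bins:
        raise ValueError("more bins than genome positions")
    chroms = layout.chromosomes
    if weights is None:
        mass = np.array([layout.lengths[c] for c in chroms], dtype=float)
    else:
        mass = np.array([np.sum(weights[c]) for c in chroms], dtype=float)
        if np.any(mass < 0) or mass.sum() <= 0:
            raise ValueError("weights must be non-negative with positive total")
    # largest-remainder allocation of bins across chromosomes
    quota = n_bins * mass / mass.sum()
    alloc = np.floor(quota).astype(int)
    remainder = n_bins - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:remainder]] += 1
    alloc = np.maximum(alloc, 1) if n_bins >= len(chroms) else alloc
    while alloc.sum() > n_bins:  # rebalance if the minimum-1 rule overshot
        alloc[np.argmax(alloc)] -= 1
    rows = []
    for c, k in zip(chroms, alloc):
        if k == 0:
            continue
        length = layout.lengths[c]
        if weights is None:
            edges = np.linspace(0, length, k + 1)
        else:
            w = np.asarray(weights[c], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(w)])
            grid = np.linspace(0, length, len(w) + 1)
            targets = np.linspace(0, cum[-1], k + 1)
            edges = np.interp(targets, cum, grid)
        edges = np.round(edges).astype(int)
        edges[0], edges[-1] = 0, length
        edges = np.maximum.accumulate(edges)
        for s, e in zip(edges[:-1], edges[1:]):
            if e > s:
                rows.append((c, int(s), int(e)))
    return BinScheme(pd.DataFrame(rows, columns=BIN_COLUMNS))


def _region_ratio_per_bin(bins: BinScheme, regions: list[SpikeInRegion]) -> np.ndarray:
    """Length-weighted copy-number ratio R per bin (1.0 outside regions)."""
    ratio = np.ones(len(bins))
    chrom = bins.chromosomes
    starts = bins.bins["start"].to_numpy()
    ends = bins.bins["end"].to_numpy()
    widths = bins.widths.astype(float)
    for region in regions:
        mask = chrom == region.chrom
        if not mask.any():
            continue
        ov = overlap_lengths(starts[mask], ends[mask], region.start, region.end)
        frac = ov / widths[mask]
        ratio[mask] += frac * (region.ratio - 1.0)
    return ratio


def spike_in(
    counts: BinnedCounts,
    regions: list[SpikeInRegion],
    bins: BinScheme,
    poisson_resample: bool = False,
    seed: int | None = None,
) -> BinnedCounts:
    """Embed simulated CNVs: Ks = Kr x R, length-weighted for partial overlap.

    ``poisson_resample`` draws Poisson(Kr x R) instead of rounding, for
    stochastic realism.
    """
    if len(counts) != len(bins):
        raise ValueError("counts and bins disagree in length")
    ratio = _region_ratio_per_bin(bins, regions)
    scaled = counts.counts * ratio
    if poisson_resample:
        rng = np.random.default_rng(seed)
        new = rng.poisson(scaled)
    else:
        new = np.rint(scaled).astype(int)
    return BinnedCounts(new, counts.sample)


def normalize_ratio(
    counts: BinnedCounts,
    bins: BinScheme | None = None,
    gc_correct: bool = True,
    lowess_frac: float = 0.3,
) -> np.ndarray:
    """Per-bin copy ratio: count / mean count, optionally GC-detrended.

    When bin GC fractions are available a lowess trend of count vs GC is
    divided out before ratio formation, removing the smooth amplification
    preference for GC-balanced fragments.
    """
    values = np.asarray(counts.counts, dtype=float)
    if values.sum() <= 0:
        raise ValueError("zero total count")
    if gc_correct and bins is not None and "gc" in bins.bins.columns:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        gc = bins.bins["gc"].to_numpy(dtype=float)
        trend = lowess(values, gc, frac=lowess_frac, return_sorted=False)
        trend = np.maximum(trend, 1e-9)
        values = values / trend
    return values / values.mean()


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

_LARGE_T = 1e12


def _arc_scan(x: np.ndarray, min_width: int, ks: np.ndarray):
    """Max pooled-t arc statistic over arcs x[i:i+k] for k in ``ks``.

    Returns (T, i, j): the arc maximizing |mean_in - mean_out| / pooled s.e.
    Zero pooled variance with a nonzero mean difference scores ``_LARGE_T``
    (noise-free changepoints dominate any noisy arc).
    """
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    q = np.concatenate([[0.0], np.cumsum(x * x)])
    total, total_sq = s[-1], q[-1]
    best = (-np.inf, 0, n)
    for k in ks:
        k = int(k)
        if k < min_width or n - k < min_width:
            continue
        sums = s[k:] - s[:-k]
        sqs = q[k:] - q[:-k]
        mean_in = sums / k
        mean_out = (total - sums) / (n - k)
        ss_in = sqs - sums**2 / k
        ss_out = (total_sq - sqs) - (total - sums) ** 2 / (n - k)
        denom_df = max(n - 2, 1)
        pooled = (ss_in + ss_out) / denom_df
        pooled = np.maximum(pooled, 0.0)
        diff = np.abs(mean_in - mean_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(pooled * (1.0 / k + 1.0 / (n - k)))
        t = np.where(pooled < 1e-18, np.where(diff > 1e-12, _LARGE_T, 0.0), t)
        idx = int(np.argmax(t))
        if t[idx] > best[0]:
            best = (float(t[idx]), idx, idx + k)
    return best


def _k_grid(n: int, min_width: int, num: int = 40) -> np.ndarray:
    """Geometric grid of arc lengths used for the permutation family."""
    hi = n - min_width
    if hi < min_width:
        return np.array([], dtype=int)
    grid = np.unique(
        np.round(np.geomspace(min_width, hi, num=num)).astype(int)
    )
    return grid[(grid >= min_width) & (grid <= hi)]


def _k_all(n: int, min_width: int) -> np.ndarray:
    return np.arange(min_width, n - min_width + 1)


def _arc_scan_batch(X: np.ndarray, min_width: int, ks: np.ndarray) -> np.ndarray:
    """Row-wise max arc statistic for a batch of (permuted) vectors."""
    B, n = X.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((B, 1)), np.cumsum(X * X, axis=1)], axis=1)
    total = S[:, -1:]
    total_sq = Q[:, -1:]
    denom_df = max(n - 2, 1)
    best = np.full(B, -np.inf)
    for k in ks:
        k = int(k)
        if k < min_width or n - k < min_width:
            continue
        sums = S[:, k:] - S[:, :-k]
        sqs = Q[:, k:] - Q[:, :-k]
        mean_in = sums / k
        mean_out = (total - sums) / (n - k)
        ss_in = sqs - sums**2 / k
        ss_out = (total_sq - sqs) - (total - sums) ** 2 / (n - k)
        pooled = np.maximum((ss_in + ss_out) / denom_df, 0.0)
        diff = np.abs(mean_in - mean_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(pooled * (1.0 / k + 1.0 / (n - k)))
        t = np.where(pooled < 1e-18, np.where(diff > 1e-12, _LARGE_T, 0.0), t)
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _significant(
    x: np.ndarray,
    min_width: int,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the max arc statistic over a restricted arc family.

    Both the observed and permuted maxima are taken over the same geometric
    arc-length family, so exchangeability makes the p-value exact. The test
    runs in two batches and accepts early once the exceedance count already
    guarantees p > alpha.
    """
    ks = _k_grid(len(x), min_width)
    if ks.size == 0:
        return False
    t_obs, _, _ = _arc_scan(x, min_width, ks)
    if t_obs >= _LARGE_T:
        return True
    budget = alpha * (n_permutations + 1) - 1  # max exceedances that still reject
    exceed = 0
    first = min(100, n_permutations)
    for chunk in (first, n_permutations - first):
        if chunk <= 0:
            continue
        X = rng.permuted(np.tile(x, (chunk, 1)), axis=1)
        exceed += int((_arc_scan_batch(X, min_width, ks) >= t_obs).sum())
        if exceed > budget:
            return False
    return True


def _best_arc_windowed(x: np.ndarray, min_width: int, window: int):
    """Full arc scan, windowed for long segments to bound cost.

    Returns (i, j, window_slice) where the slice is the sub-range on which
    significance is assessed.
    """
    n = len(x)
    if n <= window:
        _, i, j = _arc_scan(x, min_width, _k_all(n, min_width))
        return i, j, (0, n)
    best = (-np.inf, 0, n, (0, n))
    step = window // 2
    starts = list(range(0, n - window + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)
    for w0 in starts:
        sub = x[w0:w0 + window]
        t, i, j = _arc_scan(sub, min_width, _k_all(window, min_width))
        if t > best[0]:
            best = (t, w0 + i, w0 + j, (w0, w0 + window))
    return best[1], best[2], best[3]


def segment(
    ratios: np.ndarray,
    chromosomes: np.ndarray | None = None,
    alpha: float = 0.01,
    min_width: int = 2,
    n_permutations: int = 1000,
    seed: int = 0,
    window: int = 1000,
) -> SegmentProfile:
    """Circular binary segmentation of a per-bin ratio vector.

    Recursively locates the arc maximizing the pooled-t statistic, accepts the
    induced changepoints when a permutation test rejects at level ``alpha``,
    and recurses into the sub-segments. Segmentation never crosses chromosome
    boundaries. Deterministic given ``seed``.
    """
    x = np.asarray(ratios, dtype=float)
    if len(x) < min_width:
        raise ValueError("fewer bins than min_width")
    if chromosomes is None:
        chromosomes = np.array(["genome"] * len(x))
    chromosomes = np.asarray(chromosomes)
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, int, float]] = []

    def emit(chrom, lo, hi):
        rows.append((chrom, lo, hi, float(x[lo:hi].mean())))

    def recurse(chrom, lo, hi):
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_width or np.ptp(seg) < 1e-12:
            emit(chrom, lo, hi)
            return
        i, j, (w0, w1) = _best_arc_windowed(seg, min_width, window)
        if (i <= 0 and j >= n) or not _significant(
            seg[w0:w1], min_width, alpha, n_permutations, rng
        ):
            emit(chrom, lo, hi)
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(chrom, lo + a, lo + b)

    # preserve chromosome order of appearance
    seen: list[str] = []
    for c in chromosomes:
        if c not in seen:
            seen.append(c)
    for c in seen:
        idx = np.flatnonzero(chromosomes == c)
        recurse(c, int(idx[0]), int(idx[-1]) + 1)

    segments = pd.DataFrame(
        rows, columns=["chrom", "start_bin", "end_bin", "mean_ratio"]
    ).sort_values("start_bin", ignore_index=True)
    return SegmentProfile(segments, n_bins=len(x))


def mode_normalize(
    profile: SegmentProfile,
    autosome_mask: np.ndarray | None = None,
    grid_points: int = 1024,
) -> SegmentProfile:
    """Anchor the modal autosomal segment ratio to copy number two.

    The density of the per-bin segment ratio over autosomes is estimated by a
    Gaussian KDE; its mode m maps segment ratios to copy numbers 2 x ratio / m,
    invariant under any global rescaling of the input ratios.
    """
    ratios = profile.per_bin_ratio()
    if autosome_mask is None:
        autosome_mask = np.ones(len(ratios), dtype=bool)
    values = ratios[np.asarray(autosome_mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("no autosomal bins")
    if np.ptp(values) < 1e-12:
        mode = float(values[0])
    else:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(values)
        grid = np.linspace(values.min(), values.max(), grid_points)
        mode = float(grid[np.argmax(kde(grid))])
    if mode <= 0:
        raise ValueError("degenerate ratio density (non-positive mode)")
    segments = profile.segments.copy()
    segments["copy_number"] = 2.0 * segments["mean_ratio"] / mode
    return SegmentProfile(segments, profile.n_bins, mode_ratio=mode)


def call_cnvs(
    profile: SegmentProfile,
    bins: BinScheme,
    min_length: int = 1_000_000,
    gain_threshold: float = 2.5,
    loss_threshold: float = 1.5,
) -> pd.DataFrame:
    """Emit gain/loss calls of at least ``min_length`` bp from a normalized profile.

    Adjacent same-direction segments are merged before the length filter. The
    gain/loss cutoffs default to the midpoints between integer copy states.
    """
    if "copy_number" not in profile.segments.columns:
        raise ValueError("profile must be mode-normalized first")
    if profile.n_bins != len(bins):
        raise ValueError("profile and bins disagree in length")
    starts = bins.bins["start"].to_numpy()
    ends = bins.bins["end"].to_numpy()
    chroms = bins.chromosomes
    records = []
    for row in profile.segments.itertuples():
        cn = row.copy_number
        direction = "gain" if cn >= gain_threshold else (
            "loss" if cn <= loss_threshold else None
        )
        if direction is None:
            continue
        lo, hi = row.start_bin, row.end_bin
        records.append(
            {
                "chrom": chroms[lo],
                "start": int(starts[lo]),
                "end": int(ends[hi - 1]),
                "copy_number": float(cn),
                "direction": direction,
                "n_bins": hi - lo,
            }
        )
    calls = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "copy_number", "direction", "n_bins"],
    )
    if calls.empty:
        return calls
    # merge adjacent same-direction calls
    merged = []
    for rec in calls.to_dict("records"):
        if (
            merged
            and rec["chrom"] == merged[-1]["chrom"]
            and rec["direction"] == merged[-1]["direction"]
            and rec["start"] <= merged[-1]["end"]
        ):
            prev = merged[-1]
            w_prev = prev["end"] - prev["start"]
            w_new = rec["end"] - rec["start"]
            prev["copy_number"] = (
                prev["copy_number"] * w_prev + rec["copy_number"] * w_new
            ) / (w_prev + w_new)
            prev["end"] = rec["end"]
            prev["n_bins"] += rec["n_bins"]
        else:
            merged.append(rec)
    calls = pd.DataFrame(merged)
    calls = calls[(calls["end"] - calls["start"]) >= min_length]
    return calls.reset_index(drop=True)


def _calls_to_intervals(calls: pd.DataFrame, direction: str | None = None):
    out: dict[str, list[tuple[int, int]]] = {}
    if calls.empty:
        return out
    frame = calls if direction is None else calls[calls["direction"] == direction]
    for row in frame.itertuples():
        out.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    return out


def evaluate(
    calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    min_length: int = 1_000_000,
    require_direction_match: bool = False,
) -> CNVEvaluation:
    """Score single-cell CNV calls against control calls by overlap length.

    L and L_C are the merged total lengths (bp) of calls >= ``min_length`` in
    the single cell and the control; L_T their intersection. By default the
    overlap is direction-agnostic; strict mode intersects gains with gains and
    losses with losses.
    """
    def _filter(frame):
        if frame.empty:
            return frame
        return frame[(frame["end"] - frame["start"]) >= min_length]

    calls = _filter(calls)
    control_calls = _filter(control_calls)

    def _total(frame):
        return sum(
            e - s
            for ivs in _calls_to_intervals(frame).values()
            for s, e in merge_intervals(ivs)
        )

    L = _total(calls)
    L_C = _total(control_calls)
    if require_direction_match:
        L_T = sum(
            intersect_length(
                _calls_to_intervals(calls, d), _calls_to_intervals(control_calls, d)
            )
            for d in ("gain", "loss")
        )
    else:
        L_T = intersect_length(
            _calls_to_intervals(calls), _calls_to_intervals(control_calls)
        )
    return CNVEvaluation(L=int(L), L_C=int(L_C), L_T=int(L_T))
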