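"""Synthetic-data generators emulating WGA-method-specific biases.

Everything in the evaluation framework can run without external data: this
module fabricates (a) a golden-control genotype set partitioned into
HOMref/HOMmut/HETref, (b) single-cell calls corrupted by parameterized allele
drop-out, false-positive substitution and incomplete coverage, (c) over-
dispersed per-bin read counts with method-specific amplification bias and
embedded copy-number segments, and (d) breakpoint sets mixing true structural
variants with short-range chimeric junctions.

All randomness flows from one explicit integer seed through a single numpy
generator per call; identical seeds reproduce identical outputs.

The per-bin amplification factor is log-normal with unit *median* (log-mean
zero), keeping the modal ratio anchored so that mode normalization maps the
unamplified state to copy number two. Any heavy-tailed positive mixing
distribution would serve; log-normal is this package's choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chimera import Breakpoint
from .cnv import BinnedCounts, BinScheme, _region_ratio_per_bin
from .concordance import CATEGORIES, GoldenControl, SingleCellCalls
from .genome import GenomeLayout
from .profiles import CHIMERA_TYPES, MethodProfile

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CNVTruthProfile:
    """Ground-truth copy-number regions; ploidy 2 everywhere else.

    Regions are 0-based half-open, non-overlapping within a chromosome, with
    non-negative integer copy number N.
    """

    regions: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "copy_number"}
        if self.regions.empty:
            object.__setattr__(
                self,
                "regions",
                pd.DataFrame(columns=["chrom", "start", "end", "copy_number"]),
            )
            return
        if required - set(self.regions.columns):
            raise ValueError(f"truth profile needs columns {sorted(required)}")
        frame = self.regions.sort_values(["chrom", "start"], ignore_index=True)
        if (frame["end"] <= frame["start"]).any():
            raise ValueError("region end must exceed start")
        if (frame["copy_number"] < 0).any():
            raise ValueError("copy number must be non-negative")
        for _, grp in frame.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping truth regions")
        object.__setattr__(self, "regions", frame)

    def spike_regions(self):
        from .cnv import SpikeInRegion

        return [
            SpikeInRegion(r.chrom, int(r.start), int(r.end), int(r.copy_number))
            for r in self.regions.itertuples()
        ]


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct, sorted 1-based positions on a chromosome of given length."""
    if n > length:
        raise ValueError("n_sites exceeds available positions")
    if n > length // 2:
        return np.sort(rng.choice(length, size=n, replace=False)) + 1
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    while chosen.size < n:
        draw = rng.integers(0, length, size=int((n - chosen.size) * 1.3) + 8)
        chosen = np.unique(np.concatenate([chosen, draw]))
    return np.sort(rng.choice(chosen, size=n, replace=False)) + 1


def simulate_golden_control(
    n_sites: int,
    category_proportions: tuple[float, float, float],
    layout: GenomeLayout,
    seed: int = 0,
) -> GoldenControl:
    """Golden control with HOMref/HOMmut/HETref sites in given proportions.

    Positions are distinct and strictly increasing per chromosome; categories
    are multinomially assigned with the requested proportions; reference and
    alternative bases are uniform.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    props = np.asarray(category_proportions, dtype=float)
    if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("category proportions must be 3 non-negative reals summing to 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([layout.lengths[c] for c in layout.chromosomes], dtype=float)
    if n_sites > layout.total_length:
        raise ValueError("n_sites exceeds genome positions")
    per_chrom = rng.multinomial(n_sites, lengths / lengths.sum())
    frames = []
    for chrom, k in zip(layout.chromosomes, per_chrom):
        if k == 0:
            continue
        pos = _sample_positions(rng, layout.lengths[chrom], int(k))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    n = len(sites)
    cat_idx = rng.choice(3, size=n, p=props)
    ref = _BASES[rng.integers(0, 4, size=n)]
    # alternative base: uniform among the three non-reference bases
    shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    a1 = ref.copy()
    a2 = ref.copy()
    hommut = cat_idx == 1
    a1[hommut] = alt[hommut]
    a2[hommut] = alt[hommut]
    hetref = cat_idx == 2
    a2[hetref] = alt[hetref]
    sites["a1"] = a1
    sites["a2"] = a2
    sites["ref"] = ref
    sites["category"] = np.array(CATEGORIES)[cat_idx]
    return GoldenControl(sites)


def simulate_single_cell_calls(
    control: GoldenControl,
    profile: MethodProfile,
    seed: int = 0,
    ado_ref_biased: bool = False,
) -> SingleCellCalls:
    """Corrupt a golden control into single-cell calls.

    Per control site, independently: uncovered with probability
    1 - site_coverage; a covered HETref site drops one allele with probability
    ado_rate (the retained allele is chosen uniformly, or is always the
    reference when ``ado_ref_biased``); a covered site not hit by drop-out
    gains a spurious substitution with probability fp_rate, the spurious base
    drawn uniformly among bases absent from the control genotype so the event
    stays identifiable. truth labels record every event.
    """
    rng = np.random.default_rng(seed)
    sites = control.sites
    n = len(sites)
    covered = rng.random(n) < profile.site_coverage
    a1 = sites["a1"].to_numpy(dtype="U1").copy()
    a2 = sites["a2"].to_numpy(dtype="U1").copy()
    ref = sites["ref"].to_numpy(dtype="U1")
    het = a1 != a2
    labels = np.full(n, "faithful", dtype="U9")
    labels[~covered] = "uncovered"

    ado = covered & het & (rng.random(n) < profile.ado_rate)
    if ado_ref_biased:
        keep_first = a1 == ref  # pairs are sorted; reference may sit in either slot
        retained = np.where(keep_first, a1, a2)
    else:
        retained = np.where(rng.random(n) < 0.5, a1, a2)
    a1[ado] = retained[ado]
    a2[ado] = retained[ado]
    labels[ado] = "ADO"

    fp = covered & ~ado & (rng.random(n) < profile.fp_rate)
    fp_idx = np.flatnonzero(fp)
    if fp_idx.size:
        for i in fp_idx:
            present = {a1[i], a2[i]}
            options = [b for b in "ACGT" if b not in present]
            novel = options[rng.integers(0, len(options))]
            if rng.random() < 0.5:
                a1[i] = novel
            else:
                a2[i] = novel
        labels[fp_idx] = "FP"

    calls = sites.loc[covered, ["chrom", "pos"]].copy()
    calls["a1"] = a1[covered]
    calls["a2"] = a2[covered]
    calls["callable"] = True
    truth = sites[["chrom", "pos"]].copy()
    truth["label"] = labels
    return SingleCellCalls(calls, truth_labels=truth)


def simulate_binned_counts(
    bins: BinScheme,
    truth: CNVTruthProfile,
    profile: MethodProfile,
    mean_count_per_bin: float,
    seed: int = 0,
) -> BinnedCounts:
    """Over-dispersed per-bin read counts with embedded copy-number segments.

    Count ~ Poisson(mean x a_b x N_b / 2) with a_b log-normal (log-s.d. =
    bin_dispersion, unit median) and N_b the length-weighted truth copy number
    over the bin.
    """
    if mean_count_per_bin <= 0:
        raise ValueError("mean_count_per_bin must be positive")
    if profile.bin_dispersion < 0:
        raise ValueError("negative dispersion")
    rng = np.random.default_rng(seed)
    n = len(bins)
    amp = rng.lognormal(mean=0.0, sigma=profile.bin_dispersion, size=n)
    ratio = _region_ratio_per_bin(bins, truth.spike_regions())
    lam = mean_count_per_bin * amp * ratio
    return BinnedCounts(rng.poisson(lam), sample=profile.name)


def simulate_breakpoints(
    true_breakpoints: list[Breakpoint],
    profile: MethodProfile,
    layout: GenomeLayout,
    seed: int = 0,
    jitter: int = 50,
) -> tuple[list[Breakpoint], list[Breakpoint], np.ndarray]:
    """Control and single-cell breakpoint sets with injected chimeras.

    The control set is the true breakpoints. The single-cell set retains every
    true breakpoint with both ends jittered uniformly within +/- ``jitter`` bp
    (half the default 100 bp matching threshold, so true events remain
    matchable by construction), plus injected chimeras with types drawn from
    the profile's mix. Same-chromosome chimeras have exponentially distributed
    spans with scale ``chimera_itx_length_scale`` (short-range junctions from
    neighbouring amplicons); CTX chimeras join two distinct chromosomes at
    uniform positions. Returns (control, single_cell, labels) with labels
    marking injected items "chimera".
    """
    rng = np.random.default_rng(seed)
    chroms = layout.chromosomes
    lengths = np.array([layout.lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    single_cell: list[Breakpoint] = []
    for bp in true_breakpoints:
        la, lb = layout.lengths[bp.chromA], layout.lengths[bp.chromB]
        pa = int(np.clip(bp.posA + rng.integers(-jitter, jitter + 1), 1, la))
        pb = int(np.clip(bp.posB + rng.integers(-jitter, jitter + 1), 1, lb))
        single_cell.append(Breakpoint(bp.type, bp.chromA, pa, bp.chromB, pb))
    labels = ["true"] * len(single_cell)

    n_chim = int(rng.poisson(profile.chimera_rate * len(true_breakpoints)))
    mix = np.array([profile.chimera_type_mix.get(t, 0.0) for t in CHIMERA_TYPES])
    types = rng.choice(len(CHIMERA_TYPES), size=n_chim, p=mix)
    for t_idx in types:
        btype = CHIMERA_TYPES[t_idx]
        if btype == "CTX":
            ci, cj = rng.choice(len(chroms), size=2, replace=False, p=weights)
            bp = Breakpoint(
                "CTX",
                chroms[ci],
                int(rng.integers(1, layout.lengths[chroms[ci]] + 1)),
                chroms[cj],
                int(rng.integers(1, layout.lengths[chroms[cj]] + 1)),
            )
        else:
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            length = layout.lengths[chrom]
            pa = int(rng.integers(1, length + 1))
            span = max(1, int(rng.exponential(profile.chimera_itx_length_scale)))
            pb = min(pa + span, length)
            bp = Breakpoint(btype, chrom, pa, chrom, pb)
        single_cell.append(bp)
        labels.append("chimera")
    return list(true_breakpoints), single_cell, np.array(labels, dtype="U7")
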