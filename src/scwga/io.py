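"""Readers and writers for the flat formats the pipeline consumes.

Genotype tables travel as 5-column TSV (chrom, pos, a1, a2, ref[, callable])
or VCF (GT field, reference from REF; read through cyvcf2); interval inputs as
BED (0-based half-open, optional copy-number column); breakpoints as a
BEDPE-like TSV (chromA, posA, chromB, posB, type); depth tracks and bin counts
as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chimera import Breakpoint
from .cnv import BinnedCounts, BinScheme
from .concordance import GoldenControl, SingleCellCalls
from .uniformity import DepthTrack

# --- genotype tables -------------------------------------------------------

GENOTYPE_TSV_COLUMNS = ["chrom", "pos", "a1", "a2", "ref"]


def write_genotypes_tsv(frame: pd.DataFrame, path) -> None:
    cols = GENOTYPE_TSV_COLUMNS + (
        ["callable"] if "callable" in frame.columns else []
    )
    frame[cols].to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENOTYPE_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_genotypes_vcf(path) -> pd.DataFrame:
    """First-sample genotypes from a VCF; rows with missing GT are skipped."""
    from cyvcf2 import VCF

    rows = []
    for variant in VCF(str(path)):
        gts = variant.genotypes
        if not gts:
            continue
        g0, g1 = gts[0][0], gts[0][1]
        if g0 < 0 or g1 < 0:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        a1, a2 = alleles[g0], alleles[g1]
        if len(a1) != 1 or len(a2) != 1 or len(variant.REF) != 1:
            continue  # SNVs only
        rows.append((variant.CHROM, variant.POS, a1, a2, variant.REF))
    return pd.DataFrame(rows, columns=GENOTYPE_TSV_COLUMNS)


def write_genotypes_vcf(frame: pd.DataFrame, path, sample: str = "sample") -> None:
    """Minimal single-sample VCF (GT only) from a genotype table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for row in frame.itertuples():
            alts = sorted({a for a in (row.a1, row.a2) if a != row.ref})
            alt_field = ",".join(alts) if alts else "."
            index = {row.ref: 0}
            index.update({a: i + 1 for i, a in enumerate(alts)})
            gt = f"{index[row.a1]}/{index[row.a2]}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alt_field}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_golden_control(control: GoldenControl, path) -> None:
    control.sites.to_csv(path, sep="\t", index=False)


def read_golden_control(path) -> GoldenControl:
    return GoldenControl(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_calls(calls: SingleCellCalls, path, labels_path=None) -> None:
    calls.calls.to_csv(path, sep="\t", index=False)
    if labels_path is not None and calls.truth_labels is not None:
        calls.truth_labels.to_csv(labels_path, sep="\t", index=False)


def read_calls(path, labels_path=None) -> SingleCellCalls:
    calls = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    labels = (
        pd.read_csv(labels_path, sep="\t", dtype={"chrom": str})
        if labels_path is not None
        else None
    )
    return SingleCellCalls(calls, truth_labels=labels)


# --- intervals -------------------------------------------------------------


def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_columns or [])
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=names, dtype={"chrom": str}
    )
    return frame


def write_bed(frame: pd.DataFrame, path, extra_columns: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_columns or [])
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


# --- bins and counts -------------------------------------------------------


def write_bins(bins: BinScheme, path) -> None:
    bins.bins.to_csv(path, sep="\t", index=False)


def read_bins(path) -> BinScheme:
    return BinScheme(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_counts(counts: BinnedCounts, path) -> None:
    pd.DataFrame({"bin": np.arange(len(counts)), "count": counts.counts}).to_csv(
        path, sep="\t", index=False
    )


def read_counts(path, sample: str = "sample") -> BinnedCounts:
    frame = pd.read_csv(path, sep="\t")
    return BinnedCounts(frame["count"].to_numpy(), sample)


# --- depth tracks ----------------------------------------------------------


def read_depth_track(path, nominal_width: int = 100_000) -> DepthTrack:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return DepthTrack(frame, nominal_width=nominal_width)


def write_depth_track(track: DepthTrack, path) -> None:
    track.windows.to_csv(path, sep="\t", index=False)


# --- breakpoints -----------------------------------------------------------

BEDPE_COLUMNS = ["chromA", "posA", "chromB", "posB", "type"]


def write_breakpoints(breakpoints: list[Breakpoint], path, labels=None) -> None:
    rows = [
        (bp.chromA, bp.posA, bp.chromB, bp.posB, bp.type) for bp in breakpoints
    ]
    frame = pd.DataFrame(rows, columns=BEDPE_COLUMNS)
    if labels is not None:
        frame["label"] = labels
    frame.to_csv(path, sep="\t", index=False)


def read_breakpoints(path) -> list[Breakpoint]:
    frame = pd.read_csv(path, sep="\t", dtype={"chromA": str, "chromB": str})
    missing = set(BEDPE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        Breakpoint(r.type, r.chromA, int(r.posA), r.chromB, int(r.posB))
        for r in frame.itertuples()
    ]
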