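"""Genotype concordance of single-cell calls against a golden control.

The golden control is a consensus genotype set from bulk sequencing restricted
to SNP-array positions; it is the comparison baseline for every single-cell
genotype metric here. Genotypes are unordered allele pairs over {A,C,G,T} and
fall into three categories relative to the reference base:

* ``HOMref`` - both alleles equal the reference,
* ``HOMmut`` - both alleles equal each other but not the reference,
* ``HETref`` - exactly one allele equals the reference.

Single-cell and control genotypes are cross-tabulated at allele-share levels
2/1/0 (the multiset-intersection size of the two allele pairs), from which the
consensus-genotype detection efficiency (CGDE, a coverage-like fraction) and
the concordant ratio (consistency) are computed. SNV-level accuracy against a
bulk call set yields the ADO ratio, FP ratio, and detection efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = frozenset("ACGT")
CATEGORIES = ("HOMref", "HOMmut", "HETref")
SHARE_LEVELS = (2, 1, 0)
HETALT = "HETalt"  # heterozygous, neither allele matches the reference

GENOTYPE_COLUMNS = ["chrom", "pos", "a1", "a2", "ref"]


def classify_genotype(genotype, reference: str, permissive: bool = False) -> str:
    """Assign a genotype (unordered allele pair) to HOMref/HOMmut/HETref.

    A heterozygote with neither allele equal to the reference has no slot in
    the three-category scheme; it is rejected unless ``permissive`` maps it to
    the internal ``HETalt`` label (excluded from tabulated outputs).
    """
    a1, a2 = genotype
    for allele in (a1, a2, reference):
        if allele not in BASES:
            raise ValueError(f"invalid base {allele!r}")
    if a1 == a2:
        return "HOMref" if a1 == reference else "HOMmut"
    if a1 == reference or a2 == reference:
        return "HETref"
    if permissive:
        return HETALT
    raise ValueError(
        f"heterozygous non-reference genotype {a1}/{a2} vs ref {reference} "
        "is not representable (pass permissive=True to tag it HETalt)"
    )


def allele_share(g1, g2) -> int:
    """Number of alleles shared between two genotypes (multiset intersection)."""
    a, b = sorted(g1), sorted(g2)
    shared = 0
    i = j = 0
    while i < 2 and j < 2:
        if a[i] == b[j]:
            shared += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return shared


def _normalize_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Sort each allele pair so (a1, a2) is order-free."""
    out = df.copy()
    a1 = df["a1"].to_numpy(dtype="U1")
    a2 = df["a2"].to_numpy(dtype="U1")
    swap = a1 > a2
    out["a1"] = np.where(swap, a2, a1)
    out["a2"] = np.where(swap, a1, a2)
    return out


def _classify_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized category assignment; unknown het-nonref becomes HETalt."""
    a1 = df["a1"].to_numpy(dtype="U1")
    a2 = df["a2"].to_numpy(dtype="U1")
    ref = df["ref"].to_numpy(dtype="U1")
    cat = np.full(len(df), HETALT, dtype="U6")
    hom = a1 == a2
    cat[hom & (a1 == ref)] = "HOMref"
    cat[hom & (a1 != ref)] = "HOMmut"
    het_ref = ~hom & ((a1 == ref) | (a2 == ref))
    cat[het_ref] = "HETref"
    return pd.Series(cat, index=df.index)


@dataclass(frozen=True)
class GoldenControl:
    """Reference genotype set: chrom, pos (1-based), a1, a2, ref, category."""

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sites.empty:
            raise ValueError("golden control is empty")
        missing = set(GENOTYPE_COLUMNS) - set(self.sites.columns)
        if missing:
            raise ValueError(f"golden control missing columns {sorted(missing)}")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate positions in golden control")
        frame = _normalize_pairs(self.sites)
        if "category" not in frame.columns:
            frame["category"] = _classify_frame(frame)
        object.__setattr__(self, "sites", frame.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def category_counts(self) -> dict[str, int]:
        counts = self.sites["category"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}


@dataclass(frozen=True)
class SingleCellCalls:
    """Covered single-cell genotype calls; uncovered sites are absent.

    ``truth_labels`` (simulation only) tags every generating-control site with
    one of faithful/ADO/FP/uncovered.
    """

    calls: pd.DataFrame
    truth_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        frame = _normalize_pairs(self.calls)
        if "callable" not in frame.columns:
            frame["callable"] = True
        object.__setattr__(self, "calls", frame.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.calls)


def build_golden_control(
    bulk: pd.DataFrame,
    bulk2: pd.DataFrame | None = None,
    chip: pd.DataFrame | None = None,
    require_chip_match: bool = False,
    permissive: bool = True,
) -> GoldenControl:
    """Consensus of one or two bulk genotype tables restricted to chip sites.

    With two bulks only positions genotyped identically in both survive; the
    survivors are then restricted to positions present on the chip. By default
    chip restriction is positional; ``require_chip_match`` additionally
    requires the bulk genotype to equal the chip genotype.
    ``permissive`` drops het-nonref sites (no category slot) instead of
    raising.
    """
    bulk = _normalize_pairs(bulk)
    if "callable" in bulk.columns:
        bulk = bulk[bulk["callable"]]
    if bulk2 is not None:
        bulk2 = _normalize_pairs(bulk2)
        if "callable" in bulk2.columns:
            bulk2 = bulk2[bulk2["callable"]]
        merged = bulk.merge(
            bulk2[["chrom", "pos", "a1", "a2"]],
            on=["chrom", "pos"],
            suffixes=("", "_b2"),
        )
        concordant = (merged["a1"] == merged["a1_b2"]) & (merged["a2"] == merged["a2_b2"])
        bulk = merged.loc[concordant, bulk.columns.tolist()]
    if chip is not None:
        chip_cols = ["chrom", "pos"]
        chip_frame = chip
        if require_chip_match:
            if not {"a1", "a2"} <= set(chip.columns):
                raise ValueError("require_chip_match needs chip genotypes (a1, a2)")
            chip_frame = _normalize_pairs(chip)
            chip_cols += ["a1", "a2"]
        bulk = bulk.merge(chip_frame[chip_cols].drop_duplicates(), on=chip_cols)
    if bulk.empty:
        raise ValueError("empty intersection while building golden control")
    category = _classify_frame(bulk)
    keep = category != HETALT
    if not permissive and not keep.all():
        raise ValueError("het-nonref genotypes present in consensus")
    frame = bulk.loc[keep].copy()
    frame["category"] = category[keep]
    return GoldenControl(frame)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Cross-tabulation of single-cell vs control categories at share 2/1/0.

    ``counts[i, j, k]`` counts control sites whose single-cell category is
    ``CATEGORIES[i]``, control category ``CATEGORIES[j]``, sharing
    ``SHARE_LEVELS[k]`` alleles. The matrix is control-anchored: sites called
    in the cell but absent from the control are not represented here.
    """

    counts: np.ndarray
    control_totals: np.ndarray
    n_excluded_hetalt: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (3, 3, 3):
            raise ValueError("counts must be 3x3x3 (sc x control x share)")
        detected = self.counts.sum(axis=(0, 2))
        if np.any(detected > self.control_totals + 1e-9):
            raise ValueError("detected counts exceed control totals")

    @property
    def detected_per_control_category(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 2))

    @property
    def detected_total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_arrays(cls, counts, control_totals, n_excluded_hetalt=0) -> "ConcordanceMatrix":
        return cls(
            np.asarray(counts, dtype=float),
            np.asarray(control_totals, dtype=float),
            int(n_excluded_hetalt),
        )


def concordance_matrix(single_cell: SingleCellCalls, control: GoldenControl) -> ConcordanceMatrix:
    """Tabulate single-cell genotypes against the golden control.

    Iterates control sites only; control sites without a call contribute to the
    undetected mass (control total minus detected). Het-nonref single-cell
    calls are excluded from the three-category table and counted separately.
    """
    ctrl = control.sites
    calls = single_cell.calls
    calls = calls[calls["callable"]]
    merged = ctrl.merge(
        calls[["chrom", "pos", "a1", "a2"]],
        on=["chrom", "pos"],
        suffixes=("_ctrl", "_sc"),
    )
    ref = merged["ref"].to_numpy(dtype="U1")
    sc = merged.rename(columns={"a1_sc": "a1", "a2_sc": "a2"})[["a1", "a2"]]
    sc["ref"] = ref
    sc_cat = _classify_frame(sc).to_numpy()
    ctrl_cat = merged["category"].to_numpy()
    # vectorized multiset intersection of sorted pairs
    c1 = merged["a1_ctrl"].to_numpy(dtype="U1")
    c2 = merged["a2_ctrl"].to_numpy(dtype="U1")
    s1 = sc["a1"].to_numpy(dtype="U1")
    s2 = sc["a2"].to_numpy(dtype="U1")
    both = (c1 == s1) & (c2 == s2)
    any1 = (c1 == s1) | (c1 == s2) | (c2 == s1) | (c2 == s2)
    share = np.where(both, 2, np.where(any1, 1, 0))
    # a hom pair vs het pair sharing the hom allele shares exactly 1, which
    # the masks above already encode; hom vs same hom hits `both`.
    keep = sc_cat != HETALT
    n_hetalt = int((~keep).sum())
    counts = np.zeros((3, 3, 3))
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    share_index = {lvl: k for k, lvl in enumerate(SHARE_LEVELS)}
    for i_sc, i_ctrl, lvl in zip(sc_cat[keep], ctrl_cat[keep], share[keep]):
        counts[cat_index[i_sc], cat_index[i_ctrl], share_index[int(lvl)]] += 1
    control_totals = np.array(
        [control.category_counts[c] for c in CATEGORIES], dtype=float
    )
    return ConcordanceMatrix(counts, control_totals, n_hetalt)


def cgde(matrix: ConcordanceMatrix) -> dict[str, float]:
    """Consensus-genotype detection efficiency per control category + overall.

    The fraction of golden-control sites genotyped in the single cell.
    """
    detected = matrix.detected_per_control_category
    totals = matrix.control_totals
    if np.any(totals <= 0):
        raise ValueError("every control category must be nonempty")
    out = {c: float(d / t) for c, d, t in zip(CATEGORIES, detected, totals)}
    out["overall"] = float(detected.sum() / totals.sum())
    return out


def consistency(matrix: ConcordanceMatrix) -> dict[str, float]:
    """Concordant ratio: share-2 fraction per single-cell category + overall."""
    share2 = matrix.counts[:, :, 0].sum(axis=1)
    detected = matrix.counts.sum(axis=(1, 2))
    if matrix.detected_total <= 0:
        raise ValueError("no detected sites")
    out = {}
    for c, s2, d in zip(CATEGORIES, share2, detected):
        out[c] = float(s2 / d) if d > 0 else float("nan")
    out["overall"] = float(share2.sum() / detected.sum())
    return out


@dataclass(frozen=True)
class SNVMetrics:
    """SNV-level accuracy of a single cell against its bulk control.

    The FP ratio divides WGA-introduced false-positive SNVs by the number of
    genotypable genome sites (default 3e9, the human genome); the ADO ratio
    divides allele-drop-out events by detected-het + ADO sites. Efficiency is
    exposed both gross (detected/control) and net (FP-subtracted).
    """

    detected_het: int
    detected_hom: int
    fp_het: int
    fp_hom: int
    ado_count: int
    control_het: int
    control_hom: int
    genome_sites: int = 3_000_000_000

    def __post_init__(self) -> None:
        if self.fp_het > self.detected_het or self.fp_hom > self.detected_hom:
            raise ValueError("false positives cannot exceed detected counts")
        if self.control_het + self.control_hom <= 0:
            raise ValueError("bulk control SNV set is empty")

    @property
    def detected_total(self) -> int:
        return self.detected_het + self.detected_hom

    @property
    def fp_total(self) -> int:
        return self.fp_het + self.fp_hom

    @property
    def control_total(self) -> int:
        return self.control_het + self.control_hom

    @property
    def ado_ratio(self) -> float:
        denom = self.detected_het + self.ado_count
        return self.ado_count / denom if denom else 0.0

    @property
    def fp_ratio(self) -> float:
        return self.fp_total / self.genome_sites

    @property
    def efficiency_gross(self) -> float:
        return self.detected_total / self.control_total

    @property
    def efficiency_net(self) -> float:
        return (self.detected_total - self.fp_total) / self.control_total

    @property
    def efficiency_het_net(self) -> float:
        return (self.detected_het - self.fp_het) / self.control_het

    @property
    def efficiency_hom_net(self) -> float:
        return (self.detected_hom - self.fp_hom) / self.control_hom


def snv_metrics(
    single_cell: pd.DataFrame,
    bulk: pd.DataFrame,
    genome_sites: int = 3_000_000_000,
) -> SNVMetrics:
    """Compute SNV detection accuracy from genotype tables.

    ``single_cell`` is a covered-site genotype table (hom-ref calls included so
    drop-out of the alternative allele is observable); ``bulk`` is the control
    genotype table. SNVs are rows whose genotype differs from (ref, ref). A
    single-cell SNV at a position without a bulk SNV is a false positive; a
    bulk het site covered in the cell but called homozygous for one of the
    bulk alleles is an allele drop-out.
    """
    sc = _normalize_pairs(single_cell)
    bk = _normalize_pairs(bulk)
    sc_is_snv = (sc["a1"] != sc["ref"]) | (sc["a2"] != sc["ref"])
    bk_is_snv = (bk["a1"] != bk["ref"]) | (bk["a2"] != bk["ref"])
    sc_snv = sc[sc_is_snv]
    bk_snv = bk[bk_is_snv]
    sc_het = (sc_snv["a1"] != sc_snv["a2"]).to_numpy()

    detected_het = int(sc_het.sum())
    detected_hom = int(len(sc_snv) - sc_het.sum())

    in_bulk = sc_snv.merge(
        bk_snv[["chrom", "pos"]], on=["chrom", "pos"], how="left", indicator=True
    )["_merge"].eq("both").to_numpy()
    fp_het = int((sc_het & ~in_bulk).sum())
    fp_hom = int((~sc_het & ~in_bulk).sum())

    bk_het = bk_snv[bk_snv["a1"] != bk_snv["a2"]]
    ado_frame = bk_het.merge(
        sc[["chrom", "pos", "a1", "a2"]], on=["chrom", "pos"], suffixes=("_bulk", "_sc")
    )
    sc_hom = ado_frame["a1_sc"] == ado_frame["a2_sc"]
    retained = sc_hom & (
        (ado_frame["a1_sc"] == ado_frame["a1_bulk"])
        | (ado_frame["a1_sc"] == ado_frame["a2_bulk"])
    )
    ado_count = int(retained.sum())

    control_het = int(len(bk_het))
    control_hom = int(len(bk_snv) - control_het)
    return SNVMetrics(
        detected_het=detected_het,
        detected_hom=detected_hom,
        fp_het=fp_het,
        fp_hom=fp_hom,
        ado_count=ado_count,
        control_het=control_het,
        control_hom=control_hom,
        genome_sites=int(genome_sites),
    )


def ado_fp_counts(single_cell: SingleCellCalls, control: GoldenControl) -> dict[str, int]:
    """Count ADO and FP events of calls against the generating control.

    ADO: control-het site called homozygous for one of the control alleles.
    FP: call carrying an allele absent from the control genotype at that site.
    On simulated data with the same control these equal the truth-label counts
    exactly.
    """
    merged = control.sites.merge(
        single_cell.calls[single_cell.calls["callable"]][["chrom", "pos", "a1", "a2"]],
        on=["chrom", "pos"],
        suffixes=("_ctrl", "_sc"),
    )
    c1 = merged["a1_ctrl"].to_numpy(dtype="U1")
    c2 = merged["a2_ctrl"].to_numpy(dtype="U1")
    s1 = merged["a1_sc"].to_numpy(dtype="U1")
    s2 = merged["a2_sc"].to_numpy(dtype="U1")
    ctrl_het = c1 != c2
    sc_hom = s1 == s2
    ado = ctrl_het & sc_hom & ((s1 == c1) | (s1 == c2))
    novel = ((s1 != c1) & (s1 != c2)) | ((s2 != c1) & (s2 != c2))
    fp = novel & ~ado
    return {
        "ado": int(ado.sum()),
        "fp": int(fp.sum()),
        "detected": int(len(merged)),
        "detected_het": int((~sc_hom).sum()),
    }
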