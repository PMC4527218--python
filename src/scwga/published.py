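"""Published per-cell count tables used as worked-example inputs.

These are the printed cross-tabulations and SNV counts for deep-sequenced
single cells: the MDA block compares YH lymphoblastoid single cells against
the YH bulk golden control, the MALBAC block compares SW480 colon-cancer
single cells against the SW480 bulk golden control, and the SNV table holds
per-cell detected/false-positive/drop-out counts for three MDA-2 cells against
the unamplified YH-mix control. Only raw counts are stored; every ratio
(CGDE, consistency, ADO ratio, FP ratio, efficiency) is computed by the
package's estimators.

Fractional counts arise because the printed tables average over replicate
cells.
"""

from __future__ import annotations

import numpy as np

from .concordance import CATEGORIES, ConcordanceMatrix, SNVMetrics

# Cross-tabulation counts[sc_category][control_category][share_level], with
# category order (HOMref, HOMmut, HETref) and share-level order (2, 1, 0).


def _matrix(cells: dict[tuple[str, str, int], float], totals) -> ConcordanceMatrix:
    counts = np.zeros((3, 3, 3))
    cat = {c: i for i, c in enumerate(CATEGORIES)}
    share = {2: 0, 1: 1, 0: 2}
    for (sc, ctrl, lvl), value in cells.items():
        counts[cat[sc], cat[ctrl], share[lvl]] = value
    return ConcordanceMatrix(counts, np.asarray(totals, dtype=float))


def mda_yh_matrix() -> ConcordanceMatrix:
    """Mean cross-tabulation of MDA-amplified YH single cells vs YH control."""
    return _matrix(
        {
            ("HOMref", "HOMref", 2): 1_373_228.00,
            ("HOMref", "HETref", 1): 21_871.00,
            ("HOMref", "HOMmut", 0): 14.33,
            ("HOMmut", "HOMmut", 2): 256_682.67,
            ("HOMmut", "HETref", 1): 27_674.00,
            ("HOMmut", "HOMref", 0): 7.33,
            ("HOMmut", "HOMmut", 0): 1.67,
            ("HOMmut", "HETref", 0): 0.00,
            ("HETref", "HETref", 2): 256_185.67,
            ("HETref", "HOMref", 1): 212.67,
            ("HETref", "HOMmut", 1): 326.33,
            ("HETref", "HETref", 1): 2.33,
            ("HETref", "HOMmut", 0): 0.00,
        },
        totals=(1_584_649.00, 270_225.00, 351_490.00),
    )


def malbac_sw480_matrix() -> ConcordanceMatrix:
    """Mean cross-tabulation of MALBAC-amplified SW480 cells vs SW480 control."""
    return _matrix(
        {
            ("HOMref", "HOMref", 2): 849_057.40,
            ("HOMref", "HETref", 1): 10_352.40,
            ("HOMref", "HOMmut", 0): 45.40,
            ("HOMmut", "HOMmut", 2): 266_889.00,
            ("HOMmut", "HETref", 1): 18_507.40,
            ("HOMmut", "HOMref", 0): 213.40,
            ("HOMmut", "HOMmut", 0): 11.20,
            ("HOMmut", "HETref", 0): 4.60,
            ("HETref", "HETref", 2): 58_948.80,
            ("HETref", "HOMref", 1): 2_287.20,
            ("HETref", "HOMmut", 1): 6_860.40,
            ("HETref", "HETref", 1): 8.80,
            ("HETref", "HOMmut", 0): 0.00,
        },
        totals=(1_762_437.00, 403_431.00, 173_098.00),
    )


# Per-cell SNV counts against the unamplified YH-mix bulk control
# (control: 2,051,282 heterozygous + 1,598,291 homozygous SNVs).

YH_MIX_CONTROL = {"het": 2_051_282, "hom": 1_598_291}

MDA2_CELL_COUNTS = {
    "MDA-2_46": {
        "detected_het": 777_908, "fp_het": 5_563, "ado": 390_038,
        "detected_hom": 1_747_004, "fp_hom": 390_107,
    },
    "MDA-2_47": {
        "detected_het": 1_807_282, "fp_het": 6_517, "ado": 14_124,
        "detected_hom": 1_562_036, "fp_hom": 14_177,
    },
    "MDA-2_66": {
        "detected_het": 1_651_733, "fp_het": 6_347, "ado": 55_158,
        "detected_hom": 1_587_456, "fp_hom": 55_195,
    },
}

CHIMERA_TYPE_MIX = {"ITX": 0.8208, "CTX": 0.0113, "DEL": 0.0809,
                    "INS": 0.0507, "INV": 0.0368}


def mda2_cell_metrics(genome_sites: int = 3_000_000_000) -> dict[str, SNVMetrics]:
    """Per-cell SNV metrics assembled from the printed counts."""
    out = {}
    for cell, c in MDA2_CELL_COUNTS.items():
        out[cell] = SNVMetrics(
            detected_het=c["detected_het"],
            detected_hom=c["detected_hom"],
            fp_het=c["fp_het"],
            fp_hom=c["fp_hom"],
            ado_count=c["ado"],
            control_het=YH_MIX_CONTROL["het"],
            control_hom=YH_MIX_CONTROL["hom"],
            genome_sites=genome_sites,
        )
    return out
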