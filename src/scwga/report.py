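"""Summary-table rendering for concordance matrices and SNV metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import (
    CATEGORIES,
    SHARE_LEVELS,
    ConcordanceMatrix,
    SNVMetrics,
    cgde,
    consistency,
)


def concordance_table(matrix: ConcordanceMatrix) -> pd.DataFrame:
    """Labelled cross-tabulation with per-row consistency and per-column CGDE.

    Rows are (single-cell category, share level); columns are control
    categories plus a row total and consistency percentage; the final rows
    give column totals and coverage (CGDE) percentages.
    """
    rows = []
    cons = consistency(matrix)
    for i, sc_cat in enumerate(CATEGORIES):
        for k, lvl in enumerate(SHARE_LEVELS):
            rows.append(
                {
                    "single_cell": sc_cat,
                    "share": lvl,
                    **{c: matrix.counts[i, j, k] for j, c in enumerate(CATEGORIES)},
                    "total": matrix.counts[i, :, k].sum(),
                    "consistency_pct": 100.0 * cons[sc_cat] if lvl == 2 else np.nan,
                }
            )
    cov = cgde(matrix)
    detected = matrix.detected_per_control_category
    rows.append(
        {
            "single_cell": "Total",
            "share": "",
            **{c: detected[j] for j, c in enumerate(CATEGORIES)},
            "total": detected.sum(),
            "consistency_pct": 100.0 * cons["overall"],
        }
    )
    rows.append(
        {
            "single_cell": "Coverage (%)",
            "share": "",
            **{c: 100.0 * cov[c] for c in CATEGORIES},
            "total": 100.0 * cov["overall"],
            "consistency_pct": np.nan,
        }
    )
    return pd.DataFrame(rows)


def snv_table(metrics: dict[str, SNVMetrics]) -> pd.DataFrame:
    """Per-cell SNV accuracy: detected/FP/ADO counts and derived ratios."""
    rows = []
    for cell, m in metrics.items():
        rows.append(
            {
                "cell": cell,
                "detected_het": m.detected_het,
                "fp_het": m.fp_het,
                "ado_count": m.ado_count,
                "efficiency_het_net_pct": 100.0 * m.efficiency_het_net,
                "detected_hom": m.detected_hom,
                "fp_hom": m.fp_hom,
                "efficiency_hom_net_pct": 100.0 * m.efficiency_hom_net,
                "detected_total": m.detected_total,
                "fp_total": m.fp_total,
                "efficiency_net_pct": 100.0 * m.efficiency_net,
                "efficiency_gross_pct": 100.0 * m.efficiency_gross,
                "fp_ratio": m.fp_ratio,
                "ado_ratio": m.ado_ratio,
            }
        )
    return pd.DataFrame(rows)
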