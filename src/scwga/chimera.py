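"""Chimeric-breakpoint classification.

Whole-genome amplification (MDA especially) joins neighbouring amplicons into
artifactual junctions, dominantly short-range intra-chromosomal ones (ITX).
A single-cell breakpoint is accepted as a true structural variant when a
matched control (bulk) breakpoint of the same type lies within a distance
threshold (default 100 bp) at both ends; everything unmatched is a chimera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TestResult, mann_whitney

BREAKPOINT_TYPES = ("INS", "DEL", "INV", "ITX", "CTX")


@dataclass(frozen=True)
class Breakpoint:
    """Typed structural-variant junction with two 1-based ends.

    Ends are canonicalized (lexicographic chromosome order, then ascending
    position) so matching is orientation-free. CTX if and only if the two
    chromosomes differ.
    """

    type: str
    chromA: str
    posA: int
    chromB: str
    posB: int

    def __post_init__(self) -> None:
        if self.type not in BREAKPOINT_TYPES:
            raise ValueError(f"unknown breakpoint type {self.type!r}")
        if (self.type == "CTX") != (self.chromA != self.chromB):
            raise ValueError("CTX iff chromosomes differ")
        if (self.chromA, self.posA) > (self.chromB, self.posB):
            a, pa = self.chromA, self.posA
            object.__setattr__(self, "chromA", self.chromB)
            object.__setattr__(self, "posA", self.posB)
            object.__setattr__(self, "chromB", a)
            object.__setattr__(self, "posB", pa)

    @property
    def span(self) -> int:
        """End-to-end distance; defined for same-chromosome types only."""
        if self.chromA != self.chromB:
            raise ValueError("span undefined for inter-chromosomal breakpoints")
        return abs(self.posB - self.posA)


@dataclass(frozen=True)
class ChimeraMatchConfig:
    distance_threshold: int = 100
    require_same_type: bool = True
    require_both_ends: bool = True

    def __post_init__(self) -> None:
        if self.distance_threshold < 0:
            raise ValueError("distance threshold must be >= 0")


def match_breakpoints(
    single_cell: list[Breakpoint],
    control: list[Breakpoint],
    config: ChimeraMatchConfig = ChimeraMatchConfig(),
) -> np.ndarray:
    """Label each single-cell breakpoint ``true`` or ``chimera``.

    Greedy one-to-one matching: candidate pairs share the chromosome pairing
    (and the type, unless disabled) and have both ends within the threshold
    (or either end in single-end mode). Candidates are consumed in order of
    smaller total end distance, ties broken by genomic order, and each control
    breakpoint validates at most one single-cell breakpoint.
    """
    labels = np.array(["chimera"] * len(single_cell), dtype="U7")
    groups: dict[tuple, list[int]] = {}
    for idx, bp in enumerate(control):
        key = (bp.chromA, bp.chromB) + ((bp.type,) if config.require_same_type else ())
        groups.setdefault(key, []).append(idx)
    candidates = []
    thr = config.distance_threshold
    for i, bp in enumerate(single_cell):
        key = (bp.chromA, bp.chromB) + ((bp.type,) if config.require_same_type else ())
        for j in groups.get(key, ()):  # noqa: B905
            cb = control[j]
            dA = abs(bp.posA - cb.posA)
            dB = abs(bp.posB - cb.posB)
            ok = (dA <= thr and dB <= thr) if config.require_both_ends else (
                dA <= thr or dB <= thr
            )
            if ok:
                candidates.append(
                    (dA + dB, bp.chromA, bp.posA, bp.chromB, bp.posB, i, j)
                )
    used_control: set[int] = set()
    matched_sc: set[int] = set()
    for cand in sorted(candidates):
        i, j = cand[-2], cand[-1]
        if i in matched_sc or j in used_control:
            continue
        matched_sc.add(i)
        used_control.add(j)
        labels[i] = "true"
    return labels


def chimera_type_fractions(
    breakpoints: list[Breakpoint], labels: np.ndarray
) -> dict[str, float]:
    """Percentage of each breakpoint type among chimera-labelled junctions.

    Returns an empty dict when no chimeras are present. Percentages cover all
    five types and sum to 100.
    """
    chim = [bp.type for bp, lab in zip(breakpoints, labels) if lab == "chimera"]
    if not chim:
        return {}
    n = len(chim)
    return {t: 100.0 * chim.count(t) / n for t in BREAKPOINT_TYPES}


def itx_length_compare(
    true_spans,
    chimera_spans,
    alternative: str = "two-sided",
) -> dict[str, float | TestResult]:
    """Compare span distributions of true vs chimeric intra-chromosomal junctions.

    Chimeras arise from neighbouring amplicons joining on the same chromosome,
    so their spans are expected to be stochastically shorter. Returns the
    Mann-Whitney result together with the two group medians.
    """
    true_spans = np.asarray(true_spans, dtype=float)
    chimera_spans = np.asarray(chimera_spans, dtype=float)
    if true_spans.size == 0 or chimera_spans.size == 0:
        raise ValueError("both span groups must be nonempty")
    result = mann_whitney(true_spans, chimera_spans, alternative=alternative)
    return {
        "result": result,
        "median_true": float(np.median(true_spans)),
        "median_chimera": float(np.median(chimera_spans)),
    }
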