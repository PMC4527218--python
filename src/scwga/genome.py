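"""Genome layouts and interval arithmetic shared across the pipeline.

Coordinates are BED-style 0-based half-open everywhere except VCF-facing
genotype tables, which are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome layout must contain at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def is_autosome(self, chrom: str) -> bool:
        name = chrom.removeprefix("chr")
        return name.isdigit()

    @classmethod
    def example(cls, n_chromosomes: int = 5, scale: int = 100_000_000) -> "GenomeLayout":
        """Small synthetic layout with decreasing chromosome sizes."""
        lengths = {
            f"chr{i + 1}": int(scale * (1.0 - 0.12 * i))
            for i in range(n_chromosomes)
        }
        return cls(lengths)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals on one chromosome."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def total_length(intervals_by_chrom: dict[str, list[tuple[int, int]]]) -> int:
    return sum(
        e - s
        for ivs in intervals_by_chrom.values()
        for s, e in merge_intervals(ivs)
    )


def intersect_length(
    a: dict[str, list[tuple[int, int]]],
    b: dict[str, list[tuple[int, int]]],
) -> int:
    """Total overlap length (bp) between two interval sets keyed by chromosome."""
    out = 0
    for chrom in set(a) & set(b):
        ia = merge_intervals(a[chrom])
        ib = merge_intervals(b[chrom])
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                out += e - s
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    return out


def overlap_lengths(starts: np.ndarray, ends: np.ndarray, rs: int, re: int) -> np.ndarray:
    """Vectorized overlap length of each [start, end) with a single [rs, re)."""
    return np.clip(np.minimum(ends, re) - np.maximum(starts, rs), 0, None)
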