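"""Counts-per-million normalization and the locus-occupancy filter.

Counts are normalized by each sample's total library size only (no
trimmed-mean scaling): CPM[i, j] = counts[i, j] * 1e6 / library_size[j].
A locus is kept for a two-group comparison when, in each compared group, at
least ``n`` individuals show strictly more than ``cpm_threshold`` CPM, with
``n`` defaulting to the size of the smaller group in the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import CountMatrix, DataError, Locus, SampleInfo


@dataclass
class CpmMatrix:
    """Counts-per-million view of a :class:`CountMatrix` (same loci/sample order)."""

    loci: list[Locus]
    samples: list[SampleInfo]
    values: np.ndarray

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_index(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.group == group], dtype=int
        )


@dataclass
class FilterSpec:
    """Occupancy-filter parameters.

    cpm_threshold: CPM cut-off (kept samples must exceed it, strictly by default).
    n: explicit minimum number of passing individuals per group; ``None`` means
        use the size of the smallest compared group.
    inclusive: use ``>=`` instead of the default strict ``>`` (sensitivity analysis).
    """

    cpm_threshold: float = 1.0
    n: int | None = None
    inclusive: bool = False

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0:
            raise DataError("cpm_threshold must be > 0")
        if self.n is not None and self.n < 1:
            raise DataError("n must be >= 1")


def cpm_normalize(m: CountMatrix) -> CpmMatrix:
    """Normalize raw counts to counts per million by sample library size."""
    libs = m.library_sizes
    if np.any(libs <= 0):
        raise DataError("all library sizes must be positive")
    values = m.counts * (1e6 / libs[np.newaxis, :])
    return CpmMatrix(loci=list(m.loci), samples=list(m.samples), values=values)


def min_group_size(samples: Sequence[SampleInfo], groups: Sequence[str]) -> int:
    """Size of the smallest of the compared groups (the default filter ``n``)."""
    sizes = []
    for g in groups:
        size = sum(1 for s in samples if s.group == g)
        if size == 0:
            raise DataError(f"group {g!r} has no samples")
        sizes.append(size)
    return min(sizes)


def filter_loci(
    m: CountMatrix,
    spec: FilterSpec,
    groups: Sequence[str],
) -> CountMatrix:
    """Keep loci with > cpm_threshold CPM in at least ``n`` individuals of every compared group.

    ``groups`` is normally the pair of compared groups; passing all three
    group labels applies the filter jointly (used for the joint ordination).
    Locus order is preserved; the operation is idempotent.
    """
    groups = list(dict.fromkeys(groups))
    n = spec.n if spec.n is not None else min_group_size(m.samples, groups)
    cpm = cpm_normalize(m)
    keep = np.ones(len(m.loci), dtype=bool)
    for g in groups:
        idx = m.group_index(g)
        if len(idx) == 0:
            raise DataError(f"group {g!r} has no samples")
        if n > len(idx):
            raise DataError(
                f"filter n={n} exceeds the size of group {g!r} ({len(idx)} samples)"
            )
        vals = cpm.values[:, idx]
        passing = (vals >= spec.cpm_threshold) if spec.inclusive else (vals > spec.cpm_threshold)
        keep &= passing.sum(axis=1) >= n
    return m.subset_loci(keep)
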