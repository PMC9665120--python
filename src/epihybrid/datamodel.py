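"""Core containers for methylation-sensitive GBS (msGBS) count data.

msGBS digests genomic DNA with a methylation-sensitive restriction enzyme
(HpaII), so CpG methylation at a cut site blocks digestion and lowers the
read count observed at that locus.  The unit of observation is therefore a
cut-site locus (scaffold, 1-based position, strand), and the primary data
structure is a loci x samples matrix of non-negative integer read counts,
with per-sample library sizes used for counts-per-million normalization.
Reads are assumed to have been assigned per cut-site locus upstream (the
alignment and counting itself is outside this package's scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The three experimental groups: the two parental species and their F1 hybrids.
GROUPS = ("parent1", "parent2", "hybrid")

VALID_STRANDS = ("+", "-", ".")


class DataError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class Locus:
    """A restriction cut-site locus, identified by scaffold, 1-based position and strand."""

    scaffold: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"locus position must be >= 1, got {self.position}")
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold}:{self.position}:{self.strand}"


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced individual: group assignment, sampling site and total library size.

    ``library_size`` is the total number of mapped reads for the sample, which
    may exceed the column sum of any particular count matrix because loci are
    filtered after counting.
    """

    sample_id: str
    group: str
    site: str
    library_size: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {GROUPS}"
            )
        if self.library_size <= 0:
            raise DataError(
                f"library_size must be positive for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene on the reference assembly, 1-based inclusive coordinates."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"gene {self.gene_id!r}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Loci x samples matrix of non-negative integer msGBS read counts."""

    loci: list[Locus]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.loci), len(self.samples)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(np.equal(np.mod(as_int, 1), 0)):
                raise DataError("counts must be integers")
            self.counts = as_int.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise DataError("counts must be non-negative")
        _check_unique(self.locus_ids, "locus_id")
        _check_unique(self.sample_ids, "sample_id")
        col_sums = self.counts.sum(axis=0)
        for s, c in zip(self.samples, col_sums):
            if s.library_size < c:
                raise DataError(
                    f"sample {s.sample_id!r}: library_size {s.library_size} smaller "
                    f"than its column sum {c}"
                )

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def group_index(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = np.array([i for i, s in enumerate(self.samples) if s.group == group], dtype=int)
        return idx

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.samples:
            out[s.group] = out.get(s.group, 0) + 1
        return out

    def subset_loci(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to loci selected by a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s.sample_id: i for i, s in enumerate(self.samples)}
        try:
            idx = [pos[sid] for sid in sample_ids]
        except KeyError as e:
            raise DataError(f"unknown sample_id {e.args[0]!r}") from None
        return CountMatrix(
            loci=list(self.loci),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx],
        )


@dataclass
class GenotypeMatrix:
    """Markers x samples alt-allele dosage matrix; entries 0/1/2 or NaN for missing."""

    markers: list[str]
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.markers), len(self.samples)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise DataError(f"dosages must be in {{0, 1, 2}} or missing; got {bad}")
        _check_unique(self.markers, "marker")
        _check_unique(self.samples, "sample_id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape
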