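"""Genomic-context annotation of cut-site loci against a gene annotation.

Each locus is assigned exactly one category: *promoter* if it lies within a
fixed window (default 2 kb) upstream of a gene's strand-aware start,
*gene_body* if it lies within a gene's coordinates, *intergenic* otherwise,
and *unannotated* when its scaffold carries no annotation at all.  Categories
are mutually exclusive with precedence promoter > gene_body > intergenic, so
the four counts always partition the input; a dual-label mode reports
promoter and gene-body hits independently for loci near gene starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import DataError, GeneModel, Locus

CATEGORIES = ("promoter", "gene_body", "intergenic", "unannotated")


@dataclass
class ContextTable:
    n_promoter: int
    n_gene_body: int
    n_intergenic: int
    n_unannotated: int
    pct_promoter: float
    pct_gene_body: float
    pct_intergenic: float
    pct_unannotated: float

    @property
    def n_total(self) -> int:
        return self.n_promoter + self.n_gene_body + self.n_intergenic + self.n_unannotated


def _promoter_interval(g: GeneModel, window: int) -> tuple[int, int]:
    """1-based inclusive upstream window, excluding the gene body itself."""
    if g.strand == "+":
        return max(1, g.start - window), g.start - 1
    return g.end + 1, g.end + window


def annotate_context(
    loci: Sequence[Locus],
    genes: Sequence[GeneModel],
    annotated_scaffolds: Iterable[str] | None = None,
    promoter_window: int = 2000,
    dual_labels: bool = False,
) -> pd.DataFrame:
    """Assign each locus a context category (and the responsible gene, if any).

    ``annotated_scaffolds`` defaults to the scaffolds carrying at least one
    gene model; loci on other scaffolds are *unannotated*.  Ties between
    candidate genes are broken by distance to the gene start, then gene_id.
    Returns a DataFrame with columns locus_id, category, gene_id (and, with
    ``dual_labels=True``, boolean in_promoter / in_gene_body columns).
    """
    if promoter_window < 0:
        raise DataError("promoter_window must be >= 0")
    if annotated_scaffolds is None:
        annotated_scaffolds = {g.scaffold for g in genes}
    annotated = set(annotated_scaffolds)
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    rows = []
    for loc in loci:
        category, gene_id = "unannotated", None
        in_prom, in_body = False, False
        if loc.scaffold in annotated:
            prom_hits: list[tuple[int, str]] = []
            body_hits: list[tuple[int, str]] = []
            for g in by_scaffold.get(loc.scaffold, ()):
                tss = g.start if g.strand == "+" else g.end
                if promoter_window > 0:
                    lo, hi = _promoter_interval(g, promoter_window)
                    if lo <= loc.position <= hi:
                        prom_hits.append((abs(loc.position - tss), g.gene_id))
                if g.start <= loc.position <= g.end:
                    body_hits.append((abs(loc.position - tss), g.gene_id))
            in_prom, in_body = bool(prom_hits), bool(body_hits)
            if prom_hits:
                category, gene_id = "promoter", min(prom_hits)[1]
            elif body_hits:
                category, gene_id = "gene_body", min(body_hits)[1]
            else:
                category = "intergenic"
        row = {"locus_id": loc.locus_id, "category": category, "gene_id": gene_id}
        if dual_labels:
            row["in_promoter"] = in_prom
            row["in_gene_body"] = in_body
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate_context(annotations: pd.DataFrame) -> ContextTable:
    """Counts and percentages (2 decimals) of the four context categories."""
    if len(annotations) == 0:
        raise DataError("cannot tabulate an empty annotation set")
    n = len(annotations)
    counts = annotations["category"].value_counts()
    k = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    pct = {c: round(100.0 * k[c] / n, 2) for c in CATEGORIES}
    return ContextTable(
        n_promoter=k["promoter"],
        n_gene_body=k["gene_body"],
        n_intergenic=k["intergenic"],
        n_unannotated=k["unannotated"],
        pct_promoter=pct["promoter"],
        pct_gene_body=pct["gene_body"],
        pct_intergenic=pct["intergenic"],
        pct_unannotated=pct["unannotated"],
    )
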