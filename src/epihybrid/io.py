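"""Readers and writers for count matrices, sample sheets, gene annotations and genotypes.

All tabular formats are TSV with a header row.  The count-matrix dialect has
three leading columns (``scaffold``, ``position``, ``strand``) followed by
one column per sample.  Gene models come from GFF3 (``gene`` features only);
genotypes from a dosage TSV or a minimal VCF with GT calls.

Readers validate and raise :class:`~epihybrid.datamodel.DataError` on invalid
input rather than silently dropping rows; ``write_* . read_*`` round-trips are
identities on the supported dialects.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    DataError,
    GeneModel,
    GenotypeMatrix,
    Locus,
    SampleInfo,
)

_COORD_COLS = ["scaffold", "position", "strand"]


def read_sample_sheet(path: str | os.PathLike) -> list[SampleInfo]:
    """Read a sample sheet TSV with columns sample_id, group, site, library_size."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "site", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"sample sheet missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            lib = int(row.library_size)
        except ValueError:
            raise DataError(
                f"non-integer library_size {row.library_size!r} for sample {row.sample_id!r}"
            ) from None
        samples.append(
            SampleInfo(sample_id=row.sample_id, group=row.group, site=row.site, library_size=lib)
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sample_id in sample sheet")
    return samples


def read_count_matrix(
    path: str | os.PathLike,
    sample_sheet: str | os.PathLike,
    library_size_from_counts: bool = False,
) -> CountMatrix:
    """Read a cut-site count matrix TSV plus its sample sheet.

    Samples are ordered as in the sample sheet; loci as in the counts file.
    Library sizes come from the sheet (total mapped reads, which normalization
    uses even after loci are filtered); ``library_size_from_counts=True``
    falls back to column sums instead.
    """
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split("\t")
    if raw_header[:3] != _COORD_COLS:
        raise DataError(f"count matrix must start with columns {_COORD_COLS}")
    header_samples = raw_header[3:]
    if len(set(header_samples)) != len(header_samples):
        raise DataError("duplicate sample in count-matrix header")
    df = pd.read_csv(path, sep="\t")
    samples = read_sample_sheet(sample_sheet)
    sheet_ids = {s.sample_id for s in samples}
    unknown = [sid for sid in header_samples if sid not in sheet_ids]
    if unknown:
        raise DataError(f"samples in counts file absent from sample sheet: {unknown}")
    # keep only sheet samples present in the counts file, in sheet order
    samples = [s for s in samples if s.sample_id in set(header_samples)]

    loci = [
        Locus(scaffold=str(r.scaffold), position=int(r.position), strand=str(r.strand))
        for r in df[_COORD_COLS].itertuples(index=False)
    ]
    raw = df[[s.sample_id for s in samples]].to_numpy()
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.all(np.mod(arr, 1) == 0):
        raise DataError("counts must be finite integers")
    if arr.size and arr.min() < 0:
        raise DataError("counts must be non-negative")
    counts = arr.astype(np.int64)

    if library_size_from_counts:
        sums = counts.sum(axis=0)
        samples = [
            SampleInfo(s.sample_id, s.group, s.site, int(max(c, 1)))
            for s, c in zip(samples, sums)
        ]
    return CountMatrix(loci=loci, samples=samples, counts=counts)


def write_count_matrix(m: CountMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "scaffold": [l.scaffold for l in m.loci],
            "position": [l.position for l in m.loci],
            "strand": [l.strand for l in m.loci],
        }
    )
    for j, s in enumerate(m.samples):
        df[s.sample_id] = m.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "site": [s.site for s in samples],
            "library_size": [s.library_size for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    if Path(path).stat().st_size == 0:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.id or feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}"])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                scaffold=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3 ``gene`` rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tepihybrid\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a genotype matrix: dosage TSV (marker_id + one column per sample) or VCF.

    VCF GT fields are converted to alt-allele dosages (0/1 -> 1, 1/1 -> 2,
    ./. -> missing); missing entries are flagged as NaN, never imputed.
    """
    p = Path(path)
    if p.suffix.lower() == ".vcf" or p.name.lower().endswith(".vcf.gz"):
        return _read_genotypes_vcf(p)
    df = pd.read_csv(p, sep="\t")
    if df.columns[0] != "marker_id":
        raise DataError("dosage TSV must have a leading marker_id column")
    markers = df["marker_id"].astype(str).tolist()
    samples = list(df.columns[1:])
    dosages = df[samples].to_numpy(dtype=float)
    finite = dosages[np.isfinite(dosages)]
    if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
        raise DataError("dosage TSV entries must be 0, 1, 2 or missing (NA)")
    return GenotypeMatrix(markers=markers, samples=samples, dosages=dosages)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_of = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        markers.append(f"{var.CHROM}:{var.POS}")
        rows.append(dosage_of[var.gt_types])
    vcf.close()
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(markers=markers, samples=samples, dosages=dosages)


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(g.dosages, columns=g.samples)
    df.insert(0, "marker_id", g.markers)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
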