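"""Synthetic msGBS experiment generator with known ground truth.

The generator emulates the structure of a methylation-sensitive GBS dataset
from two parental species and their F1 hybrids.  Methylation is represented
directly on the expected-count scale: methylation at a cut site blocks
digestion, so a locus's expected CPM is proportional to its accessibility,
and a species-divergent methylation difference appears as a log2 fold change
of expected CPM between species.  Hybrid expectations follow the simulated
inheritance mode on the log2 scale: additive loci sit at the parental
log-mean (geometric mid-point, hence inside the parental interval on the CPM
scale), over-/under-dominant loci lie beyond the higher/lower parent by a
fixed transgressive shift.  Counts are negative-binomial around
CPM x library_size / 1e6 with a common dispersion; library sizes are
log-normal.  Species-diagnostic SNP dosages (0 vs 2, hybrids 1, in both
orientations relative to the reference) plus non-diagnostic markers give the
genotype matrix, and gene models tile a subset of scaffolds so every context
category is populated.

Default group sizes (22 / 17 / 5) mirror a natural-hybrid design with two
sympatric parental populations and few F1s.  One global seed drives
independent sub-streams for counts, library sizes, genotypes and gene
placement, so changing e.g. ``n_markers`` does not perturb the counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

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

_SITES = ("GUA", "FUN")


@dataclass
class SimulationParams:
    n_loci: int = 2000
    n_p1: int = 22
    n_p2: int = 17
    n_hybrid: int = 5
    frac_divergent: float = 0.05
    inheritance_mix: tuple[float, float, float] = (0.9, 0.06, 0.04)
    effect_log2fc: float = 3.0
    transgressive_log2fc: float = 2.0
    dispersion: float = 0.3
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.3
    baseline_cpm_log_mean: float = float(np.log(30.0))
    baseline_cpm_log_sd: float = 1.0
    n_markers: int = 200
    frac_diagnostic_markers: float = 0.8
    genotype_missing_rate: float = 0.02
    n_scaffolds: int = 10
    frac_annotated_scaffolds: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.inheritance_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise DataError("inheritance_mix must be 3 non-negative probabilities summing to 1")
        if not 0.0 <= self.frac_divergent <= 1.0:
            raise DataError("frac_divergent must be in [0, 1]")
        for name in ("effect_log2fc", "transgressive_log2fc"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment: per-locus means/modes, per-sample metadata."""

    loci: pd.DataFrame  # locus_id, true_cpm_p1, true_cpm_p2, true_cpm_hybrid, divergent, mode
    samples: pd.DataFrame  # sample_id, group, site, library_size
    params: SimulationParams
    seed: int


class SimulatedExperiment(NamedTuple):
    counts: CountMatrix
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    truth: SyntheticTruth


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # NB as gamma-mixed Poisson
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_experiment(params: SimulationParams) -> SimulatedExperiment:
    """Draw one full synthetic experiment (counts, genotypes, genes, truth)."""
    ss = np.random.SeedSequence(params.seed)
    rng_counts, rng_libs, rng_geno, rng_genes = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_samples = params.n_p1 + params.n_p2 + params.n_hybrid
    groups = (
        ["parent1"] * params.n_p1 + ["parent2"] * params.n_p2 + ["hybrid"] * params.n_hybrid
    )
    sample_ids = []
    counters: dict[str, int] = {}
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        sample_ids.append(f"{g}_{counters[g]:02d}")
    sites = [_SITES[i % 2] for i in range(n_samples)]

    # per-locus baseline accessibility (expected CPM), long-tailed
    log2_base = (
        rng_counts.normal(params.baseline_cpm_log_mean, params.baseline_cpm_log_sd, params.n_loci)
        / np.log(2)
    )
    divergent = rng_counts.random(params.n_loci) < params.frac_divergent
    mode = np.full(params.n_loci, "", dtype=object)
    mode[divergent] = rng_counts.choice(
        ["additive", "overdominant", "underdominant"],
        size=int(divergent.sum()),
        p=np.asarray(params.inheritance_mix, dtype=float),
    )
    # species 2 shifts up or down by the full effect at divergent loci
    sign = rng_counts.choice([-1.0, 1.0], size=params.n_loci)
    l2_p1 = log2_base.copy()
    l2_p2 = log2_base + np.where(divergent, sign * params.effect_log2fc, 0.0)
    l2_mid = (l2_p1 + l2_p2) / 2
    l2_hyb = l2_mid.copy()
    over = mode == "overdominant"
    under = mode == "underdominant"
    l2_hyb[over] = np.maximum(l2_p1, l2_p2)[over] + params.transgressive_log2fc
    l2_hyb[under] = np.minimum(l2_p1, l2_p2)[under] - params.transgressive_log2fc

    cpm_by_group = {
        "parent1": 2.0**l2_p1,
        "parent2": 2.0**l2_p2,
        "hybrid": 2.0**l2_hyb,
    }
    libs = np.maximum(
        _lognormal(rng_libs, params.library_size_mean, params.library_size_cv, n_samples),
        1e4,
    )
    counts = np.empty((params.n_loci, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean = cpm_by_group[groups[j]] * libs[j] / 1e6
        counts[:, j] = _nb_counts(rng_counts, mean, params.dispersion)
    col_sums = counts.sum(axis=0)
    lib_final = np.maximum(np.round(libs).astype(np.int64), col_sums)

    samples = [
        SampleInfo(sample_id=sid, group=g, site=site, library_size=int(lib))
        for sid, g, site, lib in zip(sample_ids, groups, sites, lib_final)
    ]

    # loci laid out in consecutive blocks over scaffolds, 400 bp apart
    per_scaffold = int(np.ceil(params.n_loci / params.n_scaffolds))
    loci = []
    for i in range(params.n_loci):
        s = i // per_scaffold
        k = i % per_scaffold
        loci.append(Locus(scaffold=f"scaffold_{s + 1}", position=1000 + 400 * k, strand="+"))
    count_matrix = CountMatrix(loci=loci, samples=samples, counts=counts)

    genotypes = _simulate_genotypes(rng_geno, params, sample_ids, groups)
    genes = _simulate_genes(rng_genes, params, loci)

    truth = SyntheticTruth(
        loci=pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in loci],
                "true_cpm_p1": cpm_by_group["parent1"],
                "true_cpm_p2": cpm_by_group["parent2"],
                "true_cpm_hybrid": cpm_by_group["hybrid"],
                "divergent": divergent,
                "mode": mode,
            }
        ),
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "site": sites,
                "library_size": lib_final,
            }
        ),
        params=params,
        seed=params.seed,
    )
    return SimulatedExperiment(count_matrix, genotypes, genes, truth)


def _simulate_genotypes(
    rng: np.random.Generator,
    params: SimulationParams,
    sample_ids: list[str],
    groups: list[str],
) -> GenotypeMatrix:
    n = len(sample_ids)
    m = params.n_markers
    n_diag = int(round(m * params.frac_diagnostic_markers))
    dos = np.empty((m, n))
    group_arr = np.asarray(groups)
    for i in range(m):
        if i < n_diag:
            # fixed difference; orientation relative to the reference alternates
            p1_allele = 0.0 if i % 2 == 0 else 2.0
            p2_allele = 2.0 - p1_allele
            row = np.where(
                group_arr == "parent1",
                p1_allele,
                np.where(group_arr == "parent2", p2_allele, 1.0),
            )
        else:
            row = rng.binomial(2, 0.3, size=n).astype(float)
        dos[i] = row
    miss = rng.random((m, n)) < params.genotype_missing_rate
    dos[miss] = np.nan
    markers = [f"snp_{i + 1:04d}" for i in range(m)]
    return GenotypeMatrix(markers=markers, samples=list(sample_ids), dosages=dos)


def _simulate_genes(
    rng: np.random.Generator, params: SimulationParams, loci: list[Locus]
) -> list[GeneModel]:
    scaffolds = sorted({l.scaffold for l in loci}, key=lambda s: int(s.split("_")[1]))
    n_annot = max(1, int(round(len(scaffolds) * params.frac_annotated_scaffolds)))
    max_pos: dict[str, int] = {}
    for l in loci:
        max_pos[l.scaffold] = max(max_pos.get(l.scaffold, 0), l.position)
    genes: list[GeneModel] = []
    gid = 0
    for s in scaffolds[:n_annot]:
        pos = 3000
        while pos + 3000 <= max_pos[s] + 5000:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:04d}",
                    scaffold=s,
                    start=pos,
                    end=pos + 2999,
                    strand=strand,
                )
            )
            pos += 10000
    return genes


def export_fixture(dataset: SimulatedExperiment, directory: str | os.PathLike) -> dict[str, str]:
    """Write a simulated experiment as TSV/GFF3 files consumable by the readers and CLI.

    Returns a name -> path map for counts, samples, genes, genotypes and truth.
    """
    from . import io as eio

    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.tsv"),
        "samples": os.path.join(directory, "samples.tsv"),
        "genes": os.path.join(directory, "genes.gff3"),
        "genotypes": os.path.join(directory, "genotypes.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    eio.write_count_matrix(dataset.counts, paths["counts"])
    eio.write_sample_sheet(dataset.counts.samples, paths["samples"])
    eio.write_gene_models(dataset.genes, paths["genes"])
    eio.write_genotypes(dataset.genotypes, paths["genotypes"])
    dataset.truth.loci.to_csv(paths["truth"], sep="\t", index=False)
    return paths
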