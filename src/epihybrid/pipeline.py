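"""End-to-end orchestration: counts -> DMCs -> inheritance -> context -> distances.

``run_pipeline`` executes nine stages in the analysis order: data loading (or
simulation), the three two-group DMC comparisons (parent1 vs parent2, hybrid
vs each parent), intersection of the hybrid comparisons into the common DMC
set, inheritance classification (of the parental DMC set and of the common
set, plus profile clustering), genomic-context tabulation of the common set,
ordination (classical MDS of parental-DMC profiles and of all jointly
filtered loci), and the genome-methylome association (Bray-Curtis distances,
Mantel test, pairwise mixed model).  All stage outputs are TSV/Newick files
in the output directory plus a JSON-lines manifest; given the same config
and seed, stage outputs are byte-identical between runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import CountMatrix, DataError, GenotypeMatrix
from .dmc import call_dmcs, intersect_dmcs
from .normalize import FilterSpec, cpm_normalize, filter_loci, min_group_size
from .inheritance import (
    classify_inheritance,
    hierarchical_cluster,
    linkage_to_newick,
    scale_profiles,
    summarize_inheritance,
)
from .context import annotate_context, tabulate_context
from .distances import (
    bray_curtis_distances,
    classical_mds,
    euclidean_distances,
    fit_pairwise_mixed_model,
    mantel_test,
)
from .simulate import SimulationParams, simulate_experiment, export_fixture
from . import io as eio

STAGES = (
    "load",
    "dmc_parent1_vs_parent2",
    "dmc_hybrid_vs_parent1",
    "dmc_hybrid_vs_parent2",
    "common_dmcs",
    "inheritance",
    "context",
    "ordination",
    "association",
)


@dataclass
class PipelineConfig:
    """Inputs and tuning parameters of a full run.

    Leave the input paths unset to run on a freshly simulated dataset
    (``n_loci`` loci, simulator defaults otherwise).
    """

    out_dir: str = "epihybrid_out"
    counts: str | None = None
    samples: str | None = None
    gff: str | None = None
    genotypes: str | None = None
    fdr_threshold: float = 0.01
    cpm_threshold: float = 1.0
    promoter_window: int = 2000
    n_permutations: int = 999
    seed: int = 0
    n_loci: int = 500  # simulated dataset size when no inputs are given
    mds_axes: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise DataError("fdr_threshold must be in (0, 1]")
        if self.cpm_threshold <= 0:
            raise DataError("cpm_threshold must be > 0")
        if self.promoter_window < 0:
            raise DataError("promoter_window must be >= 0")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as manifest.jsonl)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, rows_in: int, rows_out: int, **extra) -> None:
        manifest.append(
            {
                "stage": stage,
                "rows_in": int(rows_in),
                "rows_out": int(rows_out),
                "seed": config.seed,
                "version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                **extra,
            }
        )

    try:
        result = _run_stages(config, out, record)
    except Exception as err:
        stage = STAGES[len(manifest)] if len(manifest) < len(STAGES) else "report"
        _write_manifest(manifest, out)
        raise DataError(f"pipeline failed at stage {stage!r}: {err}") from err
    _write_manifest(manifest, out)
    return {"stages": manifest, **result}


def _write_manifest(manifest: list[dict], out: Path) -> None:
    with open(out / "manifest.jsonl", "w") as fh:
        for entry in manifest:
            fh.write(json.dumps(entry) + "\n")


def _run_stages(config: PipelineConfig, out: Path, record) -> dict:
    # --- load -----------------------------------------------------------
    genotypes: GenotypeMatrix | None = None
    if config.counts is not None:
        if config.samples is None:
            raise DataError("a sample sheet is required alongside the count matrix")
        m = eio.read_count_matrix(config.counts, config.samples)
        genes = eio.read_gene_models(config.gff) if config.gff else []
        if config.genotypes:
            genotypes = eio.read_genotypes(config.genotypes)
    else:
        sim = simulate_experiment(SimulationParams(n_loci=config.n_loci, seed=config.seed))
        export_fixture(sim, out / "simulated_input")
        m, genotypes, genes = sim.counts, sim.genotypes, sim.genes
    record("load", len(m.loci), len(m.loci), n_samples=len(m.samples))

    spec = FilterSpec(cpm_threshold=config.cpm_threshold)

    # --- three DMC comparisons (per-comparison filtering) ---------------
    comparisons = [
        ("parent1", "parent2"),
        ("hybrid", "parent1"),
        ("hybrid", "parent2"),
    ]
    dmc_sets = {}
    for focal, ref in comparisons:
        ds = call_dmcs(
            m, focal, ref, fdr_threshold=config.fdr_threshold, filter_spec=spec
        )
        dmc_sets[(focal, ref)] = ds
        _write_tsv(ds.results, out / f"dmc_{focal}_vs_{ref}.tsv")
        record(
            f"dmc_{focal}_vs_{ref}",
            len(m.loci),
            len(ds.results),
            n_significant=int(ds.results["significant"].sum()),
        )

    parental_dmcs = dmc_sets[("parent1", "parent2")].significant_loci

    # --- common DMCs ----------------------------------------------------
    common = intersect_dmcs(
        dmc_sets[("hybrid", "parent1")], dmc_sets[("hybrid", "parent2")]
    )
    pd.DataFrame({"locus_id": common}).to_csv(out / "common_dmcs.tsv", sep="\t", index=False)
    record("common_dmcs", len(dmc_sets[("hybrid", "parent1")].results), len(common))

    # --- inheritance ----------------------------------------------------
    cpm = cpm_normalize(m)
    summaries = {}
    for name, locus_set in (("parental_dmcs", parental_dmcs), ("common_dmcs", common)):
        if locus_set:
            calls = classify_inheritance(cpm, locus_set)
            _write_tsv(calls, out / f"inheritance_{name}.tsv")
            summaries[name] = summarize_inheritance(calls)
        else:
            summaries[name] = None
    cluster_set = common if common else parental_dmcs
    if cluster_set and len(m.samples) >= 2:
        scaled = scale_profiles(cpm, cluster_set)
        link = hierarchical_cluster(scaled)
        (out / "dendrogram.nwk").write_text(
            linkage_to_newick(link, m.sample_ids) + "\n"
        )
    record("inheritance", len(parental_dmcs) + len(common), len(parental_dmcs) + len(common))

    # --- genomic context ------------------------------------------------
    context_table = None
    context_set = common if common else parental_dmcs
    if context_set and genes:
        by_id = {l.locus_id: l for l in m.loci}
        ann = annotate_context(
            [by_id[lid] for lid in context_set], genes, promoter_window=config.promoter_window
        )
        _write_tsv(ann, out / "context.tsv")
        context_table = tabulate_context(ann)
    record("context", len(context_set), len(context_set))

    # --- ordination -----------------------------------------------------
    n_mds = 0
    if parental_dmcs:
        pos = {lid: i for i, lid in enumerate(cpm.locus_ids)}
        x = cpm.values[[pos[lid] for lid in parental_dmcs], :].T
        mds = classical_mds(euclidean_distances(x, m.sample_ids), k=config.mds_axes)
        _write_mds(mds, m, out / "mds_parental_dmcs.tsv")
        n_mds += 1
    joint = filter_loci(m, spec, ("parent1", "parent2", "hybrid"))
    if len(joint.loci):
        mds_all = classical_mds(
            euclidean_distances(cpm_normalize(joint).values.T, m.sample_ids),
            k=config.mds_axes,
        )
        _write_mds(mds_all, m, out / "mds_all_loci.tsv")
        n_mds += 1
    record("ordination", len(m.loci), n_mds)

    # --- genome-methylome association -----------------------------------
    mantel = None
    mlpe = None
    if genotypes is not None and len(m.samples) >= 4:
        shared = [s for s in m.sample_ids if s in set(genotypes.samples)]
        gpos = {s: i for i, s in enumerate(genotypes.samples)}
        dos = genotypes.dosages[:, [gpos[s] for s in shared]].T
        gen_d = bray_curtis_distances(dos, shared, pairwise_deletion=True)
        msub = m.subset_samples(shared)
        epi_set = common if common else parental_dmcs
        cpm_sub = cpm_normalize(msub)
        if epi_set:
            pos = {lid: i for i, lid in enumerate(cpm_sub.locus_ids)}
            x = cpm_sub.values[[pos[lid] for lid in epi_set], :].T
        else:
            x = cpm_sub.values.T
        epi_d = bray_curtis_distances(x, shared)
        mantel = mantel_test(
            epi_d, gen_d, n_permutations=config.n_permutations, seed=config.seed
        )
        try:
            mlpe = fit_pairwise_mixed_model(epi_d, gen_d, msub.samples)
        except DataError:
            mlpe = None
    record("association", len(m.samples), 1 if mantel else 0)

    # --- report ----------------------------------------------------------
    report = _report(summaries, context_table, mantel, mlpe, dmc_sets, common)
    _write_tsv(report, out / "report.tsv")
    return {
        "report": report,
        "summaries": summaries,
        "context": context_table,
        "mantel": mantel,
        "mlpe": mlpe,
        "common_dmcs": common,
        "dmc_sets": dmc_sets,
    }


def _write_mds(mds, m: CountMatrix, path: Path) -> None:
    df = pd.DataFrame(
        mds.coordinates,
        columns=[f"axis{i + 1}" for i in range(mds.coordinates.shape[1])],
    )
    df.insert(0, "sample_id", mds.sample_ids)
    df["group"] = [s.group for s in m.samples]
    _write_tsv(df, path)


def _report(summaries, context_table, mantel, mlpe, dmc_sets, common) -> pd.DataFrame:
    rows = []

    def add(name, value):
        rows.append({"quantity": name, "value": value})

    for (focal, ref), ds in dmc_sets.items():
        add(f"n_dmcs_{focal}_vs_{ref}", int(ds.results["significant"].sum()))
    add("n_common_dmcs", len(common))
    sp = summaries.get("parental_dmcs")
    if sp:
        add("pct_additive_parental_dmcs", sp.pct_additive)
        add("n_nonadditive_parental_dmcs", sp.n_nonadditive)
    sc = summaries.get("common_dmcs")
    if sc:
        add("pct_additive_common_dmcs", sc.pct_additive)
        add("pct_nonadditive_common_dmcs", sc.pct_nonadditive)
        add("n_overdominant_common_dmcs", sc.n_overdominant)
        add("n_underdominant_common_dmcs", sc.n_underdominant)
    if context_table:
        for cat in ("promoter", "gene_body", "intergenic", "unannotated"):
            add(f"n_context_{cat}", getattr(context_table, f"n_{cat}"))
            add(f"pct_context_{cat}", getattr(context_table, f"pct_{cat}"))
    if mantel:
        add("mantel_r", round(mantel.r, 6))
        add("mantel_p", mantel.p_value)
    if mlpe:
        add("mlpe_slope_genetic_distance", round(mlpe.coefficients.get("gen", float("nan")), 6))
        add("mlpe_delta_aic_random_effects", round(mlpe.delta_aic, 3))
    # object dtype keeps ints as ints in the mixed-type value column
    return pd.DataFrame(
        {
            "quantity": [r["quantity"] for r in rows],
            "value": pd.Series([r["value"] for r in rows], dtype=object),
        }
    )
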