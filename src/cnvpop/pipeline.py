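"""End-to-end pipeline orchestration: simulate -> call -> merge -> scan -> annotate.

A run is driven by a :class:`PipelineConfig` (loadable from YAML) and a
mandatory seed; every stage writes plain-text outputs into the run
directory and records row counts in a JSON manifest, so that two runs
with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .annotate import load_genes, overlap_genes, population_gene_sets
from .calling import call_sample, normalize_depth
from .fst import carrier_frequencies, encode_genotypes, one_vs_rest_scan, select_outliers
from .genome import GenomeModel
from .regions import (
    METAPOPULATION,
    chrom_count_regression,
    compare_population_sets,
    coverage_fraction,
    merge_calls,
    summarize_cnvs,
)
from .simulate import (
    DEFAULT_MEAN_DEPTH,
    default_design,
    default_genome,
    sample_genotypes,
    simulate_depth,
    simulate_genes,
    write_depth_tsv,
    write_gff3,
    write_samples_tsv,
    write_truth_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the stated defaults."""

    # simulation
    mean_depth: float = DEFAULT_MEAN_DEPTH
    bin_size: int = 400
    n_background_loci: int = 510
    n_differentiated_per_pop: int = 1
    gc_bias: bool = False
    n_genes: int = 300
    # calling
    gap_bins: int = 1
    p_value_max: float = 0.01
    min_call_length: int = 1_000
    del_rd_max: float = 0.7
    dup_rd_min: float = 1.3
    # cnvr
    min_support: int = 2
    # fst
    top_fraction: float = 0.05
    hom_del_rd: float = 0.25
    hom_dup_rd: float = 1.75
    # annotation
    min_gene_fraction: float = 0.5
    gene_fraction_of: str = "gene"
    # reproducibility
    seed: int = 1

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not 0 < self.p_value_max <= 1:
            raise ValueError("p_value_max must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.min_gene_fraction <= 1:
            raise ValueError("min_gene_fraction must be in [0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path, rows: int) -> None:
        self.stages.setdefault(stage, []).append(
            {"path": str(path), "rows": int(rows)}
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "version": self.version, "stages": self.stages},
                fh, indent=2,
            )
            fh.write("\n")


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, genome: GenomeModel | None = None
) -> dict:
    """Run every stage on a fresh simulation; returns in-memory results.

    Writes: truth BED, depth TSV, sample TSV, GFF3, per-sample call BED,
    per-scope CNVR BED, genotype VCF, per-contrast F_ST TSV, annotation
    TSV, summary report TSV/JSON and the run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    t0 = time.time()

    # --- simulate -----------------------------------------------------
    genome, design = default_design(
        genome=genome or default_genome(bin_size=config.bin_size),
        n_background=config.n_background_loci,
        n_differentiated_per_pop=config.n_differentiated_per_pop,
        seed=config.seed,
    )
    truth = sample_genotypes(design, seed=config.seed + 1)
    profiles, gc = simulate_depth(
        genome, truth, mean_depth=config.mean_depth, gc_bias=config.gc_bias,
        seed=config.seed + 2,
    )
    genes = simulate_genes(genome, config.n_genes, seed=config.seed + 3)

    write_truth_bed(truth, outdir / "truth.bed")
    write_depth_tsv(genome, profiles, outdir / "depth.tsv")
    write_samples_tsv(design, outdir / "samples.tsv")
    write_gff3(genes, genome, outdir / "genes.gff3")
    manifest.record("simulate", outdir / "truth.bed", len(truth.loci))
    manifest.record("simulate", outdir / "depth.tsv", genome.total_bins)
    logger.info("simulate: %d loci, %d samples (%.1fs)",
                len(truth.loci), len(profiles), time.time() - t0)

    # --- call ---------------------------------------------------------
    t0 = time.time()
    sample_pops = dict(
        zip(design.sample_table["sample"], design.sample_table["population"])
    )
    norms = {}
    calls_by_sample = {}
    for prof in profiles:
        norm = normalize_depth(prof, gc_track=gc)
        norms[prof.sample] = norm
        calls_by_sample[prof.sample] = call_sample(
            norm, genome, gap_bins=config.gap_bins, p_max=config.p_value_max,
            min_length=config.min_call_length, del_rd_max=config.del_rd_max,
            dup_rd_min=config.dup_rd_min,
        )
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    io.write_calls_bed(all_calls, outdir / "cnv_calls.bed")
    manifest.record("call", outdir / "cnv_calls.bed", len(all_calls))
    logger.info("call: %d calls (%.1fs)", len(all_calls), time.time() - t0)

    # --- merge --------------------------------------------------------
    t0 = time.time()
    pop_sets = {}
    for pop, _ in design.populations:
        pop_calls = [c for c in all_calls if sample_pops[c.sample] == pop]
        pop_sets[pop] = merge_calls(
            pop_calls, genome, scope=pop, min_support=config.min_support
        )
        io.write_cnvrs_bed(pop_sets[pop], outdir / f"cnvrs_{pop}.bed")
        manifest.record("merge", outdir / f"cnvrs_{pop}.bed", len(pop_sets[pop]))
    meta_set = merge_calls(
        all_calls, genome, scope=METAPOPULATION, min_support=config.min_support
    )
    io.write_cnvrs_bed(meta_set, outdir / "cnvrs_metapopulation.bed")
    manifest.record("merge", outdir / "cnvrs_metapopulation.bed", len(meta_set))
    sharing = compare_population_sets(meta_set, pop_sets)
    sharing.to_csv(outdir / "cnvr_sharing.tsv", sep="\t", index=False)
    logger.info("merge: %d metapopulation CNVRs (%.1fs)", len(meta_set), time.time() - t0)

    # --- fst ----------------------------------------------------------
    t0 = time.time()
    matrix = encode_genotypes(
        meta_set, calls_by_sample, norms, sample_pops, genome,
        hom_del_rd=config.hom_del_rd, hom_dup_rd=config.hom_dup_rd,
    )
    io.write_vcf(matrix, genome, outdir / "genotypes.vcf")
    tables = one_vs_rest_scan(matrix)
    flagged = {}
    for pop, table in tables.items():
        flagged[pop] = select_outliers(table, top_fraction=config.top_fraction)
        io.write_fst_tsv(flagged[pop], outdir / f"fst_{pop}_vs_rest.tsv")
        manifest.record("fst", outdir / f"fst_{pop}_vs_rest.tsv", len(flagged[pop]))
    logger.info("fst: %d contrasts x %d loci (%.1fs)",
                len(tables), len(matrix.loci), time.time() - t0)

    # --- annotate -----------------------------------------------------
    t0 = time.time()
    gene_models = load_genes(outdir / "genes.gff3")
    assoc_by_pop = {
        pop: overlap_genes(
            pop_sets[pop], gene_models,
            min_gene_fraction=config.min_gene_fraction,
            fraction_of=config.gene_fraction_of,
        )
        for pop in pop_sets
    }
    meta_assoc = overlap_genes(
        meta_set, gene_models, min_gene_fraction=config.min_gene_fraction,
        fraction_of=config.gene_fraction_of,
    )
    meta_assoc.to_csv(outdir / "cnvr_gene_associations.tsv", sep="\t", index=False)
    manifest.record("annotate", outdir / "cnvr_gene_associations.tsv", len(meta_assoc))
    gene_partition = population_gene_sets(assoc_by_pop)
    for key, gene_ids in sorted(gene_partition.items()):
        fname = outdir / f"genes_{key.replace(':', '_').replace(',', '-')}.txt"
        fname.write_text("\n".join(sorted(gene_ids)) + "\n")
    logger.info("annotate: %d associations (%.1fs)", len(meta_assoc), time.time() - t0)

    results = {
        "genome": genome,
        "design": design,
        "truth": truth,
        "norms": norms,
        "calls_by_sample": calls_by_sample,
        "population_sets": pop_sets,
        "metapopulation_set": meta_set,
        "sharing": sharing,
        "matrix": matrix,
        "fst_tables": flagged,
        "associations": assoc_by_pop,
        "gene_partition": gene_partition,
    }
    report(results, config, outdir, manifest)
    manifest.write(outdir / "manifest.json")
    return results


def report(results: dict, config: PipelineConfig, outdir: Path, manifest: RunManifest) -> dict:
    """Summary document: counts, coverage, regression, outlier/carrier tables."""
    outdir = Path(outdir)
    genome: GenomeModel = results["genome"]
    all_calls = [c for calls in results["calls_by_sample"].values() for c in calls]
    summary = summarize_cnvs(all_calls)
    meta_set = results["metapopulation_set"]
    slope, intercept, r2 = (
        chrom_count_regression(meta_set, genome)
        if len(genome.names) >= 3
        else (float("nan"),) * 3
    )
    doc = {
        "n_samples": len(results["calls_by_sample"]),
        "n_populations": len(results["population_sets"]),
        "cnv_summary": summary,
        "cnvr_counts": {
            scope: len(s)
            for scope, s in {**results["population_sets"],
                             METAPOPULATION: meta_set}.items()
        },
        "genome_coverage_fraction": coverage_fraction(meta_set, genome),
        "chrom_count_regression": {"slope": slope, "intercept": intercept, "r2": r2},
        "outliers_per_contrast": {
            pop: int(t["outlier"].sum()) for pop, t in results["fst_tables"].items()
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")

    # carrier-frequency tables for flagged loci (top of each contrast)
    rows = []
    for pop, table in results["fst_tables"].items():
        top = table[table["outlier"]].nlargest(5, "theta")
        for locus_id in top["locus_id"]:
            freqs = carrier_frequencies(results["matrix"], locus_id)
            for rec in freqs.itertuples():
                rows.append(
                    {"contrast": f"{pop}_vs_rest", "locus_id": locus_id,
                     "population": rec.population,
                     "carrier_frequency": rec.carrier_frequency}
                )
    pd.DataFrame(rows, columns=["contrast", "locus_id", "population",
                                "carrier_frequency"]).to_csv(
        outdir / "outlier_carrier_frequencies.tsv", sep="\t", index=False,
        float_format="%.4f",
    )
    manifest.record("report", outdir / "report.json", 1)
    return doc
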