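"""Synthetic multi-population CNV data with known truth.

Emulates a three-population, ten-samples-each whole-genome resequencing
design at ~22.65x mean depth: planted deletion/duplication loci with
population-specific carrier-allele frequencies, per-sample diploid
genotypes drawn binomially, and per-bin read counts drawn Poisson around
the expected number of reads in the bin,

    lambda = mean_depth * (bin_size / read_unit) * copy_ratio,

where ``read_unit`` (default 100 bp) is the effective read length that
converts base coverage into a read count.  Depth is otherwise modeled
directly as expected per-bin coverage; there is no read-level
bookkeeping beyond this scaling.

Copy ratio inside a planted locus is (total copies)/2: heterozygous
deletion 0.5, homozygous deletion 0.0, heterozygous duplication 1.5,
homozygous duplication 2.0 (one extra copy per variant allele); 1.0
elsewhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, build_genome

DEFAULT_MEAN_DEPTH = 22.65
DEFAULT_READ_UNIT = 100  # bp of sequence per counted read
DEFAULT_POPULATIONS = (("JD", 10), ("SX", 10), ("SM", 10))
# DEL:DUP mix of planted background loci; deletions predominate in
# read-depth call sets.
DEFAULT_DEL_FRACTION = 0.64


@dataclass(frozen=True)
class PlantedLocus:
    """A CNV locus planted in the simulated population."""

    chrom: str
    start: int  # 1-based closed, bin-aligned
    end: int
    cnv_type: str  # "DEL" | "DUP"
    allele_frequency: dict[str, float]  # per population, carrier allele
    locus_id: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("locus end < start")
        if self.cnv_type not in ("DEL", "DUP"):
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type}")
        for pop, f in self.allele_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {pop} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def copy_ratio(self, n_variant_alleles: int) -> float:
        """Depth ratio relative to diploid for 0/1/2 variant alleles."""
        if self.cnv_type == "DEL":
            return (2 - n_variant_alleles) / 2.0
        return (2 + n_variant_alleles) / 2.0


@dataclass(frozen=True)
class PopulationDesign:
    populations: tuple[tuple[str, int], ...]
    loci: tuple[PlantedLocus, ...]

    def __post_init__(self):
        names = [p for p, _ in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for _, n in self.populations:
            if n < 1:
                raise ValueError("each population needs >= 1 sample")

    @property
    def sample_table(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{pop}_{i + 1:02d}", "population": pop}
            for pop, n in self.populations
            for i in range(n)
        ]
        return pd.DataFrame(rows)


@dataclass
class TruthTable:
    """Planted loci and the per-sample variant-allele counts drawn for them."""

    design: PopulationDesign
    genotypes: pd.DataFrame  # rows = loci (locus_id index), columns = samples, values 0/1/2

    @property
    def loci(self) -> tuple[PlantedLocus, ...]:
        return self.design.loci

    def locus(self, locus_id: str) -> PlantedLocus:
        for loc in self.design.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)


@dataclass
class DepthProfile:
    """Raw per-bin read counts for one sample."""

    sample: str
    counts: dict[str, np.ndarray]  # chrom -> per-bin counts
    mean_depth: float

    def __post_init__(self):
        for chrom, arr in self.counts.items():
            if (arr < 0).any():
                raise ValueError(f"negative counts on {chrom}")


def sample_genotypes(design: PopulationDesign, seed: int) -> TruthTable:
    """Draw per-sample diploid genotypes at every planted locus.

    The variant-allele count of a sample is binomial(2, f) where f is the
    carrier-allele frequency of that sample's population at the locus.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    samples = design.sample_table
    data = np.zeros((len(design.loci), len(samples)), dtype=np.int8)
    for i, locus in enumerate(design.loci):
        for j, (sample, pop) in enumerate(zip(samples["sample"], samples["population"])):
            f = locus.allele_frequency.get(pop, 0.0)
            data[i, j] = rng.binomial(2, f)
    ids = [loc.locus_id or f"locus_{i + 1}" for i, loc in enumerate(design.loci)]
    gt = pd.DataFrame(data, index=ids, columns=list(samples["sample"]))
    return TruthTable(design=design, genotypes=gt)


def _gc_multiplier(genome: GenomeModel, seed: int) -> dict[str, np.ndarray]:
    """Smooth per-bin multiplier in [0.8, 1.2] standing in for GC bias."""
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom)
        x = np.arange(n)
        # sum of a few random low-frequency cosines, rescaled to [0.8, 1.2]
        wave = np.zeros(n)
        for _ in range(3):
            period = rng.uniform(200, 2000)
            phase = rng.uniform(0, 2 * np.pi)
            wave += np.cos(2 * np.pi * x / period + phase)
        lo, hi = wave.min(), wave.max()
        if hi > lo:
            wave = np.clip(0.8 + 0.4 * (wave - lo) / (hi - lo), 0.8, 1.2)
        else:
            wave = np.ones(n)
        out[chrom] = wave
    return out


def simulate_depth(
    genome: GenomeModel,
    truth: TruthTable,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    gc_bias: bool = False,
    overdispersion: float | None = None,
    read_unit: int = DEFAULT_READ_UNIT,
    seed: int = 0,
) -> tuple[list[DepthProfile], dict[str, np.ndarray] | None]:
    """Simulate per-sample binned read counts around planted copy ratios.

    Per-bin counts are Poisson(mean_depth * bin_size/read_unit *
    copy_ratio * gc), or negative binomial with the given
    inverse-dispersion when ``overdispersion`` is set.  Returns one
    profile per sample plus the per-bin GC multiplier track (None when
    gc_bias is off).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if read_unit <= 0:
        raise ValueError("read_unit must be positive")
    count_scale = genome.bin_size / read_unit
    for locus in truth.loci:
        genome.validate_interval(locus.chrom, locus.start, locus.end)
        if locus.length < genome.bin_size:
            raise ValueError(f"locus {locus.locus_id} shorter than one bin")

    rng = np.random.default_rng(seed)
    gc = _gc_multiplier(genome, seed + 1) if gc_bias else None
    samples = truth.design.sample_table
    profiles = []
    for j, sample in enumerate(samples["sample"]):
        lam = {
            chrom: np.full(genome.n_bins(chrom), mean_depth * count_scale)
            for chrom in genome.names
        }
        for i, locus in enumerate(truth.loci):
            g = int(truth.genotypes.iloc[i, j])
            if g == 0:
                continue
            b0 = genome.bin_index(locus.start)
            b1 = genome.bin_index(locus.end)
            lam[locus.chrom][b0 : b1 + 1] = (
                mean_depth * count_scale * locus.copy_ratio(g)
            )
        counts = {}
        for chrom in genome.names:
            mu = lam[chrom] * gc[chrom] if gc is not None else lam[chrom]
            if overdispersion is None:
                counts[chrom] = rng.poisson(mu)
            else:
                # NB with mean mu and variance mu + mu^2/overdispersion
                k = float(overdispersion)
                counts[chrom] = rng.negative_binomial(k, k / (k + mu))
        profiles.append(
            DepthProfile(sample=str(sample), counts=counts, mean_depth=mean_depth)
        )
    return profiles, gc


def simulate_genes(
    genome: GenomeModel,
    n_genes: int,
    mean_length: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Place non-overlapping-ish gene intervals uniformly on the genome.

    Lengths are drawn from a geometric-like exponential with the given
    mean, clipped to [200 bp, chromosome length].  Returns a gene table
    with 1-based closed coordinates, suitable for :func:`write_gff3`.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = genome.names
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(n_genes):
        chrom = names[rng.choice(len(names), p=weights)]
        glen = int(np.clip(rng.exponential(mean_length), 200, lengths[chrom]))
        start = int(rng.integers(1, lengths[chrom] - glen + 2))
        rows.append(
            {
                "gene_id": f"gene{i + 1:05d}",
                "name": f"GENE{i + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + glen - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "name", "chrom", "start", "end", "strand"]
    )


# ---------------------------------------------------------------------------
# Default scenario: the study design this package emulates.

def default_genome(bin_size: int = 400) -> GenomeModel:
    """Ten autosomes from 2.0 Mb down to 0.2 Mb (11 Mb total)."""
    lengths = [2_000_000 - i * 200_000 for i in range(10)]
    return build_genome(lengths, bin_size=bin_size)


def default_design(
    genome: GenomeModel | None = None,
    n_background: int = 510,
    n_differentiated_per_pop: int = 1,
    focal_frequency: float = 0.9,
    rest_frequency: float = 0.1,
    populations: tuple[tuple[str, int], ...] = DEFAULT_POPULATIONS,
    seed: int = 0,
) -> tuple[GenomeModel, PopulationDesign]:
    """The default population CNV architecture.

    Background loci: carrier-allele base frequency U(0.08, 0.5) with a
    per-population jitter of U(-0.1, 0.1) (between-population differences
    at most 0.2), lengths 5-15 bins, 64% deletions.  Differentiated loci:
    frequency ``focal_frequency`` in one focal population and
    ``rest_frequency`` in the others, length 8 bins.  Loci occupy
    disjoint 50-bin slots so distinct planted loci never merge into one
    region.
    """
    if genome is None:
        genome = default_genome()
    rng = np.random.default_rng(seed)
    pop_names = [p for p, _ in populations]
    n_diff = n_differentiated_per_pop * len(pop_names)
    n_total = n_background + n_diff

    slot_bins = 50
    slots = []  # (chrom, slot_start_bin)
    for chrom in genome.names:
        for s in range(genome.n_bins(chrom) // slot_bins):
            slots.append((chrom, s * slot_bins))
    if n_total > len(slots):
        raise ValueError(
            f"genome holds {len(slots)} locus slots, need {n_total}"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    chosen = sorted(chosen)

    loci = []
    # spread differentiated loci evenly through the chosen slots
    diff_positions = set(
        int(round(q)) for q in np.linspace(0, n_total - 1, n_diff)
    ) if n_diff else set()
    diff_iter = iter(
        [pop for pop in pop_names for _ in range(n_differentiated_per_pop)]
    )
    for rank, slot_idx in enumerate(chosen):
        chrom, slot_start = slots[slot_idx]
        if rank in diff_positions:
            n_bins = 8
            focal = next(diff_iter)
            freqs = {
                p: (focal_frequency if p == focal else rest_frequency)
                for p in pop_names
            }
            tag = f"sel_{focal}"
        else:
            n_bins = int(rng.integers(5, 16))
            base = rng.uniform(0.08, 0.5)
            freqs = {
                p: float(np.clip(base + rng.uniform(-0.1, 0.1), 0.0, 1.0))
                for p in pop_names
            }
            tag = "bg"
        offset = int(rng.integers(2, slot_bins - n_bins - 2))
        start_bin = slot_start + offset
        cnv_type = "DEL" if rng.random() < DEFAULT_DEL_FRACTION else "DUP"
        loci.append(
            PlantedLocus(
                chrom=chrom,
                start=genome.bin_start(start_bin),
                end=genome.bin_end(start_bin + n_bins - 1),
                cnv_type=cnv_type,
                allele_frequency=freqs,
                locus_id=f"{tag}_{rank + 1:04d}",
            )
        )
    return genome, PopulationDesign(populations=tuple(populations), loci=tuple(loci))


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)

def write_truth_bed(truth: TruthTable, path: str | Path) -> None:
    """Truth loci as BED (0-based half-open) with per-population frequencies."""
    pops = [p for p, _ in truth.design.populations]
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlocus_id\tcnv_type\t" + "\t".join(f"freq_{p}" for p in pops) + "\n")
        for locus in truth.loci:
            freqs = "\t".join(f"{locus.allele_frequency.get(p, 0.0):.4f}" for p in pops)
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.locus_id}\t{locus.cnv_type}\t{freqs}\n"
            )


def depth_matrix(genome: GenomeModel, profiles: list[DepthProfile]) -> pd.DataFrame:
    """Long-format bin table: chrom, start, end, one raw-count column per sample."""
    rows = []
    for chrom in genome.names:
        n = genome.n_bins(chrom)
        starts = np.arange(n) * genome.bin_size + 1
        block = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + genome.bin_size - 1}
        )
        for prof in profiles:
            block[prof.sample] = prof.counts[chrom]
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def write_depth_tsv(genome: GenomeModel, profiles: list[DepthProfile], path: str | Path) -> None:
    depth_matrix(genome, profiles).to_csv(path, sep="\t", index=False)


def write_samples_tsv(design: PopulationDesign, path: str | Path) -> None:
    design.sample_table.to_csv(path, sep="\t", index=False)


def write_gff3(genes: pd.DataFrame, genome: GenomeModel, path: str | Path) -> None:
    """Write a gene table as GFF3 (native 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.names:
            fh.write(f"##sequence-region {chrom} 1 {genome.lengths[chrom]}\n")
        ordered = genes.sort_values(
            ["chrom", "start"],
            key=lambda s: s.map(genome.chrom_rank) if s.name == "chrom" else s,
            kind="stable",
        )
        for row in ordered.itertuples():
            attrs = f"ID={row.gene_id};Name={row.name}"
            fh.write(
                f"{row.chrom}\tcnvpop_sim\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
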