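#!/usr/bin/env python
"""Simulate the default three-population cohort with known truth.

Generates the study-design scenario — populations JD, SX and SM with 10
diploid samples each, ~22.65x mean depth over 400 bp bins, >500 planted
CNV loci of which one per population is strongly frequency-differentiated
(0.9 focal vs 0.1 elsewhere) — and writes the raw inputs the later
stages consume (binned depth matrix, truth BED, sample table, gene
models) under scratch/pipeline/.
"""

import sys
from pathlib import Path

from cnvpop.simulate import (
    default_design, sample_genotypes, simulate_depth, simulate_genes,
    write_depth_tsv, write_gff3, write_samples_tsv, write_truth_bed,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "pipeline"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, design = default_design(seed=SEED)
    truth = sample_genotypes(design, seed=SEED + 1)
    profiles, _ = simulate_depth(genome, truth, seed=SEED + 2)
    genes = simulate_genes(genome, 300, seed=SEED + 3)

    write_truth_bed(truth, OUT / "truth.bed")
    write_depth_tsv(genome, profiles, OUT / "depth.tsv")
    write_samples_tsv(design, OUT / "samples.tsv")
    write_gff3(genes, genome, OUT / "genes.gff3")

    n_bg = sum(l.locus_id.startswith("bg") for l in truth.loci)
    n_sel = len(truth.loci) - n_bg
    print(f"genome: {len(genome.names)} autosomes, {genome.total_length / 1e6:.1f} Mb, "
          f"{genome.total_bins} bins of {genome.bin_size} bp")
    print(f"planted {n_bg} background loci and {n_sel} differentiated loci "
          f"for {len(profiles)} samples in {len(design.populations)} populations")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
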