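#!/usr/bin/env python
"""Map CNVRs onto gene models and partition genes by population.

Retains a gene for a CNVR when at least half of the gene is overlapped
(complete containment included), then splits CNVR-harboring genes into
shared and population-specific sets ready for downstream enrichment
tools.
"""

import sys
from pathlib import Path

import pandas as pd

from cnvpop import io
from cnvpop.annotate import load_genes, overlap_genes, population_gene_sets

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline"
TABLES = ROOT / "results" / "tables"
GENE_LISTS = ROOT / "results" / "gene_lists"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    GENE_LISTS.mkdir(parents=True, exist_ok=True)
    genome, _ = io.read_depth_tsv(SCRATCH / "depth.tsv")
    genes = load_genes(SCRATCH / "genes.gff3")
    sample_pops = io.read_samples_tsv(SCRATCH / "samples.tsv")

    assoc_by_pop = {}
    for pop in sorted(set(sample_pops.values())):
        cnvrs = io.read_cnvrs_bed(SCRATCH / f"cnvrs_{pop}.bed", genome)
        assoc_by_pop[pop] = overlap_genes(cnvrs, genes)
    meta = io.read_cnvrs_bed(SCRATCH / "cnvrs_metapopulation.bed", genome)
    meta_assoc = overlap_genes(meta, genes)
    meta_assoc.to_csv(TABLES / "cnvr_gene_associations.tsv", sep="\t", index=False,
                      float_format="%.4f")

    partition = population_gene_sets(assoc_by_pop)
    for key, ids in sorted(partition.items()):
        fname = GENE_LISTS / f"{key.replace(':', '_').replace(',', '-')}.txt"
        fname.write_text("\n".join(sorted(ids)) + "\n")

    print(f"{len(genes)} gene models; {len(meta_assoc)} CNVR-gene associations "
          f"at the >= 50% gene-overlap rule")
    for key in sorted(partition):
        print(f"  {key}: {len(partition[key])} genes")
    print(f"gene lists -> {GENE_LISTS}")


if __name__ == "__main__":
    sys.exit(main())
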