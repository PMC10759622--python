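#!/usr/bin/env python
"""Merge CNV calls into population and metapopulation CNVRs.

Applies the >= 1 bp overlap merge with singleton discard within each
population and over all samples pooled, classifies regions as
deletion/duplication/complex, labels sharing across populations, and
reports genome coverage plus the CNVR-count-vs-chromosome-length
regression.
"""

import sys
from pathlib import Path

import pandas as pd

from cnvpop import io
from cnvpop.regions import (
    METAPOPULATION, chrom_count_regression, compare_population_sets,
    coverage_fraction, merge_calls,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    genome, _ = io.read_depth_tsv(SCRATCH / "depth.tsv")
    calls = io.read_calls_bed(SCRATCH / "cnv_calls.bed")
    sample_pops = io.read_samples_tsv(SCRATCH / "samples.tsv")

    pop_sets = {}
    for pop in sorted(set(sample_pops.values())):
        pop_calls = [c for c in calls if sample_pops[c.sample] == pop]
        pop_sets[pop] = merge_calls(pop_calls, genome, scope=pop)
        io.write_cnvrs_bed(pop_sets[pop], SCRATCH / f"cnvrs_{pop}.bed")
    meta = merge_calls(calls, genome, scope=METAPOPULATION)
    io.write_cnvrs_bed(meta, SCRATCH / "cnvrs_metapopulation.bed")

    sharing = compare_population_sets(meta, pop_sets)
    counts = sharing["label"].value_counts()
    slope, intercept, r2 = chrom_count_regression(meta, genome)
    cov = coverage_fraction(meta, genome)

    summary = pd.DataFrame(
        [{"scope": pop, "n_cnvrs": len(s),
          "n_deletion": sum(r.cnvr_type == "DELETION" for r in s),
          "n_duplication": sum(r.cnvr_type == "DUPLICATION" for r in s),
          "n_complex": sum(r.cnvr_type == "COMPLEX" for r in s)}
         for pop, s in {**pop_sets, METAPOPULATION: meta}.items()]
    )
    summary.to_csv(TABLES / "cnvr_counts.tsv", sep="\t", index=False)
    sharing["label"].value_counts().rename_axis("label").to_frame("n_cnvrs").to_csv(
        TABLES / "cnvr_sharing_counts.tsv", sep="\t"
    )

    for row in summary.itertuples():
        print(f"{row.scope}: {row.n_cnvrs} CNVRs "
              f"({row.n_deletion} del / {row.n_duplication} dup / {row.n_complex} complex)")
    print(f"sharing: {counts.to_dict()}")
    print(f"metapopulation CNVRs cover {100 * cov:.1f}% of the genome")
    print(f"CNVR count vs chromosome length: R^2 = {r2:.2f} "
          f"(slope {slope:.3g} per bp)")


if __name__ == "__main__":
    sys.exit(main())
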