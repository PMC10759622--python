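#!/usr/bin/env python
"""Genotype CNVRs and scan for differentiated loci with Weir-Cockerham F_ST.

Encodes per-sample carrier pseudo-genotypes at every metapopulation
CNVR, computes theta-hat for each one-vs-rest population contrast, and
flags the empirical top 5% per contrast.  Writes the flagged loci and
their per-population carrier frequencies under results/tables/.
"""

import sys
from pathlib import Path

import pandas as pd

from cnvpop import io
from cnvpop.calling import normalize_depth
from cnvpop.fst import carrier_frequencies, encode_genotypes, one_vs_rest_scan, select_outliers

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    genome, profiles = io.read_depth_tsv(SCRATCH / "depth.tsv")
    cnvrs = io.read_cnvrs_bed(SCRATCH / "cnvrs_metapopulation.bed", genome)
    calls = io.read_calls_bed(SCRATCH / "cnv_calls.bed")
    sample_pops = io.read_samples_tsv(SCRATCH / "samples.tsv")

    norms = {p.sample: normalize_depth(p) for p in profiles}
    calls_by_sample = {}
    for c in calls:
        calls_by_sample.setdefault(c.sample, []).append(c)
    matrix = encode_genotypes(cnvrs, calls_by_sample, norms, sample_pops, genome)
    io.write_vcf(matrix, genome, SCRATCH / "genotypes.vcf")

    freq_rows = []
    for pop, table in one_vs_rest_scan(matrix).items():
        flagged = select_outliers(table)
        io.write_fst_tsv(flagged, SCRATCH / f"fst_{pop}_vs_rest.tsv")
        hits = flagged[flagged["outlier"]].sort_values("theta", ascending=False)
        hits.to_csv(TABLES / f"fst_outliers_{pop}_vs_rest.tsv", sep="\t",
                    index=False, float_format="%.4f")
        top = hits.iloc[0]
        print(f"{pop} vs rest: {len(hits)} outlier loci of "
              f"{int(table['theta'].notna().sum())} scored "
              f"(top theta {top['theta']:.3f} at {top['chrom']}:{top['start']}-{top['end']})")
        for locus_id in hits.head(3)["locus_id"]:
            freqs = carrier_frequencies(matrix, locus_id)
            freqs.insert(0, "locus_id", locus_id)
            freqs.insert(0, "contrast", f"{pop}_vs_rest")
            freq_rows.append(freqs)
    pd.concat(freq_rows, ignore_index=True).to_csv(
        TABLES / "outlier_carrier_frequencies.tsv", sep="\t", index=False,
        float_format="%.4f",
    )
    print(f"outlier tables -> {TABLES}")


if __name__ == "__main__":
    sys.exit(main())
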