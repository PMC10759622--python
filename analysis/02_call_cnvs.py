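#!/usr/bin/env python
"""Call CNVs per sample from the binned depth matrix.

Normalizes each sample's bin counts to RD (median = diploid), segments
deletion/duplication candidate runs, and applies the call filters
(p < 0.01, span > 1 kb, RD < 0.7 or > 1.3).  Writes the full call set
to scratch/pipeline/cnv_calls.bed and a per-sample summary to
results/tables/cnv_call_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from cnvpop import io
from cnvpop.calling import call_sample, normalize_depth
from cnvpop.regions import summarize_cnvs

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    genome, profiles = io.read_depth_tsv(SCRATCH / "depth.tsv")
    calls = []
    rows = []
    for prof in profiles:
        sample_calls = call_sample(normalize_depth(prof), genome)
        calls.extend(sample_calls)
        lengths = [c.length for c in sample_calls]
        rows.append({
            "sample": prof.sample,
            "n_calls": len(sample_calls),
            "n_del": sum(c.cnv_type == "DEL" for c in sample_calls),
            "n_dup": sum(c.cnv_type == "DUP" for c in sample_calls),
            "median_length_bp": pd.Series(lengths).median() if lengths else None,
        })
    io.write_calls_bed(calls, SCRATCH / "cnv_calls.bed")
    pd.DataFrame(rows).to_csv(TABLES / "cnv_call_summary.tsv", sep="\t", index=False)

    s = summarize_cnvs(calls)
    print(f"{s['n_calls']} CNV calls across {len(profiles)} samples "
          f"({s['n_del']} deletions, {s['n_dup']} duplications)")
    print(f"median call length {s['median_length']:.0f} bp, mean {s['mean_length']:.0f} bp")
    print(f"per-sample summary -> {TABLES / 'cnv_call_summary.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
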