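"""Plain-text interchange: BED6+, minimal VCF v4.2, depth/sample TSV.

Internal coordinates are 1-based closed; BED output is 0-based
half-open (start - 1, end), so converting a printed 1-based closed
interval to BED and back is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import CNVCall
from .fst import MISSING, CnvGenotypeMatrix
from .genome import GenomeModel, build_genome
from .regions import CNVR, CNVRSet
from .simulate import DepthProfile


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


def from_bed(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return bed_start + 1, bed_end


def write_calls_bed(calls: list[CNVCall], path: str | Path) -> None:
    """CNV calls as BED6+ (name=sample, extra: type, mean RD, p-value)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsample\tscore\tstrand\ttype\tmean_rd\tp_value\n")
        for c in calls:
            s, e = to_bed(c.start, c.end)
            fh.write(
                f"{c.chrom}\t{s}\t{e}\t{c.sample}\t0\t.\t{c.cnv_type}\t"
                f"{c.mean_rd:.4f}\t{c.p_value:.3e}\n"
            )


def read_calls_bed(path: str | Path) -> list[CNVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start, end = from_bed(int(f[1]), int(f[2]))
            calls.append(
                CNVCall(
                    sample=f[3], chrom=f[0], start=start, end=end,
                    cnv_type=f[6], mean_rd=float(f[7]), p_value=float(f[8]),
                )
            )
    return calls


def write_cnvrs_bed(cnvr_set: CNVRSet, path: str | Path) -> None:
    """CNVRs as BED6+ (name=id, extra: type, supporting calls/samples, scope)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tcnvr_id\tscore\tstrand\ttype\t"
            "supporting_calls\tsupporting_samples\tscope\n"
        )
        for r in cnvr_set:
            s, e = to_bed(r.start, r.end)
            fh.write(
                f"{r.chrom}\t{s}\t{e}\t{r.cnvr_id}\t0\t.\t{r.cnvr_type}\t"
                f"{r.supporting_calls}\t{r.supporting_samples}\t{r.scope}\n"
            )


def read_cnvrs_bed(path: str | Path, genome: GenomeModel) -> CNVRSet:
    cnvrs = []
    scope = "unknown"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start, end = from_bed(int(f[1]), int(f[2]))
            scope = f[9]
            cnvrs.append(
                CNVR(
                    cnvr_id=f[3], chrom=f[0], start=start, end=end,
                    cnvr_type=f[6], supporting_calls=int(f[7]),
                    supporting_samples=int(f[8]), scope=f[9],
                )
            )
    return CNVRSet(scope=scope, cnvrs=cnvrs, genome=genome)


def read_depth_tsv(path: str | Path, bin_size: int | None = None) -> tuple[GenomeModel, list[DepthProfile]]:
    """Read a binned depth matrix (chrom, start, end, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth TSV must have columns {sorted(required)}")
    if bin_size is None:
        bin_size = int((df["end"] - df["start"] + 1).iloc[0])
    lengths = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        lengths[str(chrom)] = int(grp["end"].max())
    genome = build_genome(lengths, bin_size=bin_size)
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    profiles = []
    for sample in sample_cols:
        counts = {
            str(chrom): grp[sample].to_numpy()
            for chrom, grp in df.groupby("chrom", sort=False)
        }
        mean_depth = float(np.concatenate(list(counts.values())).mean())
        profiles.append(DepthProfile(sample=sample, counts=counts, mean_depth=mean_depth))
    return genome, profiles


def read_samples_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: CnvGenotypeMatrix, genome: GenomeModel, path: str | Path) -> None:
    """Minimal VCF v4.2 with symbolic CNV alleles and GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cnvpop {__version__}\n")
        for chrom in genome.names:
            fh.write(f"##contig=<ID={chrom},length={genome.lengths[chrom]}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##ALT=<ID=CNV,Description="Copy number variable region">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="CNV region type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        alt_for = {"DELETION": "<DEL>", "DUPLICATION": "<DUP>", "COMPLEX": "<CNV>"}
        for i, locus in enumerate(matrix.loci.itertuples()):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.locus_id}\tN\t"
                f"{alt_for.get(locus.type, '<CNV>')}\t.\tPASS\t"
                f"END={locus.end};SVTYPE={locus.type}\tGT\t{gts}\n"
            )


def write_fst_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["locus_id", "chrom", "start", "end", "theta", "a", "b", "c",
            "n_focal", "n_rest"]
    if "outlier" in table.columns:
        cols.append("outlier")
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
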