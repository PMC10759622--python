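"""Weir-Cockerham F_ST selection scan over CNVR pseudo-genotypes.

Each CNVR is treated as a biallelic locus: allele 1 is the CNV-carrier
allele, allele 0 the reference state.  Per-sample diploid genotypes
(0, 1 or 2 carrier alleles; -1 missing) are derived from call overlap
and locus mean read depth.  Differentiation is estimated with the
Weir & Cockerham (1984) theta-hat for two groups — a focal population
against every other sample pooled — from the variance components

    theta = a / (a + b + c)

with a the among-population, b the among-individual-within-population
and c the within-individual component.  Negative estimates are kept as
computed; loci monomorphic over both groups are undefined (missing).
Outliers are the top 5% of the non-missing theta distribution of each
contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CNVCall, NormalizedProfile
from .genome import GenomeModel
from .regions import CNVRSet

MISSING = -1
HOM_DEL_RD_MAX = 0.25  # locus mean RD below this -> 1/1 deletion
HOM_DUP_RD_MIN = 1.75  # locus mean RD above this -> 1/1 duplication
DEFAULT_TOP_FRACTION = 0.05


@dataclass
class CnvGenotypeMatrix:
    """Diploid carrier-allele counts per (locus, sample).

    ``loci`` holds one row per CNVR in genome order; ``genotypes`` is an
    int8 array (n_loci x n_samples) of variant-allele counts with -1 for
    missing; ``samples``/``populations`` are parallel lists.
    """

    loci: pd.DataFrame  # columns: locus_id, chrom, start, end, type
    samples: list[str]
    populations: list[str]
    genotypes: np.ndarray

    def __post_init__(self):
        if len(self.samples) != len(self.populations):
            raise ValueError("samples and populations differ in length")
        if self.genotypes.shape != (len(self.loci), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def population_names(self) -> list[str]:
        seen = dict.fromkeys(self.populations)
        return list(seen)

    def group_mask(self, pops: list[str]) -> np.ndarray:
        pops = set(pops)
        return np.array([p in pops for p in self.populations])


def encode_genotypes(
    cnvrs: CNVRSet,
    calls_by_sample: dict[str, list[CNVCall]],
    norms: dict[str, NormalizedProfile],
    sample_populations: dict[str, str],
    genome: GenomeModel,
    hom_del_rd: float = HOM_DEL_RD_MAX,
    hom_dup_rd: float = HOM_DUP_RD_MIN,
) -> CnvGenotypeMatrix:
    """Derive pseudo-genotypes at every CNVR for every sample.

    A sample with no call overlapping the locus is 0/0.  A carrier is
    1/1 when its locus mean RD is consistent with a homozygous state
    (below ``hom_del_rd`` for deletions, above ``hom_dup_rd`` for
    duplications), else 0/1.  A sample lacking depth data at the locus
    is missing.
    """
    samples = list(norms)
    gt = np.zeros((len(cnvrs), len(samples)), dtype=np.int8)
    rows = []
    for i, r in enumerate(cnvrs):
        b0 = genome.bin_index(r.start)
        b1 = genome.bin_index(r.end)
        rows.append(
            {"locus_id": r.cnvr_id, "chrom": r.chrom, "start": r.start,
             "end": r.end, "type": r.cnvr_type}
        )
        for j, sample in enumerate(samples):
            rd_track = norms[sample].rd.get(r.chrom)
            if rd_track is None or b1 >= len(rd_track):
                gt[i, j] = MISSING
                continue
            overlapping = [
                c
                for c in calls_by_sample.get(sample, [])
                if c.chrom == r.chrom and c.start <= r.end and c.end >= r.start
            ]
            if not overlapping:
                gt[i, j] = 0
                continue
            locus_rd = float(rd_track[b0 : b1 + 1].mean())
            # carrier type from the overlapping calls (majority span)
            del_span = sum(c.length for c in overlapping if c.cnv_type == "DEL")
            dup_span = sum(c.length for c in overlapping if c.cnv_type == "DUP")
            if del_span >= dup_span:
                gt[i, j] = 2 if locus_rd < hom_del_rd else 1
            else:
                gt[i, j] = 2 if locus_rd > hom_dup_rd else 1
    loci = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end", "type"])
    return CnvGenotypeMatrix(
        loci=loci,
        samples=samples,
        populations=[sample_populations[s] for s in samples],
        genotypes=gt,
    )


@dataclass(frozen=True)
class FstRecord:
    locus_id: str
    contrast: str
    theta: float | None
    a: float | None
    b: float | None
    c: float | None
    n_focal: int
    n_rest: int
    reason: str | None = None  # why theta is missing


def _group_stats(gt: np.ndarray) -> tuple[int, float, float]:
    """(n genotyped diploids, carrier-allele frequency, het proportion)."""
    called = gt[gt != MISSING]
    n = len(called)
    if n == 0:
        return 0, math.nan, math.nan
    return n, float(called.sum()) / (2 * n), float(np.mean(called == 1))


def weir_cockerham_fst(
    genotypes: np.ndarray,
    group1: np.ndarray,
    group2: np.ndarray,
    locus_id: str = "",
    contrast: str = "",
) -> FstRecord:
    """Two-group Weir-Cockerham theta-hat at one biallelic locus.

    ``genotypes`` are variant-allele counts (0/1/2, -1 missing);
    ``group1``/``group2`` are boolean sample masks.  Returns the
    variance components and theta = a/(a+b+c); theta is missing when a
    group has no genotyped sample or when both groups are fixed for the
    same allele (the components all vanish).
    """
    n1, p1, h1 = _group_stats(genotypes[group1])
    n2, p2, h2 = _group_stats(genotypes[group2])
    if n1 == 0 or n2 == 0:
        return FstRecord(locus_id, contrast, None, None, None, None, n1, n2,
                         reason="group without genotyped samples")
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if nbar <= 1 or nc == 0:
        return FstRecord(locus_id, contrast, None, None, None, None, n1, n2,
                         reason="too few individuals per group")
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return FstRecord(locus_id, contrast, None, a, b, c, n1, n2,
                         reason="monomorphic")
    return FstRecord(locus_id, contrast, float(a / denom), float(a), float(b),
                     float(c), n1, n2)


def one_vs_rest_scan(matrix: CnvGenotypeMatrix) -> dict[str, pd.DataFrame]:
    """Per-locus theta for every focal-population-vs-pooled-rest contrast.

    Returns one genome-ordered table per focal population with columns
    locus_id, chrom, start, end, theta, a, b, c, n_focal, n_rest.
    """
    pops = matrix.population_names
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    tables = {}
    for focal in pops:
        focal_mask = matrix.group_mask([focal])
        rest_mask = ~focal_mask
        contrast = f"{focal}_vs_rest"
        rows = []
        for i, locus in enumerate(matrix.loci.itertuples()):
            rec = weir_cockerham_fst(
                matrix.genotypes[i], focal_mask, rest_mask,
                locus_id=locus.locus_id, contrast=contrast,
            )
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "theta": np.nan if rec.theta is None else rec.theta,
                    "a": np.nan if rec.a is None else rec.a,
                    "b": np.nan if rec.b is None else rec.b,
                    "c": np.nan if rec.c is None else rec.c,
                    "n_focal": rec.n_focal,
                    "n_rest": rec.n_rest,
                }
            )
        tables[focal] = pd.DataFrame(
            rows,
            columns=["locus_id", "chrom", "start", "end", "theta", "a", "b",
                     "c", "n_focal", "n_rest"],
        )
    return tables


def select_outliers(
    records: pd.DataFrame, top_fraction: float = DEFAULT_TOP_FRACTION
) -> pd.DataFrame:
    """Flag the empirical top fraction of non-missing theta values.

    Exactly ``ceil(top_fraction * m)`` loci are flagged among the m
    loci with defined theta; ties at the threshold go to the earlier
    locus in genome order.  Returns the table with an ``outlier``
    boolean column added.
    """
    out = records.copy()
    defined = out["theta"].notna()
    m = int(defined.sum())
    out["outlier"] = False
    if m == 0:
        warnings.warn("all theta values missing; no outliers flagged")
        return out
    k = math.ceil(top_fraction * m)
    idx = out.index[defined]
    order = sorted(idx, key=lambda i: (-out.at[i, "theta"], list(out.index).index(i)))
    out.loc[order[:k], "outlier"] = True
    return out


def carrier_frequencies(matrix: CnvGenotypeMatrix, locus_id: str) -> pd.DataFrame:
    """Per-population carrier-allele frequency at one locus."""
    where = matrix.loci.index[matrix.loci["locus_id"] == locus_id]
    if len(where) == 0:
        raise KeyError(locus_id)
    gt = matrix.genotypes[where[0]]
    rows = []
    for pop in matrix.population_names:
        mask = matrix.group_mask([pop])
        n, p, _ = _group_stats(gt[mask])
        rows.append(
            {"population": pop, "n_genotyped": n,
             "carrier_frequency": p if n else np.nan}
        )
    return pd.DataFrame(rows)
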