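"""CNVR construction: merging per-sample CNV calls into population regions.

A copy number variable region (CNVR) is the transitive union of calls
that overlap by at least 1 bp (book-ended calls, where one ends exactly
where the next starts minus one, are NOT merged).  Regions supported by
fewer than two calls are discarded.  A CNVR is DELETION if every
supporting call is a deletion, DUPLICATION if every call is a
duplication, and COMPLEX otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CNVCall
from .genome import GenomeModel

METAPOPULATION = "metapopulation"


def interval_length(start: int, end: int) -> int:
    """Length in bp of a 1-based closed interval: end - start + 1."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start + 1


@dataclass(frozen=True)
class CNVR:
    cnvr_id: str
    chrom: str
    start: int  # 1-based closed
    end: int
    cnvr_type: str  # DELETION | DUPLICATION | COMPLEX
    supporting_calls: int
    supporting_samples: int
    scope: str

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)


@dataclass
class CNVRSet:
    scope: str
    cnvrs: list[CNVR]
    genome: GenomeModel = field(repr=False)

    def __post_init__(self):
        self.cnvrs.sort(key=lambda r: (self.genome.chrom_rank(r.chrom), r.start))
        prev: CNVR | None = None
        for r in self.cnvrs:
            if prev is not None and prev.chrom == r.chrom and r.start <= prev.end:
                raise ValueError(
                    f"overlapping CNVRs in set {self.scope}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} / {r.chrom}:{r.start}-{r.end}"
                )
            prev = r

    def __len__(self) -> int:
        return len(self.cnvrs)

    def __iter__(self):
        return iter(self.cnvrs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cnvr_id": r.cnvr_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "length": r.length,
                    "type": r.cnvr_type,
                    "supporting_calls": r.supporting_calls,
                    "supporting_samples": r.supporting_samples,
                    "scope": r.scope,
                }
                for r in self.cnvrs
            ],
            columns=[
                "cnvr_id", "chrom", "start", "end", "length", "type",
                "supporting_calls", "supporting_samples", "scope",
            ],
        )


def _classify(types: list[str]) -> str:
    uniq = set(types)
    if uniq == {"DEL"}:
        return "DELETION"
    if uniq == {"DUP"}:
        return "DUPLICATION"
    return "COMPLEX"


def merge_calls(
    calls: list[CNVCall],
    genome: GenomeModel,
    scope: str,
    min_support: int = 2,
) -> CNVRSet:
    """Merge calls overlapping by >= 1 bp into CNVRs; drop weakly supported ones.

    ``min_support`` is the minimum number of supporting calls (default 2:
    singleton regions are discarded).  Adjacent but non-overlapping calls
    stay separate.
    """
    ordered = sorted(calls, key=lambda c: (genome.chrom_rank(c.chrom), c.start, c.end))
    cnvrs: list[CNVR] = []
    cluster: list[CNVCall] = []

    def flush():
        if not cluster:
            return
        n_calls = len(cluster)
        if n_calls >= min_support:
            cnvrs.append(
                CNVR(
                    cnvr_id=f"{scope}_cnvr_{len(cnvrs) + 1:05d}",
                    chrom=cluster[0].chrom,
                    start=min(c.start for c in cluster),
                    end=max(c.end for c in cluster),
                    cnvr_type=_classify([c.cnv_type for c in cluster]),
                    supporting_calls=n_calls,
                    supporting_samples=len({c.sample for c in cluster}),
                    scope=scope,
                )
            )

    cur_end = None
    for c in ordered:
        if cluster and c.chrom == cluster[0].chrom and c.start <= cur_end:
            cluster.append(c)
            cur_end = max(cur_end, c.end)
        else:
            flush()
            cluster = [c]
            cur_end = c.end
    flush()
    return CNVRSet(scope=scope, cnvrs=cnvrs, genome=genome)


def compare_population_sets(
    meta: CNVRSet, population_sets: dict[str, CNVRSet]
) -> pd.DataFrame:
    """Label each metapopulation CNVR by which population sets it overlaps.

    Membership is >= 1 bp overlap with any CNVR of a population's set.
    The label is "shared" (all populations), "specific:P" (exactly one),
    or the sorted comma-joined subset otherwise.
    """
    if len(population_sets) < 2:
        raise ValueError("need >= 2 population sets")
    pops = list(population_sets)
    rows = []
    for r in meta:
        members = [
            pop
            for pop in pops
            if any(
                q.chrom == r.chrom and q.start <= r.end and q.end >= r.start
                for q in population_sets[pop]
            )
        ]
        if len(members) == len(pops):
            label = "shared"
        elif len(members) == 1:
            label = f"specific:{members[0]}"
        elif members:
            label = ",".join(sorted(members))
        else:
            label = "none"
        row = {"cnvr_id": r.cnvr_id, "chrom": r.chrom, "start": r.start, "end": r.end, "label": label}
        for pop in pops:
            row[f"in_{pop}"] = pop in members
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_fraction(cnvr_set: CNVRSet, genome: GenomeModel) -> float:
    """Fraction of the genome covered by the (non-overlapping) CNVRs."""
    total = 0
    for r in cnvr_set:
        genome.validate_interval(r.chrom, r.start, r.end)
        total += r.length
    return total / genome.total_length


def chrom_count_regression(
    cnvr_set: CNVRSet, genome: GenomeModel
) -> tuple[float, float, float]:
    """OLS of per-chromosome CNVR count on chromosome length -> (slope, intercept, R^2)."""
    if len(genome.names) < 3:
        raise ValueError("regression needs >= 3 chromosomes")
    counts = {c: 0 for c in genome.names}
    for r in cnvr_set:
        counts[r.chrom] += 1
    x = np.array([genome.lengths[c] for c in genome.names], dtype=float)
    y = np.array([counts[c] for c in genome.names], dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn("CNVR counts constant across chromosomes; R^2 undefined, reporting 0")
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def summarize_cnvs(calls: list[CNVCall], hist_edges: list[int] | None = None) -> dict:
    """Descriptive summaries of a call set (per-sample counts, lengths)."""
    lengths = np.array([c.length for c in calls], dtype=float)
    per_sample = pd.Series([c.sample for c in calls]).value_counts().sort_index()
    n_del = sum(1 for c in calls if c.cnv_type == "DEL")
    if hist_edges is None:
        hist_edges = [0, 2_000, 5_000, 10_000, 50_000, 100_000, 10**9]
    hist, _ = np.histogram(lengths, bins=hist_edges) if len(calls) else (np.zeros(len(hist_edges) - 1, dtype=int), None)
    return {
        "n_calls": len(calls),
        "n_del": n_del,
        "n_dup": len(calls) - n_del,
        "per_sample_counts": per_sample.to_dict(),
        "total_length": int(lengths.sum()) if len(calls) else 0,
        "median_length": float(np.median(lengths)) if len(calls) else None,
        "mean_length": float(lengths.mean()) if len(calls) else None,
        "length_histogram": dict(zip(
            [f"{lo}-{hi}" for lo, hi in zip(hist_edges[:-1], hist_edges[1:])],
            [int(h) for h in hist],
        )),
    }
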