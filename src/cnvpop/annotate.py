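"""CNVR-to-gene annotation.

A gene is retained for a CNVR when the overlap covers at least half of
the gene (complete containment is the fraction-1.0 case).  The measured
unit is the gene by default; a flag switches to CNVR-fraction.  Strand
is ignored — copy number events are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .regions import CNVRSet, interval_length


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int  # 1-based closed (GFF3 native)
    end: int
    strand: str

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)


def load_genes(gff3_path: str | Path) -> list[GeneModel]:
    """Parse gene features from a GFF3 file (non-gene features ignored)."""
    has_features = False
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(
                    f"malformed GFF3 file {gff3_path}: line {lineno} does not "
                    "have 9 tab-separated fields"
                )
            has_features = True
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # surface the offending line where gffutils knows it
        raise ValueError(f"malformed GFF3 file {gff3_path}: {exc}") from exc
    genes = []
    seen = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {gff3_path}")
        seen.add(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                name=feat.attributes.get("Name", [gene_id])[0],
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes


def overlap_genes(
    cnvrs: CNVRSet,
    genes: list[GeneModel],
    min_gene_fraction: float = 0.5,
    fraction_of: str = "gene",
) -> pd.DataFrame:
    """Associate CNVRs with genes under the fractional-overlap rule.

    A (CNVR, gene) pair is retained iff the overlap length is at least
    ``min_gene_fraction`` times the gene length (or the CNVR length when
    ``fraction_of="cnvr"``).  ``min_gene_fraction=0`` reduces to
    any-overlap; ``1`` to full containment.
    """
    if fraction_of not in ("gene", "cnvr"):
        raise ValueError("fraction_of must be 'gene' or 'cnvr'")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree coordinates: [start, end + 1)
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    rows = []
    for r in cnvrs:
        for iv in sorted(trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end + 1)):
            g: GeneModel = iv.data
            ov = min(r.end, g.end) - max(r.start, g.start) + 1
            if ov <= 0:
                continue
            denom = g.length if fraction_of == "gene" else r.length
            frac = ov / denom
            if min_gene_fraction == 0 or frac >= min_gene_fraction:
                rows.append(
                    {
                        "cnvr_id": r.cnvr_id,
                        "gene_id": g.gene_id,
                        "gene_name": g.name,
                        "chrom": r.chrom,
                        "cnvr_start": r.start,
                        "cnvr_end": r.end,
                        "gene_start": g.start,
                        "gene_end": g.end,
                        "overlap_bp": ov,
                        "overlap_fraction": frac,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["cnvr_id", "gene_id", "gene_name", "chrom", "cnvr_start",
                 "cnvr_end", "gene_start", "gene_end", "overlap_bp",
                 "overlap_fraction"],
    )
    return df.drop_duplicates(subset=["cnvr_id", "gene_id"]).reset_index(drop=True)


def population_gene_sets(associations: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Set algebra over per-population CNVR-harboring gene ids.

    Returns a partition keyed ``shared`` (all populations),
    ``specific:P`` (exactly one population) and ``subset:P1,P2,...``
    for intermediate memberships.
    """
    if len(associations) < 2:
        raise ValueError("need >= 2 populations")
    pops = list(associations)
    gene_pops: dict[str, set[str]] = {}
    for pop, df in associations.items():
        for gid in df["gene_id"].unique():
            gene_pops.setdefault(gid, set()).add(pop)
    out: dict[str, set[str]] = {}
    for gid, members in gene_pops.items():
        if len(members) == len(pops):
            key = "shared"
        elif len(members) == 1:
            key = f"specific:{next(iter(members))}"
        else:
            key = "subset:" + ",".join(sorted(members))
        out.setdefault(key, set()).add(gid)
    return out
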