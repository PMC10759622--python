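"""Per-sample CNV detection from binned read depth.

The caller operates on normalized read depth (RD): raw per-bin counts
divided by the genome-wide median, so diploid copy number sits at
RD = 1.0.  Bins are labeled deletion candidates (RD < 0.7), duplication
candidates (RD > 1.3) or normal; maximal candidate runs (tolerating a
small number of interior normal bins) become segments; a segment becomes
a call only if it passes all of

* two-sided one-sample t-test of its bin RDs against 1.0, p < 0.01,
* span > 1 kb (strict),
* segment mean RD itself below 0.7 (deletion) or above 1.3 (duplication).

The RD thresholds are strict inequalities: RD exactly 0.7 or 1.3 is
neither candidate state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeModel
from .simulate import DepthProfile

logger = logging.getLogger(__name__)

DEL_RD_MAX = 0.7
DUP_RD_MIN = 1.3
P_VALUE_MAX = 0.01
MIN_CALL_LENGTH = 1_000  # bp, strict: length must exceed this
MIN_P = np.nextafter(0.0, 1.0)  # smallest positive double


@dataclass
class NormalizedProfile:
    sample: str
    rd: dict[str, np.ndarray]  # chrom -> per-bin normalized depth
    normalization_constant: float

    def __post_init__(self):
        if self.normalization_constant <= 0:
            raise ValueError("normalization constant must be positive")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start_bin: int  # 0-based, inclusive
    end_bin: int
    start: int  # 1-based closed bp
    end: int
    mean_rd: float
    n_bins: int
    state: str  # "DEL" | "DUP"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CNVCall:
    sample: str
    chrom: str
    start: int  # 1-based closed
    end: int
    cnv_type: str  # "DEL" | "DUP"
    mean_rd: float
    p_value: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("call end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_depth(
    profile: DepthProfile,
    gc_track: dict[str, np.ndarray] | None = None,
) -> NormalizedProfile:
    """Normalize raw bin counts to RD = count / genome-wide median.

    When a per-bin GC multiplier track is supplied, counts are first
    divided by it (GC-stratified correction), then median-normalized.
    The median is robust to the CNV bins themselves, which occupy a
    small genome fraction.
    """
    total_bins = sum(len(a) for a in profile.counts.values())
    if total_bins < 1_000:
        raise ValueError(f"need >= 1000 bins genome-wide, got {total_bins}")
    corrected = {}
    for chrom, counts in profile.counts.items():
        arr = counts.astype(float)
        if gc_track is not None:
            arr = arr / gc_track[chrom]
        corrected[chrom] = arr
    allbins = np.concatenate(list(corrected.values()))
    const = float(np.median(allbins))
    if const <= 0:
        raise ValueError(f"degenerate profile for {profile.sample}: median depth is 0")
    rd = {chrom: arr / const for chrom, arr in corrected.items()}
    return NormalizedProfile(
        sample=profile.sample, rd=rd, normalization_constant=const
    )


def _label_bins(rd: np.ndarray) -> np.ndarray:
    """-1 deletion candidate, +1 duplication candidate, 0 normal."""
    lab = np.zeros(len(rd), dtype=np.int8)
    lab[rd < DEL_RD_MAX] = -1
    lab[rd > DUP_RD_MIN] = 1
    return lab


def segment_profile(
    norm: NormalizedProfile,
    genome: GenomeModel,
    gap_bins: int = 1,
) -> list[Segment]:
    """Group candidate bins into maximal single-state runs.

    Two same-state candidate bins join the same segment when separated
    by at most ``gap_bins`` bins, all of which are normal (an
    opposite-state bin always breaks the run).  Segment mean RD is taken
    over every bin in the span, interior normal bins included.
    """
    if gap_bins < 0:
        raise ValueError("gap_bins must be >= 0")
    segments: list[Segment] = []
    for chrom in genome.names:
        rd = norm.rd[chrom]
        lab = _label_bins(rd)
        for state, name in ((-1, "DEL"), (1, "DUP")):
            idx = np.flatnonzero(lab == state)
            if idx.size == 0:
                continue
            run_start = idx[0]
            prev = idx[0]
            for i in idx[1:]:
                interior = lab[prev + 1 : i]
                if (i - prev - 1) <= gap_bins and np.all(interior == 0):
                    prev = i
                    continue
                segments.append(_make_segment(genome, chrom, run_start, prev, rd, name))
                run_start = i
                prev = i
            segments.append(_make_segment(genome, chrom, run_start, prev, rd, name))
    segments.sort(key=lambda s: (genome.chrom_rank(s.chrom), s.start))
    return segments


def _make_segment(
    genome: GenomeModel, chrom: str, b0: int, b1: int, rd: np.ndarray, state: str
) -> Segment:
    span = rd[b0 : b1 + 1]
    return Segment(
        chrom=chrom,
        start_bin=int(b0),
        end_bin=int(b1),
        start=genome.bin_start(b0),
        end=genome.bin_end(b1),
        mean_rd=float(span.mean()),
        n_bins=int(b1 - b0 + 1),
        state=state,
    )


def score_segment(seg: Segment, norm: NormalizedProfile) -> float:
    """Two-sided one-sample t-test p-value of in-segment RDs against 1.0.

    A zero-variance segment whose mean differs from 1.0 is maximally
    inconsistent with diploid depth and receives the smallest positive
    representable p; zero variance at mean exactly 1.0 gives p = 1.
    Segments of fewer than two bins have no defined significance.
    """
    if seg.n_bins < 2:
        raise ValueError("significance undefined for segments of < 2 bins")
    vals = norm.rd[seg.chrom][seg.start_bin : seg.end_bin + 1]
    if np.ptp(vals) == 0.0:
        return 1.0 if vals[0] == 1.0 else MIN_P
    res = stats.ttest_1samp(vals, popmean=1.0)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0 if abs(vals.mean() - 1.0) < 1e-12 else MIN_P
    return max(p, MIN_P)


def call_sample(
    norm: NormalizedProfile,
    genome: GenomeModel,
    gap_bins: int = 1,
    p_max: float = P_VALUE_MAX,
    min_length: int = MIN_CALL_LENGTH,
    del_rd_max: float = DEL_RD_MAX,
    dup_rd_min: float = DUP_RD_MIN,
) -> list[CNVCall]:
    """Segment a normalized profile and apply all call-level filters."""
    calls = []
    for seg in segment_profile(norm, genome, gap_bins=gap_bins):
        if seg.n_bins < 2:
            logger.debug(
                "%s %s:%d-%d rejected: single bin, significance undefined",
                norm.sample, seg.chrom, seg.start, seg.end,
            )
            continue
        if seg.length <= min_length:
            continue
        if seg.mean_rd < del_rd_max:
            cnv_type = "DEL"
        elif seg.mean_rd > dup_rd_min:
            cnv_type = "DUP"
        else:
            continue  # gap bins pulled the span mean inside the normal band
        p = score_segment(seg, norm)
        if not p < p_max:
            continue
        calls.append(
            CNVCall(
                sample=norm.sample,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                cnv_type=cnv_type,
                mean_rd=seg.mean_rd,
                p_value=p,
            )
        )
    calls.sort(key=lambda c: (genome.chrom_rank(c.chrom), c.start))
    return calls


def filter_calls(calls: list[CNVCall]) -> list[CNVCall]:
    """Re-apply the call-level filters; a no-op on caller output."""
    return [
        c
        for c in calls
        if c.p_value < P_VALUE_MAX
        and c.length > MIN_CALL_LENGTH
        and (
            (c.cnv_type == "DEL" and c.mean_rd < DEL_RD_MAX)
            or (c.cnv_type == "DUP" and c.mean_rd > DUP_RD_MIN)
        )
    ]
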