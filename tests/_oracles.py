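"""Independent brute-force oracles used only by the test suite.

These deliberately take the dumbest correct route — per-bp boolean
masks for interval algebra, the textbook Weir & Cockerham (1984)
component formulas for theta — so they share no code with the package
paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def mask_union(intervals: list[tuple[int, int]], genome_len: int) -> np.ndarray:
    """Boolean per-bp occupancy mask of 1-based closed intervals."""
    mask = np.zeros(genome_len + 1, dtype=bool)  # index 0 unused
    for start, end in intervals:
        mask[start : end + 1] = True
    return mask


def mask_merged_blocks(intervals: list[tuple[int, int]], genome_len: int) -> list[tuple[int, int]]:
    """Transitive >=1 bp overlap closure by repeated pairwise union.

    Book-ended intervals (end + 1 == next start) share no bp, so they
    stay separate — the per-bp mask alone cannot express that, hence the
    pairwise check here uses the masks of individual intervals.
    """
    blocks = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                shared = mask_union([a], genome_len) & mask_union([b], genome_len)
                if shared.any():
                    blocks[i] = (min(a[0], b[0]), max(a[1], b[1]))
                    del blocks[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(blocks)


def mask_overlap_bp(a: tuple[int, int], b: tuple[int, int], genome_len: int) -> int:
    return int((mask_union([a], genome_len) & mask_union([b], genome_len)).sum())


def wc84_theta(
    genotypes1: list[int], genotypes2: list[int]
) -> tuple[float, float, float, float] | None:
    """Textbook two-population WC84 components from genotype lists.

    Genotypes are variant-allele counts 0/1/2.  Returns (a, b, c, theta)
    or None when undefined (empty group or all components zero).
    """
    groups = [genotypes1, genotypes2]
    if any(len(g) == 0 for g in groups):
        return None
    r = 2
    n = [len(g) for g in groups]
    p = [sum(g) / (2 * len(g)) for g in groups]
    h = [sum(1 for x in g if x == 1) / len(g) for g in groups]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    if nbar <= 1 or nc == 0:
        return None
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a, b, c, a / (a + b + c)


def top_fraction_flags(thetas: list[float | None], fraction: float = 0.05) -> set[int]:
    """Indices of the ceil(fraction * m) largest defined thetas.

    Ties at the cut go to the smaller index (genome-first).
    """
    defined = [(i, t) for i, t in enumerate(thetas) if t is not None and not math.isnan(t)]
    if not defined:
        return set()
    k = math.ceil(fraction * len(defined))
    ranked = sorted(defined, key=lambda it: (-it[1], it[0]))
    return {i for i, _ in ranked[:k]}
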