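"""Genome coordinate model.

All genomic intervals in this package are 1-based closed: a bin of width
``b`` starting at position ``s`` covers ``[s, s + b - 1]`` and the first
bin of every chromosome starts at position 1.  The length of an interval
``(start, end)`` is therefore ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_BIN_SIZE = 400


@dataclass(frozen=True)
class GenomeModel:
    """Named autosomes tiled by fixed-width bins.

    Chromosome lengths are truncated to an exact multiple of ``bin_size``
    on construction, so bins tile each chromosome with no partial
    trailing bin.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE
    _offsets: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        truncated = []
        for name, length in self.chromosomes:
            if length < self.bin_size:
                raise ValueError(
                    f"chromosome {name!r} length {length} is shorter than one bin"
                )
            truncated.append((name, (length // self.bin_size) * self.bin_size))
        object.__setattr__(self, "chromosomes", tuple(truncated))
        object.__setattr__(
            self, "_offsets", {name: i for i, (name, _) in enumerate(truncated)}
        )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        return self.lengths[chrom] // self.bin_size

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_start(self, bin_index: int) -> int:
        """1-based start position of a 0-based bin index."""
        return bin_index * self.bin_size + 1

    def bin_end(self, bin_index: int) -> int:
        """1-based (inclusive) end position of a 0-based bin index."""
        return (bin_index + 1) * self.bin_size

    def bin_index(self, pos: int) -> int:
        """0-based index of the bin containing a 1-based position."""
        return (pos - 1) // self.bin_size

    def chrom_rank(self, chrom: str) -> int:
        """Genome-order rank of a chromosome (for sorting)."""
        return self._offsets[chrom]

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= self.lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(1-{self.lengths[chrom]})"
            )


def build_genome(
    lengths: list[int] | dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    names: list[str] | None = None,
) -> GenomeModel:
    """Construct a :class:`GenomeModel` from chromosome lengths.

    ``lengths`` may be a list (chromosomes auto-named ``chr1..chrN``) or
    a ``{name: length}`` mapping.  Lengths are truncated to whole bins.
    """
    if isinstance(lengths, dict):
        chroms = tuple(lengths.items())
    else:
        if names is None:
            names = [f"chr{i + 1}" for i in range(len(lengths))]
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        chroms = tuple(zip(names, lengths))
    if not chroms:
        raise ValueError("at least one chromosome required")
    for _, length in chroms:
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
    return GenomeModel(chromosomes=chroms, bin_size=bin_size)
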