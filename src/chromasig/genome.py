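"""Genome coordinate system: fixed-width bins, intervals, genes, cohort design.

Everything downstream (tracks, segmentations, signature calls) lives on one
:class:`BinGrid`: each chromosome is tiled by half-open ``bin_size`` windows in
0-based coordinates, the final bin truncated at the chromosome end so the bins
partition the chromosome exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

UNSTRANDED = "."


class GenomeError(ValueError):
    """Invalid coordinates, malformed files, or inconsistent inputs."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based genomic interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise GenomeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class BinGrid:
    """Partition of a genome into fixed-width half-open bins.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp. Order is preserved and
        defines the global bin order.
    bin_size
        Bin width in bp (default 200, the resolution used throughout).
    """

    def __init__(self, chrom_sizes: dict[str, int], bin_size: int = 200):
        if bin_size <= 0:
            raise GenomeError(f"bin_size must be positive, got {bin_size}")
        if not chrom_sizes:
            raise GenomeError("chrom_sizes is empty")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise GenomeError(f"chromosome {chrom} has non-positive length {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.bin_size = int(bin_size)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    def bin_bounds(self, chrom: str, index: int) -> tuple[int, int]:
        """(start, end) in bp of bin ``index``; the last bin may be short."""
        n = self.n_bins(chrom)
        if not 0 <= index < n:
            raise GenomeError(f"bin {index} out of range for {chrom} ({n} bins)")
        start = index * self.bin_size
        return start, min(start + self.bin_size, self.chrom_sizes[chrom])

    def interval_to_bins(self, interval: GenomicInterval) -> list[tuple[str, int]]:
        """All bins overlapping ``interval`` by >= 1 bp, in genomic order."""
        if interval.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        size = self.chrom_sizes[interval.chrom]
        lo = max(0, interval.start) // self.bin_size
        hi = -(-min(interval.end, size) // self.bin_size)
        return [(interval.chrom, i) for i in range(lo, hi)]

    def bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open bin index range overlapping [start, end) on ``chrom``."""
        size = self.chrom_sizes[chrom]
        start = max(0, min(start, size))
        end = max(0, min(end, size))
        if end <= start:
            return 0, 0
        return start // self.bin_size, -(-end // self.bin_size)

    def zeros(self, dtype=np.float64) -> dict[str, np.ndarray]:
        """A fresh all-zero track on this grid."""
        return {c: np.zeros(self.n_bins(c), dtype=dtype) for c in self.chroms}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def __repr__(self) -> str:
        return f"BinGrid({len(self.chrom_sizes)} chroms, bin_size={self.bin_size}, total_bins={self.total_bins})"


def make_bingrid(chrom_sizes: dict[str, int], bin_size: int = 200) -> BinGrid:
    """Build the genome bin grid (thin functional wrapper over BinGrid)."""
    return BinGrid(chrom_sizes, bin_size)


@dataclass
class Segmentation:
    """Per-bin chromatin-state assignment for one sample on a BinGrid.

    ``states[chrom]`` is an integer array over the chromosome's bins; the
    label vocabulary maps state index -> state name (``E1``..``EK`` or a
    biological label such as ``PrAct``).
    """

    states: dict[str, np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        self.states = {c: np.asarray(v, dtype=np.int32) for c, v in self.states.items()}
        K = len(self.labels)
        for chrom, v in self.states.items():
            if v.ndim != 1:
                raise GenomeError(f"states for {chrom} must be 1-D")
            if v.size and (v.min() < 0 or v.max() >= K):
                raise GenomeError(f"state index out of range on {chrom} (K={K})")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def copy(self) -> "Segmentation":
        return Segmentation({c: v.copy() for c, v in self.states.items()}, list(self.labels))

    def check_grid(self, grid: BinGrid) -> None:
        if set(self.states) != set(grid.chroms):
            raise GenomeError("segmentation chromosomes do not match grid")
        for chrom in grid.chroms:
            if len(self.states[chrom]) != grid.n_bins(chrom):
                raise GenomeError(f"segmentation length mismatch on {chrom}")

    def runs(self, chrom: str):
        """Maximal runs of a constant state: yields (start_bin, end_bin, state)."""
        v = self.states[chrom]
        if v.size == 0:
            return
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [v.size]])
        for s, e in zip(starts, ends):
            yield int(s), int(e), int(v[s])


@dataclass
class Gene:
    """A gene body interval with id and strand; TSS is the 5' end."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(f"gene {self.gene_id}: invalid body {self.start}-{self.end}")

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.end
        if self.strand == UNSTRANDED:
            log.debug("gene %s is unstranded; TSS defaults to start", self.gene_id)
        return self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)


@dataclass
class GeneAnnotation:
    """Collection of genes with unique ids."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeError(f"duplicate gene ids: {dupes[:5]}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def tss_window(self, gene_id: str, flank: int = 1000) -> GenomicInterval:
        g = self._by_id[gene_id]
        return GenomicInterval(g.chrom, max(0, g.tss - flank), g.tss + flank, name=gene_id)


# Subtype-group semantics of the cohort: two binary partitions over the design,
# normal-immortalized vs cancer, and (within cancer) TNBC vs luminal/HER2.
@dataclass
class SubtypeDesign:
    """Cell-line cohort design: line -> subtype plus the two group partitions."""

    lines: list[str]
    subtype_of: dict[str, str]
    normal_subtypes: frozenset[str]
    tnbc_subtypes: frozenset[str]

    def __post_init__(self) -> None:
        self.normal_subtypes = frozenset(self.normal_subtypes)
        self.tnbc_subtypes = frozenset(self.tnbc_subtypes)
        missing = [ln for ln in self.lines if ln not in self.subtype_of]
        if missing:
            raise GenomeError(f"lines without subtype: {missing}")
        if len(set(self.lines)) != len(self.lines):
            raise GenomeError("duplicate cell-line ids")
        if not self.normal_subtypes:
            raise GenomeError("design needs at least one normal-like subtype")
        if self.tnbc_subtypes & self.normal_subtypes:
            raise GenomeError("a subtype cannot be both normal-like and TNBC-side")
        if not (set(self.tnbc_subtypes) <= set(self.subtypes)):
            raise GenomeError("unknown TNBC-side subtype")

    @property
    def subtypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ln in self.lines:
            seen.setdefault(self.subtype_of[ln], None)
        return list(seen)

    @property
    def cancer_subtypes(self) -> list[str]:
        return [s for s in self.subtypes if s not in self.normal_subtypes]

    @property
    def luminal_subtypes(self) -> list[str]:
        return [s for s in self.cancer_subtypes if s not in self.tnbc_subtypes]

    def lines_of(self, subtype: str) -> list[str]:
        return [ln for ln in self.lines if self.subtype_of[ln] == subtype]

    def partition(self, which: str) -> tuple[list[str], list[str]]:
        """Subtype lists (side_A, side_B) for ``pan-cancer`` or ``tnbc``."""
        if which == "pan-cancer":
            return [s for s in self.subtypes if s in self.normal_subtypes], self.cancer_subtypes
        if which == "tnbc":
            return [s for s in self.subtypes if s in self.tnbc_subtypes], self.luminal_subtypes
        raise GenomeError(f"unknown partition {which!r}; use 'pan-cancer' or 'tnbc'")
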