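"""Genome coordinate system, fixed-size binning, and Hi-C contact-matrix I/O.

The genome is partitioned into fixed-size bins (default 500 kb), each of
which becomes one bead in the polymer model and one row/column of the
contact matrix. Coordinates are 0-based; bins are half-open intervals
``[k*bin_size, (k+1)*bin_size)``; the last bin of a chromosome may be
shorter than ``bin_size`` but still counts as one bin. Genome-wide bin
indices are contiguous, chromosome by chromosome, in the order the
chromosomes were given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 500_000

__all__ = [
    "DEFAULT_BIN_SIZE",
    "BinTable",
    "ContactMatrix",
    "make_bin_table",
    "locus_to_bin",
    "read_chrom_sizes",
    "load_contact_matrix",
    "save_contact_matrix",
    "write_bins_bed",
    "normalize_chrom_name",
]


def normalize_chrom_name(name: str, style: Literal["chr", "plain", "keep"] = "keep") -> str:
    """Normalize a chromosome identifier.

    ``style="chr"`` ensures a ``chr`` prefix, ``"plain"`` strips it,
    ``"keep"`` returns the name unchanged. Normalization is applied at
    table-construction time so all downstream lookups agree on one
    convention.
    """
    name = str(name).strip()
    if style == "keep":
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    return f"chr{bare}" if style == "chr" else bare


@dataclass(frozen=True)
class BinTable:
    """Maps (chromosome, base-pair position) to a genome-wide bin index.

    Attributes
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Base pairs per chromosome, same order as ``chrom_names``.
    bin_size
        Bin width in base pairs.
    bin_offsets
        Genome-wide index of the first bin of each chromosome
        (cumulative bin counts).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    bin_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        offsets = np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])
        object.__setattr__(self, "bin_offsets", tuple(int(o) for o in offsets))

    @property
    def bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(
            math.ceil(length / self.bin_size) for length in self.chrom_lengths
        )

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def locus_to_bin(self, chrom: str, pos: int) -> int:
        """Genome-wide bin index of 0-based position ``pos`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(
                f"position {pos} out of range for {chrom} "
                f"(length {self.chrom_lengths[ci]})"
            )
        return self.bin_offsets[ci] + int(pos) // self.bin_size

    def chrom_of_bin(self, bin_index: int) -> str:
        """Chromosome containing genome-wide ``bin_index``."""
        if not 0 <= bin_index < self.n_bins:
            raise ValueError(f"bin index {bin_index} out of range [0, {self.n_bins})")
        ci = int(np.searchsorted(self.bin_offsets, bin_index, side="right")) - 1
        return self.chrom_names[ci]

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open genome-wide bin index range ``[start, stop)`` of a chromosome."""
        ci = self.chrom_index(chrom)
        start = self.bin_offsets[ci]
        return start, start + self.bins_per_chrom[ci]

    def bin_interval(self, bin_index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a genome-wide bin, end clipped to chromosome length."""
        chrom = self.chrom_of_bin(bin_index)
        ci = self.chrom_index(chrom)
        local = bin_index - self.bin_offsets[ci]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.chrom_lengths[ci])
        return chrom, start, end

    def chain_breaks(self) -> tuple[int, ...]:
        """Bin indices at which a new chromosome chain starts (excluding 0)."""
        return tuple(o for o in self.bin_offsets if o != 0)


def make_bin_table(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_style: Literal["chr", "plain", "keep"] = "keep",
) -> BinTable:
    """Build a :class:`BinTable` from a chromosome→length mapping.

    Parameters
    ----------
    chrom_sizes
        Mapping or sequence of ``(name, length)`` pairs; order is preserved.
    bin_size
        Bin width in base pairs (default 500 kb).
    chrom_style
        Chromosome-name normalization applied to every name.
    """
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    if not items:
        raise ValueError("chrom_sizes is empty")
    names = tuple(normalize_chrom_name(n, chrom_style) for n, _ in items)
    lengths = tuple(int(l) for _, l in items)
    return BinTable(chrom_names=names, chrom_lengths=lengths, bin_size=int(bin_size))


def locus_to_bin(chrom: str, pos: int, bins: BinTable) -> int:
    """Functional form of :meth:`BinTable.locus_to_bin`."""
    return bins.locus_to_bin(chrom, pos)


def read_chrom_sizes(
    path: str | Path, chrom_style: Literal["chr", "plain", "keep"] = "keep"
) -> list[tuple[str, int]]:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], comment="#")
    return [
        (normalize_chrom_name(n, chrom_style), int(l))
        for n, l in zip(df[0], df[1])
    ]


@dataclass
class ContactMatrix:
    """Symmetric genome-wide Hi-C contact matrix on a :class:`BinTable` grid.

    ``counts[i, j]`` is the contact frequency between genome-wide bins
    ``i`` and ``j``. Counts may be raw or pre-normalized; no balancing is
    applied here.
    """

    bins: BinTable
    counts: np.ndarray
    cell_label: str = ""

    SYMMETRY_TOL = 1e-8

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        n = self.bins.n_bins
        if counts.shape != (n, n):
            raise ValueError(
                f"counts shape {counts.shape} does not match bin count {n}"
            )
        if np.any(counts < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(counts, counts.T, atol=self.SYMMETRY_TOL, rtol=0):
            counts = (counts + counts.T) / 2.0
        self.counts = counts

    def chrom_block(self, chrom: str) -> np.ndarray:
        """Intra-chromosomal sub-matrix (view) for one chromosome."""
        start, stop = self.bins.chrom_bin_range(chrom)
        return self.counts[start:stop, start:stop]

    def marginal(self) -> np.ndarray:
        """Per-bin total contact count (row sum)."""
        return self.counts.sum(axis=1)


def load_contact_matrix(
    path: str | Path,
    bins: BinTable,
    format: Literal["dense", "triplet"] = "triplet",
    cell_label: str = "",
) -> ContactMatrix:
    """Load a contact matrix from whitespace-delimited text.

    ``dense``: one row of numbers per bin. ``triplet``: lines of
    ``i j value`` with genome-wide 0-based bin indices; missing entries
    are zero, and each triplet is mirrored across the diagonal.
    """
    path = Path(path)
    n = bins.n_bins
    if format == "dense":
        counts = np.loadtxt(path, dtype=float, ndmin=2)
        if counts.shape != (n, n):
            raise ValueError(
                f"dense matrix shape {counts.shape} does not match bin count {n}"
            )
    elif format == "triplet":
        counts = np.zeros((n, n), dtype=float)
        raw = np.loadtxt(path, dtype=float, ndmin=2) if path.stat().st_size else np.empty((0, 3))
        if raw.size:
            if raw.shape[1] != 3:
                raise ValueError("triplet file must have 3 columns: i j value")
            i = raw[:, 0].astype(int)
            j = raw[:, 1].astype(int)
            v = raw[:, 2]
            if (i < 0).any() or (j < 0).any() or (i >= n).any() or (j >= n).any():
                raise ValueError("triplet indices outside bin table range")
            counts[i, j] = v
            counts[j, i] = v
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMatrix(bins=bins, counts=counts, cell_label=cell_label)


def save_contact_matrix(
    matrix: ContactMatrix,
    path: str | Path,
    format: Literal["dense", "triplet"] = "triplet",
) -> None:
    """Write a contact matrix in the dialects :func:`load_contact_matrix` reads.

    Triplet output keeps the upper triangle (including diagonal) of
    non-zero entries only.
    """
    path = Path(path)
    if format == "dense":
        np.savetxt(path, matrix.counts, fmt="%.10g")
    elif format == "triplet":
        iu, ju = np.triu_indices(matrix.bins.n_bins)
        v = matrix.counts[iu, ju]
        keep = v != 0
        with open(path, "w") as fh:
            for i, j, val in zip(iu[keep], ju[keep], v[keep]):
                fh.write(f"{i} {j} {val:.10g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_bins_bed(bins: BinTable, path: str | Path) -> None:
    """Write bin definitions as BED3 (chrom, start, end) for interoperability."""
    with open(path, "w") as fh:
        for b in range(bins.n_bins):
            chrom, start, end = bins.bin_interval(b)
            fh.write(f"{chrom}\t{start}\t{end}\n")
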