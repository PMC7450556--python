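"""Per-bin compartment degree (chromatin activity) from a Hi-C matrix.

The compartment degree is computed with the standard A/B compartment
pipeline: per-chromosome observed/expected normalization of the contact
matrix, Pearson correlation of the O/E matrix, and the first principal
eigenvector of that correlation matrix. The eigenvector, scaled to unit
maximum absolute value, is the per-bin degree; higher (more positive)
degree is read as more active chromatin and is later mapped to a smaller
nuclear radius in the polymer model.

Sign orientation: the eigenvector sign is arbitrary, so it is oriented
against an optional user track (e.g. gene density) if supplied; otherwise
the larger compartment (more bins) is made negative, treating the
smaller, denser compartment as active.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_grid import BinTable, ContactMatrix

__all__ = [
    "CompartmentProfile",
    "DegenerateInputError",
    "observed_over_expected",
    "compartment_degree",
    "genome_compartment_profile",
    "write_bedgraph",
]


class DegenerateInputError(ValueError):
    """Raised when a chromosome's contact data cannot support the computation."""


@dataclass
class CompartmentProfile:
    """Per-bin compartment degree with a validity mask.

    ``degree`` is defined where ``mask`` is True; masked bins (zero Hi-C
    coverage) hold values filled by nearest-valid-neighbor interpolation
    so downstream radial restraints cover every bead. Within each
    chromosome the degree has zero mean over valid bins.
    """

    bins: BinTable
    degree: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.degree = np.asarray(self.degree, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.bins.n_bins
        if self.degree.shape != (n,) or self.mask.shape != (n,):
            raise ValueError("degree/mask length must equal bin count")


def observed_over_expected(matrix: ContactMatrix, chrom: str) -> np.ndarray:
    """Observed/expected matrix for one chromosome.

    Entry (i, j) is the observed count divided by the mean observed count
    at genomic offset ``|i - j|`` over the whole chromosome (diagonal
    included). Offsets with zero total coverage stay 0.
    """
    block = matrix.chrom_block(chrom)
    n = block.shape[0]
    if n < 3:
        raise DegenerateInputError(f"{chrom}: need >= 3 bins, got {n}")
    if not block.any():
        raise DegenerateInputError(f"{chrom}: all-zero contact matrix")
    oe = np.zeros_like(block)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    for d in range(n):
        sel = dist == d
        mean_d = block[sel].mean()
        if mean_d > 0:
            oe[sel] = block[sel] / mean_d
    return oe


def _first_eigvec(corr: np.ndarray) -> np.ndarray:
    """Leading eigenvector (largest eigenvalue) of a symmetric matrix."""
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, -1]


def compartment_degree(
    matrix: ContactMatrix,
    chrom: str,
    orientation_track: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Compartment degree for one chromosome.

    Returns ``(degree, mask)`` arrays over the chromosome's bins. Bins
    with zero marginal count are masked out of the correlation step and
    filled by nearest-valid-neighbor interpolation. The degree is the
    first principal eigenvector of the Pearson correlation of the O/E
    matrix, scaled to unit maximum absolute value and mean-centered over
    valid bins.

    Parameters
    ----------
    orientation_track
        Optional per-bin real vector (over the chromosome's bins); the
        sign is chosen so the degree correlates non-negatively with it.
    """
    block = matrix.chrom_block(chrom)
    n = block.shape[0]
    valid = block.sum(axis=1) > 0
    if valid.sum() < 3:
        raise DegenerateInputError(f"{chrom}: fewer than 3 bins with coverage")

    sub = ContactMatrix(
        bins=BinTable((chrom,), (int(valid.sum()) * matrix.bins.bin_size,),
                      matrix.bins.bin_size),
        counts=block[np.ix_(valid, valid)],
    )
    oe = observed_over_expected(sub, chrom)
    if np.any(oe.std(axis=1) == 0):
        raise DegenerateInputError(f"{chrom}: constant O/E rows, correlation undefined")
    corr = np.corrcoef(oe)
    vec = _first_eigvec(corr)

    degree = np.zeros(n)
    degree[valid] = vec
    # fill masked bins from the nearest valid neighbor (ties -> left)
    valid_idx = np.flatnonzero(valid)
    for i in np.flatnonzero(~valid):
        j = valid_idx[np.argmin(np.abs(valid_idx - i))]
        degree[i] = degree[j]

    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)
        if track.shape != (n,):
            raise ValueError("orientation_track length must equal chromosome bin count")
        c = np.corrcoef(degree[valid], track[valid])[0, 1]
        if np.isfinite(c) and c < 0:
            degree = -degree
    else:
        if (degree[valid] > 0).sum() > (degree[valid] < 0).sum():
            degree = -degree

    degree -= degree[valid].mean()
    peak = np.abs(degree).max()
    if peak > 0:
        degree /= peak
    return degree, valid


def genome_compartment_profile(
    matrix: ContactMatrix,
    orientation_tracks: dict[str, np.ndarray] | None = None,
) -> CompartmentProfile:
    """Compute the compartment degree chromosome by chromosome."""
    bins = matrix.bins
    degree = np.zeros(bins.n_bins)
    mask = np.zeros(bins.n_bins, dtype=bool)
    for chrom in bins.chrom_names:
        start, stop = bins.chrom_bin_range(chrom)
        track = orientation_tracks.get(chrom) if orientation_tracks else None
        d, m = compartment_degree(matrix, chrom, orientation_track=track)
        degree[start:stop] = d
        mask[start:stop] = m
    return CompartmentProfile(bins=bins, degree=degree, mask=mask)


def write_bedgraph(profile: CompartmentProfile, path: str | Path) -> None:
    """Write the degree track as bedGraph (chrom, start, end, value)."""
    with open(path, "w") as fh:
        for b in range(profile.bins.n_bins):
            chrom, start, end = profile.bins.bin_interval(b)
            fh.write(f"{chrom}\t{start}\t{end}\t{profile.degree[b]:.6g}\n")
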