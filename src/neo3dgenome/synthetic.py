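"""Synthetic data with planted, recoverable structure.

Every pipeline stage can be exercised without external downloads:

* :func:`generate_hic` — a contact matrix with power-law distance decay
  and a planted A/B checkerboard (same-compartment contacts multiplied
  by ``checkerboard_strength``, cross-compartment divided), Poisson
  count noise (negative-binomial behind a flag);
* :func:`generate_epitope_set` — labeled, located 9-mer epitopes whose
  positives are optionally concentrated in a chosen set of bins;
* :func:`generate_baseline_scores` — baseline pMHC scores of tunable
  discriminative quality (binormal model with expected AUC =
  ``target_auc``), oriented lower-is-better and rescaled to [0, 1];
* :func:`generate_assay_table` — an assay-level epitope table with a
  planted positive/negative/ambiguous group composition, for testing
  the curation chain.

Peptide sequences deliberately carry no signal: everything recoverable
lives in loci, labels, and counts — exactly the information the method
uses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .epitopes import LabeledEpitope
from .genome_grid import BinTable, ContactMatrix
from .knn import rescale_baseline

__all__ = [
    "alternating_compartment_labels",
    "generate_hic",
    "generate_epitope_set",
    "generate_baseline_scores",
    "generate_assay_table",
    "random_peptides",
    "write_epitope_fixture",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def alternating_compartment_labels(bins: BinTable, block: int = 5) -> np.ndarray:
    """±1 labels in alternating blocks of ``block`` bins, restarting each
    chromosome — a simple planted checkerboard ground truth."""
    labels = np.empty(bins.n_bins, dtype=int)
    for chrom in bins.chrom_names:
        start, stop = bins.chrom_bin_range(chrom)
        local = np.arange(stop - start)
        labels[start:stop] = np.where((local // block) % 2 == 0, 1, -1)
    return labels


def generate_hic(
    bins: BinTable,
    compartment_labels: np.ndarray,
    decay_exponent: float = 1.0,
    intra_scale: float = 100.0,
    inter_scale: float = 1.0,
    checkerboard_strength: float = 3.0,
    noise: Literal["poisson", "nbinom"] = "poisson",
    nbinom_dispersion: float = 10.0,
    seed: int = 0,
    cell_label: str = "synthetic",
) -> ContactMatrix:
    """Distance-decaying contact matrix with a planted compartment signal.

    Expected intra-chromosomal counts are
    ``intra_scale * max(|i-j|, 1) ** -decay_exponent``, multiplied by
    ``checkerboard_strength`` when bins share a compartment label and
    divided by it when they differ; inter-chromosomal counts use
    ``inter_scale`` with the same multiplier. Counts are sampled around
    the expectation (Poisson by default) on the upper triangle and
    mirrored, so the output is symmetric and non-negative.
    """
    if checkerboard_strength < 1:
        raise ValueError("checkerboard_strength must be >= 1")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    labels = np.asarray(compartment_labels)
    n = bins.n_bins
    if labels.shape != (n,):
        raise ValueError("compartment_labels length must equal bin count")

    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    chrom_of = np.empty(n, dtype=int)
    for ci, chrom in enumerate(bins.chrom_names):
        start, stop = bins.chrom_bin_range(chrom)
        chrom_of[start:stop] = ci

    dist = np.abs(idx[:, None] - idx[None, :])
    same_chrom = chrom_of[:, None] == chrom_of[None, :]
    same_comp = labels[:, None] == labels[None, :]

    expected = np.where(
        same_chrom,
        intra_scale * np.maximum(dist, 1) ** (-decay_exponent),
        inter_scale,
    )
    expected = expected * np.where(
        same_comp, checkerboard_strength, 1.0 / checkerboard_strength
    )

    iu, ju = np.triu_indices(n)
    mu = expected[iu, ju]
    if noise == "poisson":
        vals = rng.poisson(mu).astype(float)
    elif noise == "nbinom":
        r = nbinom_dispersion
        vals = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    counts = np.zeros((n, n))
    counts[iu, ju] = vals
    counts[ju, iu] = vals
    return ContactMatrix(bins=bins, counts=counts, cell_label=cell_label)


def random_peptides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Unique random peptides over the 20-letter alphabet."""
    peptides: set[str] = set()
    while len(peptides) < n:
        peptides.add("".join(rng.choice(_AA, size=length)))
    return sorted(peptides)  # sort for seed-stable order independent of set hashing


def generate_epitope_set(
    bins: BinTable,
    n_pos: int,
    n_neg: int,
    spatial_mode: Literal["clustered", "uniform"] = "clustered",
    cluster_bins: Sequence[int] | None = None,
    leak: float = 0.1,
    allele: str = "HLA-A*02:01",
    peptide_length: int = 9,
    seed: int = 0,
) -> list[LabeledEpitope]:
    """Labeled, located epitopes with an optional planted spatial pattern.

    ``clustered`` places a fraction ``1 - leak`` of the positives
    uniformly within ``cluster_bins`` and everything else (leaked
    positives and all negatives) uniformly genome-wide; ``uniform``
    places both labels uniformly (the spatial null). Positions are
    uniform within the assigned bin.
    """
    if spatial_mode == "clustered":
        if cluster_bins is None or len(cluster_bins) == 0:
            raise ValueError("clustered mode needs non-empty cluster_bins")
        cluster_bins = np.asarray(cluster_bins, dtype=int)
    rng = np.random.default_rng(seed)
    peptides = random_peptides(n_pos + n_neg, peptide_length, rng)
    rng.shuffle(peptides)

    def place(bin_index: int) -> tuple[str, int, int]:
        chrom, start, end = bins.bin_interval(bin_index)
        pos = int(rng.integers(start, end))
        return chrom, pos, bin_index

    epitopes: list[LabeledEpitope] = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        if positive and spatial_mode == "clustered" and rng.random() >= leak:
            b = int(rng.choice(cluster_bins))
        else:
            b = int(rng.integers(0, bins.n_bins))
        chrom, pos, b = place(b)
        epitopes.append(
            LabeledEpitope(
                peptide=peptides[i],
                mhc_allele=allele,
                positive_rate=1.0 if positive else 0.0,
                label="positive" if positive else "negative",
                chrom=chrom,
                position=pos,
                bin_index=b,
            )
        )
    return epitopes


def generate_baseline_scores(
    labels: Sequence[int] | Sequence[bool],
    target_auc: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Baseline pMHC scores with expected AUC = ``target_auc``.

    Binormal model: negatives ~ N(0, 1) and positives ~ N(-mu, 1) with
    ``mu = sqrt(2) * Phi^{-1}(target_auc)``, so positives score lower
    (stronger predicted binders) and the expected AUC of the
    lower-is-positive ranking equals ``target_auc``. Scores are then
    rank-rescaled to [0, 1] (a monotone map, leaving the AUC unchanged).
    """
    if not 0.5 <= target_auc <= 1.0:
        raise ValueError("target_auc must be in [0.5, 1]")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    mu = np.sqrt(2.0) * norm.ppf(target_auc)  # inf at target_auc = 1 (noiseless limit)
    raw = rng.normal(size=y.size) - np.where(y == 1, mu, 0.0)
    return rescale_baseline(raw, mode="rank")


def generate_assay_table(
    n_pos_groups: int,
    n_neg_groups: int,
    n_mid_groups: int,
    assays_per_group: int = 10,
    host: str = "Homo sapiens",
    mhc_class: str = "I",
    allele: str = "HLA-A*02:01",
    peptide_length: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay-level epitope table with a planted label composition.

    Positive groups get a positive rate of 0.9, negative groups 0.1, and
    ambiguous groups 0.5 (with ``assays_per_group = 10`` that is 9/10,
    1/10 and 5/10 positive assays), so the curation chain should recover
    exactly ``n_pos_groups`` positives, ``n_neg_groups`` negatives and
    drop the rest.
    """
    rng = np.random.default_rng(seed)
    n_groups = n_pos_groups + n_neg_groups + n_mid_groups
    peptides = random_peptides(n_groups, peptide_length, rng)
    rng.shuffle(peptides)
    rows = []
    rates = (
        [0.9] * n_pos_groups + [0.1] * n_neg_groups + [0.5] * n_mid_groups
    )
    for pep, rate in zip(peptides, rates):
        n_positive = round(rate * assays_per_group)
        outcomes = ["Positive"] * n_positive + ["Negative"] * (assays_per_group - n_positive)
        for out in outcomes:
            rows.append(
                {
                    "peptide": pep,
                    "host": host,
                    "mhc_class": mhc_class,
                    "mhc_allele": allele,
                    "assay_outcome": out,
                }
            )
    return pd.DataFrame(rows)


def write_epitope_fixture(
    epitopes: Sequence[LabeledEpitope],
    baseline_scores: Sequence[float],
    directory: str | Path,
    assays_per_group: int = 10,
) -> dict[str, Path]:
    """Emit the TSV fixtures the pipeline consumes, plus a truth JSON.

    Writes an assay-level epitope table (each epitope expanded to
    ``assays_per_group`` assays consistent with its label), the
    peptide-mapping table, the baseline-score table, and a truth file
    with the planted labels and loci.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    assay_rows, map_rows, base_rows = [], [], []
    for ep, score in zip(epitopes, baseline_scores):
        n_positive = assays_per_group if ep.is_positive else 0
        for i in range(assays_per_group):
            assay_rows.append(
                {
                    "peptide": ep.peptide,
                    "host": "Homo sapiens",
                    "mhc_class": "I",
                    "mhc_allele": ep.mhc_allele,
                    "assay_outcome": "Positive" if i < n_positive else "Negative",
                }
            )
        map_rows.append(
            {"peptide": ep.peptide, "chrom": ep.chrom, "position": ep.position}
        )
        base_rows.append(
            {
                "peptide": ep.peptide,
                "mhc_allele": ep.mhc_allele,
                "baseline_score": float(score),
            }
        )
    paths = {
        "epitopes": directory / "epitopes.tsv",
        "mapping": directory / "mapping.tsv",
        "baseline": directory / "baseline.tsv",
        "truth": directory / "truth.json",
    }
    pd.DataFrame(assay_rows).to_csv(paths["epitopes"], sep="\t", index=False)
    pd.DataFrame(map_rows).to_csv(paths["mapping"], sep="\t", index=False)
    pd.DataFrame(base_rows).to_csv(paths["baseline"], sep="\t", index=False)
    truth = [
        {
            "peptide": e.peptide,
            "label": e.label,
            "chrom": e.chrom,
            "position": e.position,
            "bin_index": e.bin_index,
        }
        for e in epitopes
    ]
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
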