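"""Epitope record parsing, curation, labeling, and genome placement.

Mirrors a T-cell-assay curation pipeline over an IEDB-style export:
records are restricted to human MHC class I 9-mers; per-(peptide, allele)
groups pool their assay outcomes into a positive rate; groups with rate
strictly above 0.8 become immuno-positive, strictly below 0.2
immuno-negative, and everything in between (boundaries included) is
dropped as ambiguous. Labeled peptides are then placed on the genome via
a peptide -> (chromosome, position) mapping table — the end product of an
external sequence-alignment lookup — and assigned a genome-wide bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_grid import BinTable

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "POSITIVE_RATE_THRESHOLD",
    "NEGATIVE_RATE_THRESHOLD",
    "EpitopeRecord",
    "LabeledEpitope",
    "parse_epitope_table",
    "filter_records",
    "label_by_positive_rate",
    "attach_loci",
    "write_labeled_table",
    "read_labeled_table",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
POSITIVE_RATE_THRESHOLD = 0.8  # strictly above -> immuno-positive
NEGATIVE_RATE_THRESHOLD = 0.2  # strictly below -> immuno-negative

DEFAULT_COLUMN_MAP = {
    "peptide": "peptide",
    "host": "host",
    "mhc_class": "mhc_class",
    "mhc_allele": "mhc_allele",
    "assay_outcome": "assay_outcome",
}

_POSITIVE_WORDS = {"positive", "positive-high", "positive-intermediate", "positive-low", "1", "true"}
_NEGATIVE_WORDS = {"negative", "0", "false"}


@dataclass(frozen=True)
class EpitopeRecord:
    """One assay-level record: a peptide tested once against one allele."""

    peptide: str
    mhc_allele: str
    mhc_class: str
    host: str
    assay_outcomes: tuple[bool, ...]  # True = positive

    def __post_init__(self) -> None:
        if not self.assay_outcomes:
            raise ValueError("assay_outcomes must be non-empty")
        if not set(self.peptide) <= AMINO_ACIDS:
            raise ValueError(f"illegal amino-acid alphabet in {self.peptide!r}")


@dataclass
class LabeledEpitope:
    """A curated peptide with its immunogenicity label and genomic locus."""

    peptide: str
    mhc_allele: str
    positive_rate: float
    label: str  # "positive" | "negative"
    chrom: str | None = None
    position: int | None = None
    bin_index: int | None = None

    @property
    def located(self) -> bool:
        return self.bin_index is not None

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


def _parse_outcome(raw) -> bool | None:
    s = str(raw).strip().lower()
    if s in _POSITIVE_WORDS:
        return True
    if s in _NEGATIVE_WORDS:
        return False
    return None


def parse_epitope_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[EpitopeRecord]:
    """Parse an assay-level epitope TSV into one record per row.

    ``column_map`` maps the canonical field names (peptide, host,
    mhc_class, mhc_allele, assay_outcome) to the file's column headers.
    Rows with an illegal peptide alphabet or unparseable outcome are
    skipped and counted in the log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"epitope table missing required columns: {missing}")
    records: list[EpitopeRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        peptide = str(row[cmap["peptide"]]).strip().upper()
        outcome = _parse_outcome(row[cmap["assay_outcome"]])
        if outcome is None or not peptide or not set(peptide) <= AMINO_ACIDS:
            skipped += 1
            continue
        records.append(
            EpitopeRecord(
                peptide=peptide,
                mhc_allele=str(row[cmap["mhc_allele"]]).strip(),
                mhc_class=str(row[cmap["mhc_class"]]).strip(),
                host=str(row[cmap["host"]]).strip(),
                assay_outcomes=(outcome,),
            )
        )
    if skipped:
        logger.info("parse_epitope_table: skipped %d malformed rows", skipped)
    return records


def filter_records(
    records: Iterable[EpitopeRecord],
    host: str = "Homo sapiens",
    mhc_class: str = "I",
    length: int = 9,
) -> list[EpitopeRecord]:
    """Keep records matching host AND MHC class AND peptide length, in order."""
    return [
        r
        for r in records
        if r.host == host and r.mhc_class == mhc_class and len(r.peptide) == length
    ]


def label_by_positive_rate(records: Iterable[EpitopeRecord]) -> list[LabeledEpitope]:
    """Pool assays per (peptide, allele) group and label by positive rate.

    rate > 0.8 -> positive; rate < 0.2 -> negative; boundary and
    intermediate rates (0.2 <= rate <= 0.8) are dropped. Output order
    follows first appearance of each group.
    """
    groups: dict[tuple[str, str], list[bool]] = {}
    for r in records:
        groups.setdefault((r.peptide, r.mhc_allele), []).extend(r.assay_outcomes)
    labeled: list[LabeledEpitope] = []
    for (peptide, allele), outcomes in groups.items():
        rate = sum(outcomes) / len(outcomes)
        if rate > POSITIVE_RATE_THRESHOLD:
            label = "positive"
        elif rate < NEGATIVE_RATE_THRESHOLD:
            label = "negative"
        else:
            continue
        labeled.append(
            LabeledEpitope(peptide=peptide, mhc_allele=allele, positive_rate=rate, label=label)
        )
    return labeled


def attach_loci(
    labeled: Sequence[LabeledEpitope],
    mapping: pd.DataFrame | str | Path,
    bins: BinTable,
) -> list[LabeledEpitope]:
    """Attach genomic loci and bin indices from a peptide-mapping table.

    ``mapping`` is a TSV (or DataFrame) with columns peptide, chrom,
    position (0-based). When a peptide has several mapping rows the first
    wins; rows whose position falls outside the chromosome are rejected
    with a log entry. Peptides absent from the mapping stay unlocated
    (and are excluded from spatial analyses downstream).
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t", dtype={"peptide": str, "chrom": str})
    required = {"peptide", "chrom", "position"}
    if not required <= set(mapping.columns):
        raise ValueError(f"mapping table must have columns {sorted(required)}")

    first_hit: dict[str, tuple[str, int]] = {}
    for _, row in mapping.iterrows():
        pep = str(row["peptide"])
        if pep in first_hit:
            continue  # first hit wins
        chrom, pos = str(row["chrom"]), int(row["position"])
        try:
            bins.locus_to_bin(chrom, pos)
        except (KeyError, ValueError) as exc:
            logger.warning("attach_loci: rejected mapping row for %s: %s", pep, exc)
            continue
        first_hit[pep] = (chrom, pos)

    out: list[LabeledEpitope] = []
    for ep in labeled:
        hit = first_hit.get(ep.peptide)
        if hit is None:
            out.append(
                LabeledEpitope(ep.peptide, ep.mhc_allele, ep.positive_rate, ep.label)
            )
        else:
            chrom, pos = hit
            out.append(
                LabeledEpitope(
                    ep.peptide,
                    ep.mhc_allele,
                    ep.positive_rate,
                    ep.label,
                    chrom=chrom,
                    position=pos,
                    bin_index=bins.locus_to_bin(chrom, pos),
                )
            )
    return out


def write_labeled_table(epitopes: Sequence[LabeledEpitope], path: str | Path) -> None:
    """Write the labeled-located table as TSV."""
    rows = [
        {
            "peptide": e.peptide,
            "mhc_allele": e.mhc_allele,
            "positive_rate": e.positive_rate,
            "label": e.label,
            "chrom": e.chrom if e.chrom is not None else "",
            "position": e.position if e.position is not None else "",
            "bin_index": e.bin_index if e.bin_index is not None else "",
        }
        for e in epitopes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labeled_table(path: str | Path) -> list[LabeledEpitope]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "chrom": str})
    out = []
    for _, row in df.iterrows():
        located = pd.notna(row["bin_index"]) and str(row["bin_index"]) != ""
        out.append(
            LabeledEpitope(
                peptide=str(row["peptide"]),
                mhc_allele=str(row["mhc_allele"]),
                positive_rate=float(row["positive_rate"]),
                label=str(row["label"]),
                chrom=str(row["chrom"]) if located else None,
                position=int(row["position"]) if located else None,
                bin_index=int(row["bin_index"]) if located else None,
            )
        )
    return out
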