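"""Chloroplast tRNA gene CCA census.

tRNase Z cleaves pre-tRNAs immediately after the discriminator nucleotide
(N73, the first unpaired base after the acceptor stem).  Whether a tRNA gene
already encodes all, part, or none of the 3'-terminal CCA is read off the
trinucleotide at tRNA positions 74-76, i.e. the first three genomic bases
downstream of the annotated gene end on the coding strand.  Each gene falls
in exactly one category:

* CCA    - the full CCA is encoded
* CCN    - the first two C's are encoded (third base not A)
* CNN    - only C74 is encoded (second base not C)
* OTHER  - the first base is not C
* TRUNCATED - fewer than three bases remain before the contig edge

Per-genome rows report the counts of the three C-initial categories and the
integer percentage (round-half-up) of examined genes falling in them.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq


class Category(str, Enum):
    CCA = "CCA"
    CCN = "CCN"
    CNN = "CNN"
    OTHER = "OTHER"
    TRUNCATED = "TRUNCATED"


class CensusError(ValueError):
    pass


@dataclass(frozen=True)
class TrnaGene:
    """An annotated tRNA gene whose span ends at the discriminator N73.

    Coordinates are 0-based half-open on the given contig.  If the source
    annotation excludes the discriminator, shift the window with the
    ``discriminator_included`` flag of the census functions.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CensusError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CensusError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class CensusRecord:
    gene_id: str
    trinucleotide: str
    category: Category


@dataclass(frozen=True)
class CensusRow:
    label: str
    n_cca: int
    n_ccn: int
    n_cnn: int
    n_other: int
    n_truncated: int
    n_total: int
    percent: int

    def __post_init__(self) -> None:
        if self.n_cca + self.n_ccn + self.n_cnn > self.n_total:
            raise CensusError(f"{self.label}: category counts exceed total")

    @classmethod
    def from_counts(
        cls,
        label: str,
        n_cca: int,
        n_ccn: int,
        n_cnn: int,
        n_total: int,
        n_other: int | None = None,
        n_truncated: int = 0,
    ) -> "CensusRow":
        if n_total <= 0:
            raise CensusError(f"{label}: no usable census records")
        if n_other is None:
            n_other = n_total - n_cca - n_ccn - n_cnn
        return cls(
            label=label,
            n_cca=n_cca,
            n_ccn=n_ccn,
            n_cnn=n_cnn,
            n_other=n_other,
            n_truncated=n_truncated,
            n_total=n_total,
            percent=round_half_up(100 * (n_cca + n_ccn + n_cnn) / n_total),
        )


def round_half_up(x: float) -> int:
    """Integer rounding with exact halves going up (1.5 -> 2, 2.5 -> 3)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def normalize_nt(s: str) -> str:
    """Uppercase and convert RNA letters to DNA (U -> T)."""
    return s.upper().replace("U", "T")


def categorize(trinucleotide: str) -> Category:
    """Category of a post-discriminator trinucleotide (pure function)."""
    tri = normalize_nt(trinucleotide)
    if len(tri) < 3:
        return Category.TRUNCATED
    if tri == "CCA":
        return Category.CCA
    if tri.startswith("CC"):
        return Category.CCN
    if tri.startswith("C"):
        return Category.CNN
    return Category.OTHER


def extract_trinucleotide(
    genome: Mapping[str, str],
    gene: TrnaGene,
    discriminator_included: bool = True,
) -> CensusRecord:
    """The coding-strand trinucleotide at tRNA positions 74-76.

    For '+' genes this is the three genomic bases just downstream of the
    gene end; for '-' genes, the reverse complement of the three bases just
    upstream of the gene start.  Windows clipped at contig edges yield
    TRUNCATED records.
    """
    if gene.seq_id not in genome:
        raise CensusError(f"{gene.gene_id}: unknown sequence {gene.seq_id!r}")
    contig = genome[gene.seq_id]
    shift = 0 if discriminator_included else 1
    if gene.strand == "+":
        lo = gene.end + shift
        hi = min(lo + 3, len(contig))
        tri = normalize_nt(contig[lo:hi]) if lo <= len(contig) else ""
    else:
        hi = gene.start - shift
        lo = max(hi - 3, 0)
        raw = contig[lo:hi] if hi >= 0 else ""
        tri = str(Seq(normalize_nt(raw)).reverse_complement()) if raw else ""
    return CensusRecord(gene.gene_id, tri, categorize(tri))


def tabulate(
    records: Iterable[CensusRecord],
    label: str,
    count_truncated_in_total: bool = False,
) -> CensusRow:
    """Table-4-style per-genome summary row.

    TRUNCATED records are reported separately and by default excluded from
    the total; OTHER records count toward the total but not the numerator.
    """
    counts = {c: 0 for c in Category}
    for rec in records:
        counts[rec.category] += 1
    usable = sum(counts.values()) - counts[Category.TRUNCATED]
    n_total = usable + (counts[Category.TRUNCATED] if count_truncated_in_total else 0)
    if n_total == 0:
        raise CensusError(f"{label}: no usable census records")
    return CensusRow.from_counts(
        label=label,
        n_cca=counts[Category.CCA],
        n_ccn=counts[Category.CCN],
        n_cnn=counts[Category.CNN],
        n_total=n_total,
        n_other=counts[Category.OTHER],
        n_truncated=counts[Category.TRUNCATED],
    )


def census_pipeline(
    genome_fasta: str | Path,
    annotations: str | Path,
    label: str,
    annotation_format: str = "auto",
    feature_type: str = "tRNA",
    discriminator_included: bool = True,
) -> tuple[CensusRow, list[CensusRecord]]:
    """Run the census over a genome FASTA plus tRNA gene annotations."""
    from .interfaces import read_annotations, read_nt_fasta

    genome = dict(read_nt_fasta(genome_fasta))
    genes = read_annotations(
        annotations, dialect=annotation_format, feature_type=feature_type
    )
    if not genes:
        raise CensusError(f"no tRNA features found in {annotations}")
    records = [
        extract_trinucleotide(genome, g, discriminator_included=discriminator_included)
        for g in genes
    ]
    return tabulate(records, label), records
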