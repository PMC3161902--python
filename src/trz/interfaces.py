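"""File readers/writers, run configuration, and the survey driver.

FASTA parsing goes through Biopython, GFF3 through gffutils, BED6 and
tabular annotations through pandas; all annotation coordinates are
normalized to the internal 0-based half-open convention (GFF3 is 1-based
closed on disk, BED is already half-open).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import ALPHABET, MotifCatalog, load_catalog
from .census import CensusError, TrnaGene, normalize_nt
from .classify import classify_type

logger = logging.getLogger("trz")

NT_ALPHABET = set("ACGTUN")


class FastaError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


def _read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"empty FASTA record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Protein FASTA: order-preserving (id, uppercased sequence) pairs."""
    records = _read_fasta_records(path)
    for rid, seq in records:
        bad = next((c for c in seq if c not in ALPHABET), None)
        if bad is not None:
            raise FastaError(f"record {rid!r}: illegal protein residue {bad!r}")
    return records


def read_nt_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Nucleotide FASTA, RNA letters normalized to DNA."""
    records = [(rid, normalize_nt(seq)) for rid, seq in _read_fasta_records(path)]
    for rid, seq in records:
        bad = next((c for c in seq if c not in NT_ALPHABET), None)
        if bad is not None:
            raise FastaError(f"record {rid!r}: illegal nucleotide {bad!r}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], description: str = "") -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description=description) for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _detect_dialect(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".bed":
        return "bed"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise AnnotationError(f"cannot infer annotation dialect from {path}")


def _check_gene(gene_id: str, seq_id: str, start: int, end: int, strand: str, where: str) -> TrnaGene:
    if strand not in ("+", "-"):
        raise AnnotationError(f"{where}: invalid strand {strand!r} for {gene_id}")
    if start >= end:
        raise AnnotationError(
            f"{where}: inverted coordinates [{start}, {end}) for {gene_id}"
        )
    return TrnaGene(gene_id=gene_id, seq_id=seq_id, start=start, end=end, strand=strand)


def read_annotations(
    path: str | Path,
    dialect: str = "auto",
    feature_type: str = "tRNA",
) -> list[TrnaGene]:
    """tRNA gene annotations as internal 0-based half-open records.

    GFF3 records are filtered by feature type; an empty selection raises an
    error listing the feature types that were present.
    """
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True
        )
        genes = []
        for feat in db.features_of_type(feature_type, order_by="start"):
            genes.append(
                _check_gene(
                    feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand, str(path)
                )
            )
        if not genes:
            seen = sorted(db.featuretypes())
            raise AnnotationError(
                f"no {feature_type!r} features in {path}; feature types seen: {seen}"
            )
        return genes
    if dialect == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["seq_id", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6),
        )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "seq_id", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise AnnotationError(
                f"{path}: tabular annotations need columns {sorted(required)}"
            )
    else:
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    if df.empty:
        raise AnnotationError(f"no annotation records in {path}")
    return [
        _check_gene(
            str(row.gene_id), str(row.seq_id), int(row.start), int(row.end),
            str(row.strand), f"{path} record {i}",
        )
        for i, row in enumerate(df.itertuples())
    ]


def write_gff3(path: str | Path, genes: list[TrnaGene], source: str = "trz", seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\t{source}\ttRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def write_bed6(path: str | Path, genes: list[TrnaGene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.seq_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


@dataclass
class RunConfig:
    """Validated knobs shared by the pipeline stages."""

    catalog: str = "default"
    s_max: int = 450
    l_min: int = 600
    tm_arm_max: int = 45
    bacterial_arm_max: int = 58
    discriminator_included: bool = True
    seed: int = 0
    output_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.s_max >= self.l_min:
            raise ValueError("form thresholds must satisfy s_max < l_min")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def load_catalog(self) -> MotifCatalog:
        return load_catalog(self.catalog)


def typing_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        arm = r.arm
        rows.append(
            {
                "protein_id": r.protein_id,
                "length": r.evidence.get("length"),
                "form": r.form.value,
                "type": r.ztype.value,
                "arm_type": arm.arm_type.value if arm else "NONE",
                "arm_len": arm.length if arm else 0,
                "present_motifs": ",".join(
                    sorted(k for k, v in r.evidence.get("motifs", {}).items() if v)
                ),
                "missing_required": ",".join(r.missing_required),
            }
        )
    return pd.DataFrame(rows)


def run_survey(
    fasta: str | Path,
    config: RunConfig | None = None,
    out: str | Path | None = None,
    evidence_out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every protein in a FASTA; returns the table and type counts."""
    config = config or RunConfig()
    catalog = config.load_catalog()
    records = read_fasta(fasta)
    results = []
    for rid, seq in records:
        logger.debug("classifying %s (%d aa)", rid, len(seq))
        results.append(classify_type(seq, catalog, protein_id=rid))
    table = typing_table(results)
    summary: dict[str, int] = {}
    for r in results:
        summary[r.ztype.value] = summary.get(r.ztype.value, 0) + 1
    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    if evidence_out is not None:
        payload = {r.protein_id: r.evidence for r in results}
        with open(evidence_out, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    return table, summary
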