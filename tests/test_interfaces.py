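"""File formats, run configuration, the survey driver, and the CLI."""

import json

import pytest
from click.testing import CliRunner

from trz.cli import main
from trz.census import TrnaGene
from trz.interfaces import (
    AnnotationError,
    FastaError,
    RunConfig,
    read_annotations,
    read_fasta,
    run_survey,
    write_bed6,
    write_fasta,
    write_gff3,
)
from trz.synthetic import GenomeSpec, ProteinSpec, synth_genome, synth_protein


class TestFasta:
    def test_order_preserved_and_case_normalized(self, tmp_path):
        path = tmp_path / "in.faa"
        path.write_text(">b\nmkl\n>a\nACD\nEFG\n")
        assert read_fasta(path) == [("b", "MKL"), ("a", "ACDEFG")]

    def test_duplicate_id_rejected_by_name(self, tmp_path):
        path = tmp_path / "dup.faa"
        path.write_text(">p1\nMKL\n>p1\nACD\n")
        with pytest.raises(FastaError, match="p1"):
            read_fasta(path)

    def test_illegal_residue_rejected(self, tmp_path):
        path = tmp_path / "bad.faa"
        path.write_text(">p1\nMK1L\n")
        with pytest.raises(FastaError, match="p1"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.faa"
        path.write_text("")
        with pytest.raises(FastaError):
            read_fasta(path)

    def test_round_trip(self, tmp_path):
        records = [("p1", "MKLACD"), ("p2", "WFQ")]
        path = tmp_path / "out.faa"
        write_fasta(path, records)
        assert read_fasta(path) == records


class TestAnnotations:
    def test_bed_is_half_open(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t10\t85\ttrnF\t0\t+\n")
        (gene,) = read_annotations(path)
        assert (gene.start, gene.end, gene.strand) == (10, 85, "+")

    def test_gff3_converted_to_same_internal_span(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\nchr1\ttest\ttRNA\t11\t85\t.\t+\t.\tID=trnF\n"
        )
        (gene,) = read_annotations(gff)
        assert (gene.start, gene.end, gene.strand) == (10, 85, "+")

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene_id\tseq_id\tstart\tend\tstrand\ntrnF\tchr1\t10\t85\t+\n")
        (gene,) = read_annotations(path)
        assert (gene.start, gene.end) == (10, 85)

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t10\t85\ttrnF\t0\t.\n")
        with pytest.raises((AnnotationError, ValueError)):
            read_annotations(path)

    def test_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t85\t10\ttrnF\t0\t+\n")
        with pytest.raises((AnnotationError, ValueError)):
            read_annotations(path)

    def test_missing_feature_type_lists_types_seen(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text("##gff-version 3\nchr1\ttest\tgene\t11\t85\t.\t+\t.\tID=g1\n")
        with pytest.raises(AnnotationError, match="gene"):
            read_annotations(gff)

    def test_round_trip_gff3_and_bed(self, tmp_path):
        genes = [
            TrnaGene("t1", "chr1", 10, 85, "+"),
            TrnaGene("t2", "chr1", 100, 172, "-"),
        ]
        gff = tmp_path / "x.gff3"
        bed = tmp_path / "x.bed"
        write_gff3(gff, genes)
        write_bed6(bed, genes)
        assert read_annotations(gff) == genes
        assert read_annotations(bed) == genes


class TestRunConfig:
    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(s_max=700, l_min=600)


class TestSurvey:
    @pytest.fixture()
    def survey_fasta(self, tmp_path, catalog):
        records = []
        for i in range(5):
            for ztype in ("TM_S", "BACTERIAL_S", "EUKARYOTIC_L"):
                seq, _ = synth_protein(ProteinSpec(ztype, seed=600 + i), catalog)
                records.append((f"{ztype}_{i}", seq))
        path = tmp_path / "survey.faa"
        write_fasta(path, records)
        return path

    def test_balanced_set_summary(self, survey_fasta):
        table, summary = run_survey(survey_fasta)
        assert summary == {"TM_S": 5, "BACTERIAL_S": 5, "EUKARYOTIC_L": 5}
        assert len(table) == 15

    def test_rerun_is_byte_identical(self, survey_fasta, tmp_path):
        out1 = tmp_path / "a.tsv"
        out2 = tmp_path / "b.tsv"
        run_survey(survey_fasta, out=out1)
        run_survey(survey_fasta, out=out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_empty_fasta_errors(self, tmp_path):
        path = tmp_path / "none.faa"
        path.write_text("")
        with pytest.raises(FastaError):
            run_survey(path)


class TestCli:
    def test_version(self):
        result = CliRunner().invoke(main, ["--version"])
        assert result.exit_code == 0

    def test_scan_emits_hit_table(self, tmp_path, catalog):
        seq, truth = synth_protein(ProteinSpec("TM_S", seed=700), catalog)
        fasta = tmp_path / "p.faa"
        write_fasta(fasta, [("p1", seq)])
        out = tmp_path / "hits.tsv"
        result = CliRunner().invoke(
            main, ["scan", "--fasta", str(fasta), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        header, *rows = out.read_text().strip().split("\n")
        assert header.split("\t") == [
            "protein_id", "motif", "start", "end", "matched", "mismatches",
        ]
        starts = {
            (r.split("\t")[1], int(r.split("\t")[2])) for r in rows
        }
        for name, (start, _) in truth.motifs.items():
            assert (name, start) in starts

    def test_classify_prints_summary(self, tmp_path, catalog):
        seq, _ = synth_protein(ProteinSpec("BACTERIAL_S", seed=701), catalog)
        fasta = tmp_path / "p.faa"
        write_fasta(fasta, [("p1", seq)])
        out = tmp_path / "typing.tsv"
        result = CliRunner().invoke(
            main, ["classify", "--fasta", str(fasta), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert json.loads(result.output.strip()) == {"BACTERIAL_S": 1}

    def test_census_end_to_end(self, tmp_path):
        genome, genes, _ = synth_genome(GenomeSpec(3, 2, 5, 10, seed=42))
        fasta = tmp_path / "cp.fa"
        gff = tmp_path / "cp.gff3"
        write_fasta(fasta, list(genome.items()))
        write_gff3(gff, genes)
        out = tmp_path / "row.tsv"
        per_gene = tmp_path / "genes.tsv"
        result = CliRunner().invoke(
            main,
            [
                "census", "--genome", str(fasta), "--annot", str(gff),
                "--label", "synthetic", "--out", str(out),
                "--per-gene", str(per_gene),
            ],
        )
        assert result.exit_code == 0, result.output
        header, row = out.read_text().strip().split("\n")
        values = dict(zip(header.split("\t"), row.split("\t")))
        assert values["n_CCA"] == "3" and values["percent"] == "50"
        assert len(per_gene.read_text().strip().split("\n")) == 21

    def test_simulate_proteins_deterministic(self, tmp_path):
        spec = tmp_path / "spec.json"
        spec.write_text(json.dumps([{"ztype": "TM_S", "seed": 4}]))
        outputs = []
        for name in ("a", "b"):
            out = tmp_path / f"{name}.faa"
            truth = tmp_path / f"{name}.json"
            result = CliRunner().invoke(
                main,
                [
                    "simulate", "proteins", "--spec", str(spec),
                    "--out", str(out), "--truth", str(truth),
                ],
            )
            assert result.exit_code == 0, result.output
            outputs.append(out.read_bytes() + truth.read_bytes())
        assert outputs[0] == outputs[1]
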