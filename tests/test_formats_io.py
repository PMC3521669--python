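import logging

import pytest
from hypothesis import given, strategies as st

from te_spread import formats_io as io


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestGenomicInterval:
    def test_valid(self):
        iv = io.GenomicInterval("chr1", 0, 10, "+")
        assert len(iv) == 10
        assert iv.midpoint == 5.0

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (10, 3)])
    def test_invalid_coordinates(self, start, end):
        with pytest.raises(ValueError):
            io.GenomicInterval("chr1", start, end)

    def test_empty_chrom_rejected(self):
        with pytest.raises(ValueError):
            io.GenomicInterval("", 0, 10)

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            io.GenomicInterval("chr1", 0, 10, "x")

    @given(st.integers(0, 10**6), st.integers(1, 10**4))
    def test_any_valid_pair_accepted(self, start, length):
        iv = io.GenomicInterval("c", start, start + length)
        assert iv.start < iv.end

    def test_overlaps(self):
        a = io.GenomicInterval("c", 0, 10)
        assert a.overlaps(io.GenomicInterval("c", 9, 20))
        assert not a.overlaps(io.GenomicInterval("c", 10, 20))
        assert not a.overlaps(io.GenomicInterval("d", 0, 10))


class TestCytosineRecord:
    def test_meth_gt_total_rejected(self):
        with pytest.raises(ValueError):
            io.CytosineRecord("chr1", 5, "+", "CG", 5, 4)

    def test_ok(self):
        r = io.CytosineRecord("chr1", 5, "-", "CHH", 2, 7)
        assert r.total_count == 7


class TestReadAlignment:
    def test_tails_exceed_query(self):
        with pytest.raises(ValueError):
            io.ReadAlignment("r", 60, io.GenomicInterval("c", 0, 80),
                             99.0, 30, 30, True)


# ---------------------------------------------------------------------------
# context helper
# ---------------------------------------------------------------------------

class TestContextAt:
    @pytest.mark.parametrize("seq,pos,expected", [
        ("ACGTA", 1, "CG"),
        ("ACCGA", 1, "CHG"),   # C with H=C then G
        ("ACATA", 1, "CHH"),
        ("CGTAA", 0, "CG"),
    ])
    def test_forward(self, seq, pos, expected):
        assert io.context_at(seq, pos, "+") == expected

    def test_reverse_strand(self):
        # forward ...ACG...: the G at index 2 is a C on - strand, and the
        # reverse complement context reads CGT -> CG
        assert io.context_at("TACGT", 3, "-") == "CG"
        # forward CAG: G at index 2 -> revcomp CTG -> CHG
        assert io.context_at("TCAGT", 3, "-") == "CHG"
        # forward TTG: G at index 2 -> revcomp CAA -> CHH
        assert io.context_at("TTTGT", 3, "-") == "CHH"

    def test_not_a_c(self):
        with pytest.raises(ValueError):
            io.context_at("AAAA", 0, "+")

    def test_edge_undefined(self):
        with pytest.raises(IndexError):
            io.context_at("AAC", 2, "+")


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

class TestReadRepeats:
    def test_bed_line(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t999\t2000\tfamA|RLG|c1\t.\t+\n")
        (rep,) = io.read_repeats(path, "BED")
        assert rep.interval.start == 999
        assert rep.interval.end == 2000
        assert rep.family_id == "famA"
        assert rep.superfamily == "RLG"
        assert rep.copy_id == "c1"

    def test_gff3_coordinate_conversion(self, tmp_path):
        path = tmp_path / "r.gff3"
        path.write_text("chr1\tsrc\trepeat\t1000\t2000\t.\t+\t.\t"
                        "ID=c1;family=famA;superfamily=RLG\n")
        (rep,) = io.read_repeats(path, "GFF3")
        assert rep.interval.start == 999
        assert rep.interval.end == 2000

    def test_gff3_start_one_becomes_zero(self, tmp_path):
        path = tmp_path / "r.gff3"
        path.write_text("chr1\tsrc\trepeat\t1\t50\t.\t+\t.\t"
                        "ID=c1;family=f\n")
        (rep,) = io.read_repeats(path, "GFF3")
        assert rep.interval.start == 0

    def test_empty_file(self, tmp_path, caplog):
        path = tmp_path / "r.bed"
        path.write_text("")
        with caplog.at_level(logging.WARNING):
            assert io.read_repeats(path) == []
        assert any("empty" in m for m in caplog.messages)

    def test_missing_family_rejected_and_logged(self, tmp_path, caplog):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\tnofamilytag\t.\t+\n"
                        "chr1\t200\t300\tfamA|RLG|c1\t.\t+\n")
        with caplog.at_level(logging.WARNING):
            reps = io.read_repeats(path)
        assert len(reps) == 1
        assert any("rejected" in m for m in caplog.messages)

    def test_malformed_line_carries_line_number(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\tfamA|RLG|c1\t.\t+\n"
                        "chr1\tnotanint\t3\tfamB|RLG|c2\t.\t+\n")
        with pytest.raises(io.FormatError) as err:
            io.read_repeats(path)
        assert ":2" in str(err.value)

    def test_duplicate_copy_id(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\tfamA|RLG|c1\t.\t+\n"
                        "chr1\t200\t300\tfamA|RLG|c1\t.\t+\n")
        with pytest.raises(io.FormatError, match="duplicate"):
            io.read_repeats(path)

    def test_sorted_output(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr2\t0\t10\tf|RLG|a\t.\t+\n"
                        "chr1\t50\t60\tf|RLG|b\t.\t+\n"
                        "chr1\t0\t10\tf|RLG|c\t.\t+\n")
        reps = io.read_repeats(path)
        keys = [(r.interval.chrom, r.interval.start) for r in reps]
        assert keys == sorted(keys)

    def test_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "rt.bed"
        io.write_repeats_bed(small_bundle.repeats, path)
        again = io.read_repeats(path)
        assert again == small_bundle.repeats


# ---------------------------------------------------------------------------
# probes + signals
# ---------------------------------------------------------------------------

def _write_probe_files(tmp_path, signal_rows):
    probe_path = tmp_path / "p.tsv"
    probe_path.write_text(
        "probe_id\tchrom\tstart\tend\tsingle_copy\n"
        "p1\tchr1\t100\t150\t1\n"
        "p2\tchr1\t300\t350\t0\n")
    signal_path = tmp_path / "s.tsv"
    header = "probe_id\tmark\tgenotype\ttissue\treplicate\tlog_ratio\n"
    signal_path.write_text(header + "".join(signal_rows))
    return probe_path, signal_path


class TestReadProbeSignals:
    def test_three_replicates_joined(self, tmp_path):
        rows = [f"p1\t5mC\tB73\tleaf\t{i}\t0.{i}\n" for i in (1, 2, 3)]
        pp, sp = _write_probe_files(tmp_path, rows)
        probes = io.read_probe_signals(pp, sp)
        by_id = {p.probe_id: p for p in probes}
        assert len(by_id["p1"].signals[("5mC", "B73", "leaf")]) == 3
        # probe with no signal retained with empty map
        assert by_id["p2"].signals == {}

    def test_duplicate_row_errors(self, tmp_path):
        rows = ["p1\t5mC\tB73\tleaf\t1\t0.1\n",
                "p1\t5mC\tB73\tleaf\t1\t0.2\n"]
        pp, sp = _write_probe_files(tmp_path, rows)
        with pytest.raises(io.FormatError, match="duplicate"):
            io.read_probe_signals(pp, sp)

    def test_unknown_probe_id_errors(self, tmp_path):
        rows = ["zzz\t5mC\tB73\tleaf\t1\t0.1\n"]
        pp, sp = _write_probe_files(tmp_path, rows)
        with pytest.raises(io.FormatError, match="zzz"):
            io.read_probe_signals(pp, sp)

    def test_single_copy_flag_zero(self, tmp_path):
        pp, sp = _write_probe_files(tmp_path, [])
        probes = {p.probe_id: p for p in io.read_probe_signals(pp, sp)}
        assert probes["p1"].single_copy is True
        assert probes["p2"].single_copy is False

    def test_round_trip(self, tmp_path, small_bundle):
        pp = tmp_path / "p.tsv"
        sp = tmp_path / "s.tsv"
        probes = small_bundle.probes[:40]
        io.write_probes_tsv(probes, pp)
        io.write_signals_tsv(probes, sp)
        again = io.read_probe_signals(pp, sp)
        assert len(again) == len(probes)
        by_id = {p.probe_id: p for p in again}
        for p in probes:
            q = by_id[p.probe_id]
            assert q.interval == p.interval
            assert q.single_copy == p.single_copy
            for key, values in p.signals.items():
                assert q.signals[key] == pytest.approx(values, abs=1e-6)


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

class TestCytosineReport:
    GENOME = {"chr1": "AACGTACCGATCATG"}
    #                  012345678901234

    def _write(self, tmp_path, body):
        path = tmp_path / "cx.tsv"
        path.write_text(
            "chrom\tposition\tstrand\tcontext\tmeth_count\ttotal_count\n"
            + body)
        return path

    def test_context_recomputed_cg(self, tmp_path):
        path = self._write(tmp_path, "chr1\t2\t+\t.\t3\t5\n")
        (rec,) = io.read_cytosine_report(path, self.GENOME)
        assert rec.context == "CG"

    def test_context_mismatch_errors(self, tmp_path):
        path = self._write(tmp_path, "chr1\t2\t+\tCHH\t3\t5\n")
        with pytest.raises(io.FormatError, match="mismatch"):
            io.read_cytosine_report(path, self.GENOME)

    def test_not_a_c_errors(self, tmp_path):
        path = self._write(tmp_path, "chr1\t0\t+\tCG\t1\t2\n")
        with pytest.raises(io.FormatError):
            io.read_cytosine_report(path, self.GENOME)

    def test_meth_exceeds_total(self, tmp_path):
        path = self._write(tmp_path, "chr1\t2\t+\tCG\t5\t4\n")
        with pytest.raises(io.FormatError):
            io.read_cytosine_report(path, self.GENOME)

    def test_minus_strand_context(self, tmp_path):
        # position 3 is G; revcomp of positions 1..3 (ACG) is CGT -> CG
        path = self._write(tmp_path, "chr1\t3\t-\t.\t1\t2\n")
        (rec,) = io.read_cytosine_report(path, self.GENOME)
        assert rec.context == "CG"

    def test_round_trip(self, tmp_path):
        records = [io.CytosineRecord("chr1", 2, "+", "CG", 3, 5),
                   io.CytosineRecord("chr1", 3, "-", "CG", 0, 7)]
        path = tmp_path / "cx.tsv"
        io.write_cytosine_report(records, path)
        assert io.read_cytosine_report(path) == records


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


class TestReadAlignmentsSAM:
    def test_full_match_identity(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_HEADER +
                        "r1\t0\tchr1\t501\t60\t100M\t*\t0\t0\t" +
                        "A" * 100 + "\t*\tNM:i:3\n")
        (aln,) = io.read_alignments(path, "SAM")
        assert aln.identity_pct == pytest.approx(97.0)
        assert aln.interval.start == 500
        assert aln.interval.end == 600

    def test_soft_clip_tails(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_HEADER +
                        "r1\t0\tchr1\t501\t60\t30S70M\t*\t0\t0\t" +
                        "A" * 100 + "\t*\tNM:i:0\n")
        (aln,) = io.read_alignments(path, "SAM")
        assert aln.left_unaligned == 30
        assert aln.right_unaligned == 0
        assert len(aln.interval) == 70
        assert aln.query_length == 100

    def test_secondary_dropped_in_unique_mode(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_HEADER +
                        "r1\t256\tchr1\t501\t60\t50M\t*\t0\t0\t" +
                        "A" * 50 + "\t*\tNM:i:0\n")
        assert io.read_alignments(path, "SAM", unique_only=True) == []

    def test_missing_nm_instructs_tsv(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(SAM_HEADER +
                        "r1\t0\tchr1\t501\t60\t50M\t*\t0\t0\t" +
                        "A" * 50 + "\t*\n")
        with pytest.raises(io.FormatError, match="TSV"):
            io.read_alignments(path, "SAM")


class TestReadAlignmentsTSV:
    def test_round_trip(self, tmp_path):
        alns = [io.ReadAlignment("r1", 120, io.GenomicInterval("c", 5, 86),
                                 96.5, 30, 9, True)]
        path = tmp_path / "a.tsv"
        io.write_alignments_tsv(alns, path)
        assert io.read_alignments(path, "TSV") == alns

    def test_non_unique_filtered(self, tmp_path):
        alns = [io.ReadAlignment("r1", 50, io.GenomicInterval("c", 0, 50),
                                 100.0, 0, 0, False)]
        path = tmp_path / "a.tsv"
        io.write_alignments_tsv(alns, path)
        assert io.read_alignments(path, "TSV", unique_only=True) == []


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

class TestGenes:
    def test_read_write_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "g.gff3"
        io.write_genes_gff3(small_bundle.genes, path)
        again = io.read_genes(path)
        assert len(again) == len(small_bundle.genes)
        by_id = {g.gene_id: g for g in again}
        for g in small_bundle.genes:
            q = by_id[g.gene_id]
            assert q.interval == g.interval
            assert q.exon_length_bp == g.exon_length_bp

    def test_overlapping_exons_merged(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t101\t250\t.\t+\t.\tID=e1;Parent=g1\n"
            "chr1\tx\texon\t201\t400\t.\t+\t.\tID=e2;Parent=g1\n")
        (gene,) = io.read_genes(path)
        assert len(gene.exons) == 1
        assert gene.exon_length_bp == 300

    def test_fasta_round_trip(self, tmp_path):
        genome = {"chr1": "ACGTACGTAA", "chr2": "GGGCCC"}
        path = tmp_path / "g.fa"
        io.write_fasta(genome, path, width=4)
        assert io.read_fasta(path) == genome
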