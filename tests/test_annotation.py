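"""Transcript-model construction, region derivation, and GTF loading."""

import numpy as np
import pytest

from riboterm.annotation import (
    STOP_CODONS,
    AnnotationError,
    TranscriptModel,
    derive_regions,
    find_next_inframe_stop,
    load_gtf_models,
    load_transcript_table,
    reverse_complement,
    write_transcript_table,
)
from riboterm.simulate import SimulationParams, simulate_transcriptome

from conftest import TOY_SEQ


class TestTranscriptModel:
    def test_valid_toy(self, toy_model):
        assert toy_model.validate() is None
        assert toy_model.ntc_start == 20

    def test_rna_input_folded_to_dna(self):
        tm = TranscriptModel("r1", 21, 0, 21, "AUG" + "GCU" * 5 + "UAA")
        assert tm.validate() is None
        assert tm.sequence.endswith("TAA")

    @pytest.mark.parametrize(
        "cds_start,cds_end,seq_tail,reason",
        [
            (5, 24, None, "cds_not_codon_multiple"),
            (5, 23, "CCC", "no_terminal_stop"),  # replace NTC with CCC
            (0, 9, None, "cds_too_short"),
        ],
    )
    def test_invariant_violations(self, cds_start, cds_end, seq_tail, reason):
        seq = TOY_SEQ
        if seq_tail is not None:
            seq = seq[:20] + seq_tail + seq[23:]
        tm = TranscriptModel("bad", len(seq), cds_start, cds_end, seq)
        assert tm.validate() == reason


class TestNextInframeStop:
    def test_stop_one_codon_downstream(self, toy_model):
        # 3'UTR reads AAA TGA ... -> first in-frame stop at cds_end + 3
        assert find_next_inframe_stop(toy_model) == toy_model.cds_end + 3

    def test_immediate_stop_gives_zero_length_extension(self):
        seq = "ATG" + "GCA" * 5 + "TAA" + "TGA" + "CCCCCC"
        tm = TranscriptModel("t", len(seq), 0, 21, seq)
        assert find_next_inframe_stop(tm) == 21

    def test_out_of_frame_stop_not_found(self):
        # 3'UTR contains TGA only shifted out of the CDS frame
        utr3 = "CTGACC" + "CCC" * 4  # TGA at offset 1, out of frame
        seq = "ATG" + "GCA" * 5 + "TAA" + utr3
        tm = TranscriptModel("t", len(seq), 0, 21, seq)
        for pos in range(21, tm.length - 2, 3):
            assert seq[pos : pos + 3] not in STOP_CODONS
        assert find_next_inframe_stop(tm) is None

    def test_agrees_with_bruteforce_on_random_transcripts(self):
        params = SimulationParams(n_transcripts=1000)
        for tm in simulate_transcriptome(params, 7):
            expected = None
            for pos in range(tm.cds_end, tm.length - 2, 3):
                codon = tm.sequence[pos] + tm.sequence[pos + 1] + tm.sequence[pos + 2]
                if codon in ("TAA", "TAG", "TGA"):
                    expected = pos
                    break
            assert find_next_inframe_stop(tm) == expected, tm.transcript_id


class TestDeriveRegions:
    def test_interval_arithmetic(self):
        # CDS [10, 310): body [25, 298), stop codon [307, 310)
        seq = "G" * 10 + "ATG" + "GCA" * 98 + "TAA" + "C" * 40
        tm = TranscriptModel("t", len(seq), 10, 310, seq)
        rs = derive_regions(tm)
        assert rs.cds == (10, 310)
        assert rs.cds_body == (25, 298)
        assert rs.stop_codon == (307, 310)
        assert rs.pause_eligible

    def test_short_cds_flagged_pause_ineligible(self):
        seq = "ATG" + "GCA" * 4 + "TAA" + "C" * 30  # 18 nt CDS
        tm = TranscriptModel("t", len(seq), 0, 18, seq)
        rs = derive_regions(tm)
        assert not rs.pause_eligible
        assert rs.cds_body[0] == rs.cds_body[1]

    def test_extension_interval(self, toy_model):
        rs = derive_regions(toy_model)
        assert rs.extension == (23, 26)
        assert (rs.next_stop_start - toy_model.cds_end) % 3 == 0

    def test_regions_never_overlap(self):
        params = SimulationParams(n_transcripts=200)
        for tm in simulate_transcriptome(params, 11):
            rs = derive_regions(tm)
            assert rs.cds_body[1] <= rs.stop_codon[0]
            if rs.extension is not None:
                assert rs.extension[0] >= rs.cds[1]
                assert (rs.extension[1] - rs.extension[0]) % 3 == 0

    def test_invalid_model_rejected(self):
        tm = TranscriptModel("bad", 30, 0, 21, "A" * 30)
        with pytest.raises(AnnotationError):
            derive_regions(tm)


class TestLoading:
    def test_table_roundtrip(self, tmp_path, toy_model):
        path = tmp_path / "tx.tsv"
        write_transcript_table([toy_model], path)
        models, report = load_transcript_table(path)
        assert models == [toy_model]
        assert report.n_loaded == 1 and report.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path, toy_model):
        bad = TranscriptModel("bad", len(TOY_SEQ), 5, 23, TOY_SEQ[:20] + "CCC" + TOY_SEQ[23:])
        path = tmp_path / "tx.tsv"
        write_transcript_table([toy_model, bad], path)
        models, report = load_transcript_table(path)
        assert [m.transcript_id for m in models] == ["toy1"]
        assert report.dropped_by_reason == {"no_terminal_stop": 1}

    def _write_minus_strand_toy(self, tmp_path):
        """Two-exon minus-strand toy: transcript == revcomp of the
        genomic exon concatenation, stop_codon annotated separately."""
        # transcript exon A = positions 0..29, exon B = 30..59
        genome = (
            reverse_complement(TOY_SEQ[30:])  # genomic 1..30 (exon B)
            + "A" * 10                        # intron 31..40
            + reverse_complement(TOY_SEQ[:30])  # genomic 41..70 (exon A)
        )
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + genome + "\n")
        # transcript coord t on exon A maps to genomic 70 - t (1-based)
        lines = []
        attrs = 'gene_id "g1"; transcript_id "tx1";'
        for feat, start, end in [
            ("transcript", 1, 70),
            ("exon", 41, 70),
            ("exon", 1, 30),
            ("CDS", 51, 65),        # transcript 5..19 (CDS minus stop)
            ("stop_codon", 48, 50),  # transcript 20..22
        ]:
            lines.append(f"chr1\ttoy\t{feat}\t{start}\t{end}\t.\t-\t.\t{attrs}")
        gtf = tmp_path / "toy.gtf"
        gtf.write_text("\n".join(lines) + "\n")
        return gtf, fasta

    def test_minus_strand_gtf_matches_hand_construction(self, tmp_path, toy_model):
        gtf, fasta = self._write_minus_strand_toy(tmp_path)
        models, report = load_gtf_models(gtf, fasta)
        assert report.n_loaded == 1
        (m,) = models
        assert m.sequence == TOY_SEQ
        assert (m.cds_start, m.cds_end, m.length) == (5, 23, 60)

    def test_gtf_route_equals_table_route(self, tmp_path, toy_model):
        gtf, fasta = self._write_minus_strand_toy(tmp_path)
        (gtf_model,) = load_gtf_models(gtf, fasta)[0]
        table = tmp_path / "tx.tsv"
        write_transcript_table([toy_model], table)
        (table_model,) = load_transcript_table(table)[0]
        assert gtf_model == TranscriptModel(
            "tx1", table_model.length, table_model.cds_start,
            table_model.cds_end, table_model.sequence,
        )

    def test_malformed_table_raises_with_context(self, tmp_path):
        path = tmp_path / "junk.tsv"
        path.write_text("transcript_id\tlength\n")
        with pytest.raises(AnnotationError, match="missing columns"):
            load_transcript_table(path)
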