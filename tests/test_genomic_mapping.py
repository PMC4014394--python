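"""Coordinate projection, codon expansion, sequence relocation and the
element-to-protein mapping rules."""
import numpy as np
import pytest

from scestruct import genomic_mapping as gm
from scestruct.types import (
    ExclusionRecord,
    GenomicInterval,
    SCERecord,
    SFBSRecord,
    TranscriptModel,
    TranscriptSet,
)


def per_base_oracle(interval, transcript):
    """Independent oracle: project every genomic position separately."""
    offsets = []
    for g in range(interval.start, interval.end):
        acc = 0
        for block in transcript.cds_blocks:
            if block.start <= g < block.end:
                if transcript.strand == "+":
                    offsets.append(acc + g - block.start)
                else:
                    offsets.append(acc + block.end - 1 - g)
            acc += block.length
    return offsets


class TestProjectInterval:
    def test_plus_strand_offset_arithmetic(self, plus_transcript):
        t = TranscriptModel(
            transcript_id="t1", gene_id="g1", strand="+",
            exons=(GenomicInterval("c", 1000, 1100, "+"),),
            cds_blocks=(GenomicInterval("c", 1000, 1100, "+"),),
            cds_sequence="A" * 100, protein_sequence="X",
        )
        p = gm.project_interval_to_cds(GenomicInterval("c", 1010, 1019, "+"), t)
        assert (p.cds_start, p.cds_end) == (10, 19)
        assert p.clipped_nt == 0

    def test_intron_spanning_interval(self, plus_transcript):
        iv = GenomicInterval("chrT", 120, 210, "+")  # 10 nt exon1 + 10 nt exon2
        p = gm.project_interval_to_cds(iv, plus_transcript)
        oracle = per_base_oracle(iv, plus_transcript)
        assert p.covered_nt == len(oracle) == 20
        assert (p.cds_start, p.cds_end) == (min(oracle), max(oracle) + 1)
        assert p.clipped_nt == 70  # the intron

    def test_minus_strand_maps_3prime_genomic_to_small_offsets(
        self, minus_transcript
    ):
        # genomically-last block (400,430) is the transcript 5' end
        iv = GenomicInterval("chrT", 420, 430, "-")
        p = gm.project_interval_to_cds(iv, minus_transcript)
        oracle = per_base_oracle(iv, minus_transcript)
        assert (p.cds_start, p.cds_end) == (min(oracle), max(oracle) + 1)
        assert p.cds_start == 0

    def test_minus_strand_random_intervals_match_oracle(self, minus_transcript):
        rng = np.random.default_rng(31)
        for _ in range(50):
            s = int(rng.integers(290, 435))
            e = s + int(rng.integers(1, 40))
            iv = GenomicInterval("chrT", s, e, "-")
            oracle = per_base_oracle(iv, minus_transcript)
            if not oracle:
                with pytest.raises(gm.OutsideCdsError):
                    gm.project_interval_to_cds(iv, minus_transcript)
                continue
            p = gm.project_interval_to_cds(iv, minus_transcript)
            assert (p.cds_start, p.cds_end) == (min(oracle), max(oracle) + 1)
            assert p.covered_nt == len(oracle)

    def test_outside_cds_errors(self, plus_transcript):
        with pytest.raises(gm.OutsideCdsError):
            gm.project_interval_to_cds(
                GenomicInterval("chrT", 140, 160, "+"), plus_transcript
            )


class TestCdsRangeToResidues:
    @pytest.mark.parametrize(
        "cds_range, residues",
        [
            ((0, 27), (0, 9)),  # nine whole codons
            ((4, 10), (1, 4)),  # partial codons at both ends
            ((26, 27), (8, 9)),  # single-nt edge
            ((3, 4), (1, 2)),
        ],
    )
    def test_examples(self, cds_range, residues):
        assert gm.cds_range_to_residues(*cds_range) == residues

    def test_matches_codon_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = int(rng.integers(0, 300))
            b = a + int(rng.integers(1, 100))
            codons = {nt // 3 for nt in range(a, b)}
            assert gm.cds_range_to_residues(a, b) == (min(codons), max(codons) + 1)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            gm.cds_range_to_residues(5, 5)


class TestLocateElement:
    CDS = "ATGGCTACGTTTAAAGGGCCCAGTACCATTGACGAGTGGCATAAGCGA"

    def test_exact_substring(self):
        elem = self.CDS[9:27]
        out = gm.locate_element_in_cds(elem, self.CDS)
        assert out.status == "exact"
        assert (out.cds_start, out.cds_end) == (9, 27)

    def test_exact_at_predicted_offset_preferred(self):
        out = gm.locate_element_in_cds(self.CDS[9:27], self.CDS, predicted_offset=9)
        assert out.status == "exact"
        assert out.cds_start == 9

    def test_single_mismatch_aligned(self):
        elem = list(self.CDS[9:30])
        elem[10] = "A" if elem[10] != "A" else "C"
        out = gm.locate_element_in_cds("".join(elem), self.CDS)
        assert out.status == "aligned"
        assert out.identity == pytest.approx((len(elem) - 1) / len(elem))
        assert out.max_gap_run == 0

    def test_two_nt_gap_rejected(self):
        # deleting 2 consecutive nt forces a 2-nt gap run in any alignment
        elem = self.CDS[6:36]
        broken = elem[:12] + elem[14:]
        out = gm.locate_element_in_cds(broken, self.CDS)
        assert out.status == "rejected"

    def test_many_mismatches_rejected(self):
        rng = np.random.default_rng(7)
        elem = "".join(rng.choice(list("ACGT"), size=30))
        out = gm.locate_element_in_cds(elem, self.CDS)
        assert out.status == "rejected"

    def test_identity_tracks_planted_mismatch_count(self):
        # internal mismatches only: a local alignment trims terminal
        # mismatches, which lowers identity below the planted count
        rng = np.random.default_rng(9)
        for k in (1, 2, 3):
            elem = list(self.CDS[6:36])
            pos = rng.choice(np.arange(5, 25), size=k, replace=False)
            for p in pos:
                elem[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[elem[p]]
            out = gm.locate_element_in_cds("".join(elem), self.CDS)
            expected_identity = (30 - k) / 30
            if expected_identity >= 0.9:
                assert out.status == "aligned"
                assert out.identity == pytest.approx(expected_identity)
            else:
                assert out.status == "rejected"


def _record(gene_id, intervals, window=9, eid="e1"):
    return SCERecord(
        element_id=eid, window_codons=window, gene_id=gene_id,
        intervals=tuple(intervals),
    )


class TestMapElement:
    def test_canonical_preference(self, plus_transcript):
        minor = TranscriptModel(
            transcript_id="txp_minor", gene_id="gplus", strand="+",
            exons=plus_transcript.exons, cds_blocks=plus_transcript.cds_blocks,
            cds_sequence=plus_transcript.cds_sequence,
            protein_sequence=plus_transcript.protein_sequence,
            protein_id="minor_p", is_canonical=False,
        )
        tset = TranscriptSet([minor, plus_transcript])
        rec = _record("gplus", [GenomicInterval("chrT", 103, 130, "+")])
        seg = gm.map_element_to_protein(rec, tset)
        assert seg.protein_id == plus_transcript.protein_id

    def test_oversized_protein_excluded(self, plus_transcript):
        big = TranscriptModel(
            transcript_id="big", gene_id="gbig", strand="+",
            exons=(GenomicInterval("c", 0, 36000, "+"),),
            cds_blocks=(GenomicInterval("c", 0, 36000, "+"),),
            cds_sequence="ACG" * 12000, protein_sequence="T" * 12000,
        )
        tset = TranscriptSet([big])
        rec = _record("gbig", [GenomicInterval("c", 300, 327, "+")])
        out = gm.map_element_to_protein(rec, tset)
        assert isinstance(out, ExclusionRecord)
        assert "longer than 10000" in " ".join(out.reasons.values())

    def test_mid_codon_window_gains_a_residue(self, plus_transcript):
        # 9-codon element starting 1 nt into a codon covers 10 residues
        rec = _record("gplus", [GenomicInterval("chrT", 104, 130, "+"),
                                GenomicInterval("chrT", 200, 201, "+")])
        seg = gm.map_element_to_protein(rec, TranscriptSet([plus_transcript]))
        assert seg.length == 10
        assert (seg.start, seg.end) == (1, 11)

    def test_untranslatable_transcript_skipped(self, plus_transcript):
        broken = TranscriptModel(
            transcript_id="broken", gene_id="gplus", strand="+",
            exons=plus_transcript.exons, cds_blocks=plus_transcript.cds_blocks,
            cds_sequence=plus_transcript.cds_sequence + "AC",
            protein_sequence="", is_canonical=True, translation_ok=False,
            notes="CDS length not divisible by 3",
        )
        tset = TranscriptSet([broken, plus_transcript])
        rec = _record("gplus", [GenomicInterval("chrT", 103, 130, "+")])
        seg = gm.map_element_to_protein(rec, tset)
        assert seg.protein_id == plus_transcript.protein_id

    def test_sequence_verification_falls_back_to_alignment(self, plus_transcript):
        tset = TranscriptSet([plus_transcript])
        rec = _record("gplus", [GenomicInterval("chrT", 103, 130, "+")])
        true_seq = plus_transcript.cds_sequence[3:30]
        mutated = "T" + true_seq[1:]
        if mutated == true_seq:
            mutated = "G" + true_seq[1:]
        seg = gm.map_element_to_protein(rec, tset, element_seq=mutated)
        assert not isinstance(seg, ExclusionRecord)
        heavily = "TTTTTTTTTT" + true_seq[10:]
        out = gm.map_element_to_protein(rec, tset, element_seq=heavily)
        assert isinstance(out, ExclusionRecord)

    def test_deterministic(self, toy_transcript_set):
        rec = _record("gminus", [GenomicInterval("chrT", 410, 425, "-")], window=15)
        a = gm.map_element_to_protein(rec, toy_transcript_set)
        b = gm.map_element_to_protein(rec, toy_transcript_set)
        assert a == b


class TestMapSfbs:
    def test_ordinary_site_single_segment(self, toy_transcript_set):
        site = SFBSRecord(
            site_id="s1", gene_id="gplus",
            interval=GenomicInterval("chrT", 106, 115, "+"),
            factor_name="SRSF1",
        )
        out = gm.map_sfbs(site, toy_transcript_set)
        assert isinstance(out, list) and len(out) == 1
        assert out[0].provenance == "SFBS"

    def test_dual_frame_site_two_segments(self):
        from scestruct.synthetic_data import SyntheticConfig, generate_study

        bundle = generate_study(
            SyntheticConfig(n_genes=5, sce_counts={}, seed=2)
        )
        dual_sites = [
            s for s in bundle.sfbs_records if s.site_id.startswith("sfbs_dual")
        ]
        assert dual_sites
        out = gm.map_sfbs(dual_sites[0], bundle.transcripts)
        assert isinstance(out, list) and len(out) == 2
        pep = {
            bundle.proteome[s.protein_id][s.start : s.end] for s in out
        }
        assert len(pep) == 2  # distinct residue content in the two frames

    def test_unmappable_site_excluded(self, toy_transcript_set):
        site = SFBSRecord(
            site_id="s2", gene_id="gplus",
            interval=GenomicInterval("chrT", 150, 160, "+"),  # intronic
            factor_name="SRSF1",
        )
        out = gm.map_sfbs(site, toy_transcript_set)
        assert isinstance(out, ExclusionRecord)


class TestRoundTripInvariant:
    def test_residue_range_reprojects_with_codon_slack(self, small_bundle):
        """For exact matches the emitted residue range, re-projected to CDS
        space, contains the element's CDS range with <= 2 nt slack per end."""
        from scestruct.enrichment_pipelines import map_sce_datasets
        from scestruct.genomic_mapping import project_element_to_cds

        segments, _ = map_sce_datasets(
            small_bundle.sce_records,
            small_bundle.transcripts,
            small_bundle.element_seqs,
        )
        checked = 0
        for w, segs in segments.items():
            recs = {r.element_id: r for r in small_bundle.sce_records[w]}
            for seg in segs:
                rec = recs[seg.source_element_id]
                tx = small_bundle.transcripts.canonical(rec.gene_id)
                proj = project_element_to_cds(rec.intervals, tx)
                re_start, re_end = 3 * seg.start, 3 * seg.end
                assert re_start <= proj.cds_start <= re_start + 2
                assert re_end - 2 <= proj.cds_end <= re_end
                checked += 1
        assert checked == sum(len(s) for s in segments.values())
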