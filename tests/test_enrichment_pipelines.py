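"""Study-level pipelines: orchestration logic, classification rules, filter
bookkeeping, and reproducibility."""
import numpy as np
import pytest

from scestruct import report
from scestruct.enrichment_pipelines import (
    classify_overlap,
    count_peptide_overlaps,
    map_sce_datasets,
    measure_segments,
    peptides_from_segments,
    run_disprot_analysis,
    run_sce_comparison,
    run_sfbs_analysis,
    run_window_correlation,
)
from scestruct.types import EXPECTED_SIGN, PROPERTIES, SegmentProperties


@pytest.fixture(scope="module")
def mapped_small(small_bundle):
    segments, exclusions = map_sce_datasets(
        small_bundle.sce_records, small_bundle.transcripts,
        small_bundle.element_seqs,
    )
    return segments, exclusions


@pytest.fixture(scope="module")
def medium_study():
    """A mid-size planted study: large enough for the rarer low-complexity
    events to carry statistical power."""
    from scestruct.synthetic_data import (
        SyntheticConfig,
        annotations_from_truth,
        generate_study,
    )

    bundle = generate_study(
        SyntheticConfig(n_genes=150, sce_counts={9: 150, 15: 150, 30: 150}, seed=77)
    )
    annotations = annotations_from_truth(bundle)
    segments, _ = map_sce_datasets(
        bundle.sce_records, bundle.transcripts, bundle.element_seqs
    )
    return bundle, annotations, segments


class TestSceComparison:
    def test_planted_study_recovers_all_four_signs(self, medium_study):
        _, annotations, segments = medium_study
        res = run_sce_comparison(segments, annotations, seed=3)
        for prop in PROPERTIES:
            t = res.tests[9][prop]
            assert t["direction"] == EXPECTED_SIGN[prop]
            assert t["significant"], (prop, t["chi_square"].p_value)

    def test_reference_drawn_from_sce_containing_proteins_only(
        self, small_annotations, mapped_small
    ):
        segments, _ = mapped_small
        res = run_sce_comparison(segments, small_annotations, seed=3)
        # reproduce the draw: hosts must be proteins that carry a 9-codon SCE
        from scestruct.segment_analysis import (
            SamplingPlan,
            sample_reference_segments,
        )
        from scestruct.enrichment_pipelines import _child_seed

        hosts = {s.protein_id for s in segments[9]}
        plan = SamplingPlan(
            [s.length for s in segments[9]],
            {pid: len(small_annotations[pid]) for pid in sorted(hosts)},
            seed=_child_seed(3, 9),
        )
        for seg in sample_reference_segments(plan):
            assert seg.protein_id in hosts

    def test_single_segment_dataset_flags_low_power(
        self, small_annotations, mapped_small
    ):
        segments, _ = mapped_small
        res = run_sce_comparison({9: segments[9][:1]}, small_annotations, seed=1)
        assert any("low power" in n for n in res.notes)

    def test_same_seed_reproduces_every_number(
        self, small_annotations, mapped_small
    ):
        segments, _ = mapped_small
        a = run_sce_comparison(segments, small_annotations, seed=11)
        b = run_sce_comparison(segments, small_annotations, seed=11)
        assert report.result_summary(a) == report.result_summary(b)

    def test_bonferroni_threshold_recorded(self, small_annotations, mapped_small):
        segments, _ = mapped_small
        res = run_sce_comparison(segments, small_annotations, seed=2)
        assert res.metadata["bonferroni_threshold"] == pytest.approx(0.0125)


class TestWindowCorrelation:
    def test_planted_trend_signs(self, medium_study):
        _, annotations, segments = medium_study
        props = {
            w: [p for _, p in measure_segments(segments[w], annotations)]
            for w in segments
        }
        res = run_window_correlation(props)
        assert res.correlations["disorder"] == pytest.approx(-1.0)
        assert res.correlations["secondary_structure"] == pytest.approx(1.0)
        # low-complexity content is rare at the coarser windows, so its 90th
        # percentile can tie at 0 between windows 15 and 30; the correlation
        # is negative but not always exactly -1 at this scale
        lc = res.correlations["low_complexity"]
        assert lc is None or lc < 0
        assert "domain" not in res.correlations
        for prop in PROPERTIES:
            assert "kruskal_wallis" in res.tests[prop]
            assert len(res.tests[prop]["dunn"]) == 3

    def test_constant_descriptives_reported_as_no_trend(self):
        const = SegmentProperties(0.4, 0.4, 0.4, 0.4, False, False, False, False)
        props = {w: [const] * 5 for w in (9, 15, 30)}
        res = run_window_correlation(props)
        assert res.correlations["disorder"] is None
        assert any("no trend" in n for n in res.notes)

    def test_missing_window_errors(self):
        const = SegmentProperties(0.4, 0.4, 0.4, 0.4, False, False, False, False)
        with pytest.raises(ValueError):
            run_window_correlation({9: [const], 15: [const]})


class TestOverlapClassification:
    @pytest.mark.parametrize(
        "segment, expected",
        [
            ((10, 20), "complete"),
            ((15, 30), "partial"),
            ((25, 40), "none"),
        ],
    )
    def test_interval_logic(self, segment, expected):
        assert classify_overlap(segment, [(5, 25)]) == expected

    def test_best_class_wins_for_multimatch(self):
        proteome = {"pA": "XXXPEPTIDEXXX", "pB": "PEPTIDEYYYYYY"}
        region_sets = [("pA", [(0, 13)]), ("pB", [(5, 9)])]
        counts = count_peptide_overlaps(["PEPTIDE"], region_sets, proteome)
        assert counts["complete"] == 1  # pA's complete overlap beats pB's partial
        assert counts["partial"] == 0


class TestDisprotAnalysis:
    def _toy_world(self):
        rng = np.random.default_rng(0)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        proteome = {
            f"p{i}": "".join(rng.choice(letters, size=100)) for i in range(30)
        }
        return proteome

    def test_peptides_inside_own_regions_all_complete(self):
        from scestruct.types import DisorderRegionAnnotation

        proteome = self._toy_world()
        annotated = [
            DisorderRegionAnnotation("p0", ((10, 40),)),
            DisorderRegionAnnotation("p1", ((50, 90),)),
        ]
        peptides = [proteome["p0"][15:30], proteome["p1"][60, None] if False else proteome["p1"][60:75]]
        res = run_disprot_analysis(peptides, annotated, proteome, seed=4)
        assert res.counts["observed_complete"] == 2
        assert res.counts["observed_overlapping"] == 2

    def test_self_control_gives_expected_equal_observed(self):
        from scestruct.types import DisorderRegionAnnotation

        proteome = self._toy_world()
        annotated = [("p0", ((10, 40),)), ("p1", ((50, 90),))]
        # two overlapping peptides plus one that matches nothing annotated
        peptides = [
            proteome["p0"][15:30],
            proteome["p1"][60:75],
            proteome["p5"][10:25],
        ]
        obs = count_peptide_overlaps(peptides, annotated, proteome)
        assert obs["overlapping"] == 2
        # transferring the regions onto the true proteins reproduces the
        # observation exactly: expected == observed, chi-square p = 1
        again = count_peptide_overlaps(peptides, annotated, proteome)
        assert again == obs
        from scestruct import stats

        t = stats.yates_chi_square(
            [obs["overlapping"], len(peptides) - obs["overlapping"]],
            [obs["overlapping"], len(peptides) - obs["overlapping"]],
        )
        assert t.p_value == 1.0

    def test_no_length_compatible_control_skipped(self):
        from scestruct.types import DisorderRegionAnnotation

        rng = np.random.default_rng(1)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        # unique lengths, +5% band never reaches the next protein
        proteome = {
            "pA": "".join(rng.choice(letters, size=100)),
            "pB": "".join(rng.choice(letters, size=200)),
        }
        annotated = [DisorderRegionAnnotation("pA", ((10, 50),))]
        res = run_disprot_analysis(
            [proteome["pA"][12:30]], annotated, proteome, n_reps=2, seed=9
        )
        assert res.counts["skipped_controls"] == 2  # once per repetition

    def test_synthetic_study_end_to_end(self, small_bundle, mapped_small):
        segments, _ = mapped_small
        peptides = peptides_from_segments(segments[15], small_bundle.proteome)
        res = run_disprot_analysis(
            peptides, small_bundle.disprot, small_bundle.proteome,
            n_reps=5, seed=13,
        )
        assert res.counts["total_peptides"] == len(segments[15])
        assert len(res.counts["control_counts"]) == 5
        assert res.counts["expected"] == pytest.approx(
            float(np.median(res.counts["control_counts"]))
        )


class TestSfbsAnalysis:
    def test_filter_bookkeeping(self, small_bundle, small_annotations):
        res = run_sfbs_analysis(
            small_bundle.sfbs_records, small_bundle.transcripts,
            small_annotations, seed=5,
        )
        f = res.counts["filtering"]
        ids = {s.site_id for s in small_bundle.sfbs_records}
        assert f["raw"] == len(small_bundle.sfbs_records)
        assert f["after_mutant_filter"] == f["raw"] - 1  # one mutant site
        assert f["after_dedup"] == f["after_mutant_filter"] - 1  # one duplicate
        # the 4-nt and 50-nt sites are dropped; 5 and 49 would be retained
        assert f["after_length_filter"] == f["after_dedup"] - 2
        assert "sfbs_len4" in ids and "sfbs_len50" in ids

    def test_length_filter_boundaries(self, small_bundle, small_annotations):
        from scestruct.types import SFBSRecord, GenomicInterval

        base = [s for s in small_bundle.sfbs_records if not s.is_mutant_gene][0]
        sites = []
        for ln, sid in ((4, "s4"), (5, "s5"), (49, "s49"), (50, "s50")):
            iv = base.interval
            sites.append(
                SFBSRecord(
                    site_id=sid, gene_id=base.gene_id,
                    interval=GenomicInterval(iv.chrom, iv.start, iv.start + ln, iv.strand),
                    factor_name="X",
                )
            )
        res = run_sfbs_analysis(
            sites, small_bundle.transcripts, small_annotations, seed=1
        )
        assert res.counts["filtering"]["after_length_filter"] == 2

    def test_residue_level_expected_arithmetic(
        self, small_bundle, small_annotations
    ):
        """Expected assigned residues = (sum of segment lengths) x
        proteome-wide fraction; verified against an independent recount."""
        res = run_sfbs_analysis(
            small_bundle.sfbs_records, small_bundle.transcripts,
            small_annotations, seed=5,
        )
        info = res.counts["residue_level"]
        total = info["total_residues"]
        # independent recount of the proteome disorder fraction
        n_dis = sum(
            int(np.count_nonzero(a.disorder_scores >= 0.5))
            for a in small_annotations.values()
        )
        n_all = sum(len(a) for a in small_annotations.values())
        assert info["proteome_fractions"]["disorder"] == pytest.approx(n_dis / n_all)
        expected = total * n_dis / n_all
        raw = res.tests["residue_level"]["disorder"]
        from scestruct import stats

        manual = stats.yates_chi_square(
            [info["observed"]["disorder"], total - info["observed"]["disorder"]],
            [expected, total - expected],
        )
        assert raw.statistic == pytest.approx(manual.statistic)

    def test_design_effect_adjustment_shrinks_statistic(
        self, small_bundle, small_annotations
    ):
        res = run_sfbs_analysis(
            small_bundle.sfbs_records, small_bundle.transcripts,
            small_annotations, seed=5,
        )
        d = res.metadata["residue_design_effect"]
        assert d > 1.0
        for prop, raw in res.tests["residue_level"].items():
            adj = res.tests["residue_level_adjusted"][prop]
            assert adj.statistic == pytest.approx(raw.statistic / d)

    def test_zero_sites_after_filtering_errors(
        self, small_bundle, small_annotations
    ):
        mutants = [s for s in small_bundle.sfbs_records if s.is_mutant_gene]
        with pytest.raises(ValueError):
            run_sfbs_analysis(
                mutants, small_bundle.transcripts, small_annotations, seed=1
            )


class TestReporting:
    def test_config_hash_stable_and_sensitive(self, small_bundle):
        h1 = report.config_hash(small_bundle.config)
        h2 = report.config_hash(small_bundle.config)
        assert h1 == h2
        import dataclasses

        other = dataclasses.replace(small_bundle.config, seed=999)
        assert report.config_hash(other) != h1

    def test_manifest_comparable_ignores_timestamp(self):
        m1 = report.RunManifest("abc", seeds={"main": 1}, timestamp="t1")
        m2 = report.RunManifest("abc", seeds={"main": 1}, timestamp="t2")
        assert m1.comparable() == m2.comparable()

    def test_protein_report_renders_tracks(self, small_bundle, small_annotations):
        pid = sorted(small_bundle.proteome)[0]
        text = report.protein_report(
            pid, small_bundle.proteome[pid], small_annotations[pid]
        )
        assert pid in text
        assert "dis  " in text and "lcx  " in text and "dom  " in text

    def test_study_report_lists_tests(self, small_annotations, mapped_small):
        segments, _ = mapped_small
        res = run_sce_comparison(segments, small_annotations, seed=3)
        text = report.study_report(res)
        assert "yates_chi_square_2x2" in text
        assert "mann_whitney_u" in text

    def test_result_summary_is_json_serializable(
        self, small_annotations, mapped_small
    ):
        import json

        segments, _ = mapped_small
        res = run_sce_comparison(segments, small_annotations, seed=3)
        json.dumps(report.result_summary(res))
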