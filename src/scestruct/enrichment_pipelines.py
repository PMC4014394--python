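"""Study-level analyses: the four enrichment pipelines.

Each pipeline is a deterministic orchestration of mapping, annotation,
measurement and statistics:

* :func:`run_sce_comparison` - per detection window, compare SCE-encoded
  segments to length-matched reference segments drawn from the
  SCE-containing proteins (binary >=50% assignment counts by Yates
  chi-square on the 2x2 table, raw fractions by Mann-Whitney U, Bonferroni
  threshold over the four properties);
* :func:`run_window_correlation` - Spearman correlation between detection
  window size and each property's descriptive value, plus Kruskal-Wallis and
  Dunn comparisons across the three window datasets;
* :func:`run_disprot_analysis` - exact matches of SCE-encoded peptides
  against proteins with experimentally validated disordered regions,
  with a length-matched region-transfer control repeated ``n_reps`` times
  (expected = median of the control counts, Yates goodness-of-fit);
* :func:`run_sfbs_analysis` - splicing-factor binding sites: filtering,
  dual-frame mapping, segment-level Mann-Whitney against the whole canonical
  proteome, and residue-level Yates goodness-of-fit against proteome-wide
  property fractions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from . import genomic_mapping, segment_analysis, stats
from .segment_analysis import (
    build_comparison_table,
    descriptive_value,
    sample_reference_segments,
    segment_fractions,
    SamplingPlan,
)
from .types import (
    PROPERTIES,
    DisorderRegionAnnotation,
    ExclusionRecord,
    ProteinSegment,
    SCERecord,
    SegmentProperties,
    SFBSRecord,
    StructuralAnnotation,
    TranscriptSet,
    TestResult,
)

logger = logging.getLogger(__name__)

WINDOW_SIZES = (9, 15, 30)

__all__ = [
    "StudyResult",
    "SyntheticStudyRun",
    "run_synthetic_end_to_end",
    "map_sce_datasets",
    "measure_segments",
    "run_sce_comparison",
    "run_window_correlation",
    "run_disprot_analysis",
    "run_sfbs_analysis",
    "peptides_from_segments",
    "classify_overlap",
    "count_peptide_overlaps",
    "proteome_property_fractions",
]


@dataclass
class StudyResult:
    """Bundle of tables, test results and bookkeeping for one analysis run."""

    name: str
    tables: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    descriptives: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


@dataclass
class SyntheticStudyRun:
    """Everything produced by one simulate -> map -> annotate -> measure ->
    compare pass over a synthetic study."""

    bundle: object
    annotations: dict
    segments: dict
    exclusions: dict
    measured: dict  # window -> list[SegmentProperties]
    comparison: StudyResult
    trend: Optional[StudyResult]


def run_synthetic_end_to_end(config=None, analysis_seed: int = 0) -> SyntheticStudyRun:
    """Generate a synthetic study and run the full SCE analysis on it.

    Disorder, secondary-structure and domain tracks come from the
    generator's ground truth (the role external predictors play on real
    data); the low-complexity mask is computed internally.  The window-size
    trend is computed when exactly the windows 9/15/30 are present.
    """
    from . import synthetic_data

    bundle = synthetic_data.generate_study(config)
    annotations = synthetic_data.annotations_from_truth(bundle)
    segments, exclusions = map_sce_datasets(
        bundle.sce_records, bundle.transcripts, bundle.element_seqs
    )
    comparison = run_sce_comparison(segments, annotations, seed=analysis_seed)
    measured = {
        w: [p for _, p in measure_segments(segments[w], annotations)]
        for w in segments
    }
    trend = None
    if tuple(sorted(segments)) == WINDOW_SIZES:
        trend = run_window_correlation(measured)
    return SyntheticStudyRun(
        bundle=bundle,
        annotations=annotations,
        segments=segments,
        exclusions=exclusions,
        measured=measured,
        comparison=comparison,
        trend=trend,
    )


def _child_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2^31."""
    state = np.random.SeedSequence([int(seed), *[int(t) for t in tags]])
    return int(state.generate_state(1)[0] % (2**31))


def map_sce_datasets(
    sce_records: Mapping[int, Sequence[SCERecord]],
    transcript_set: TranscriptSet,
    element_seqs: Optional[Mapping[str, str]] = None,
    **mapping_kwargs,
) -> tuple[dict[int, list[ProteinSegment]], dict[int, list[ExclusionRecord]]]:
    """Map every SCE of every resolution; returns segments and exclusions."""
    segments: dict[int, list[ProteinSegment]] = {}
    exclusions: dict[int, list[ExclusionRecord]] = {}
    for w in sorted(sce_records):
        segs, excl = [], []
        for rec in sce_records[w]:
            seq = element_seqs.get(rec.element_id) if element_seqs else None
            out = genomic_mapping.map_element_to_protein(
                rec, transcript_set, element_seq=seq, **mapping_kwargs
            )
            if isinstance(out, ExclusionRecord):
                excl.append(out)
            else:
                segs.append(out)
        segments[w] = segs
        exclusions[w] = excl
        logger.info(
            "window %d: mapped %d, excluded %d (%.2f%%)",
            w, len(segs), len(excl),
            100.0 * len(excl) / max(1, len(segs) + len(excl)),
        )
    return segments, exclusions


def measure_segments(
    segments: Sequence[ProteinSegment],
    annotations: Mapping[str, StructuralAnnotation],
) -> list[tuple[ProteinSegment, SegmentProperties]]:
    """Excise the per-segment properties from full-protein annotations."""
    out = []
    for seg in segments:
        try:
            ann = annotations[seg.protein_id]
        except KeyError:
            raise KeyError(
                f"no structural annotation for protein {seg.protein_id!r}"
            ) from None
        out.append((seg, segment_fractions(seg, ann)))
    return out


def run_sce_comparison(
    datasets: Mapping[int, Sequence[ProteinSegment]],
    annotations: Mapping[str, StructuralAnnotation],
    seed: int,
    alpha: float = 0.05,
    ref_weighting: str = "protein",
    ref_replicates: int = 1,
) -> StudyResult:
    """Compare SCE-encoded segments with length-matched reference segments.

    For each detection window, one reference set (or ``ref_replicates``
    pooled sets) is drawn from the SCE-containing proteins of that window's
    dataset, and each structural property is tested two ways: the number of
    >=50%-assigned segments by Yates chi-square on the 2x2 table and the raw
    fraction distributions by Mann-Whitney U.  The per-test significance
    threshold is Bonferroni-corrected over the four properties.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    threshold = stats.bonferroni_threshold(alpha, len(PROPERTIES))
    result = StudyResult(
        name="sce_comparison",
        metadata={
            "seed": seed,
            "alpha": alpha,
            "bonferroni_threshold": threshold,
            "ref_weighting": ref_weighting,
            "ref_replicates": ref_replicates,
        },
    )
    for w in sorted(datasets):
        segments = list(datasets[w])
        if not segments:
            raise ValueError(f"window {w}: empty dataset")
        measured = measure_segments(segments, annotations)
        props = [p for _, p in measured]
        candidates = {
            pid: len(annotations[pid])
            for pid in sorted({s.protein_id for s in segments})
        }
        lengths = [s.length for s in segments] * ref_replicates
        plan = SamplingPlan(
            lengths=lengths,
            candidate_proteins=candidates,
            seed=_child_seed(seed, w),
            weighting=ref_weighting,
        )
        ref_segments = sample_reference_segments(plan)
        ref_props = [p for _, p in measure_segments(ref_segments, annotations)]
        table = build_comparison_table(props, ref_props)
        result.tables[w] = table
        result.counts[w] = {"n_sce": len(props), "n_ref": len(ref_props)}
        tests = {}
        for prop in PROPERTIES:
            cmp_ = table[prop]
            chi = stats.yates_chi_square_2x2(
                cmp_.n_test_assigned, cmp_.n_test,
                cmp_.n_ref_assigned, cmp_.n_ref,
            )
            mwu = stats.mann_whitney_u(cmp_.test_fractions, cmp_.ref_fractions)
            direction = int(np.sign(cmp_.test_rate - cmp_.ref_rate))
            if direction == 0:
                direction = int(
                    np.sign(
                        float(np.mean(cmp_.test_fractions))
                        - float(np.mean(cmp_.ref_fractions))
                    )
                )
            note = ""
            if len(props) < 10:
                note = "low power: fewer than 10 segments"
                result.notes.append(f"window {w} {prop}: {note}")
            tests[prop] = {
                "chi_square": chi,
                "mann_whitney": mwu,
                "direction": direction,
                "significant": chi.p_value < threshold,
                "note": note,
            }
        result.tests[w] = tests
        result.descriptives[w] = {
            prop: descriptive_value(table[prop].test_fractions, prop)
            for prop in segment_analysis.DESCRIPTIVE_PERCENTILE
        }
    return result


def run_window_correlation(
    datasets_props: Mapping[int, Sequence[SegmentProperties]],
) -> StudyResult:
    """Correlate detection window size with each property's descriptive value.

    Requires exactly the three windows 9/15/30.  Domain content is excluded
    from the correlation (binary-like, no single descriptive value) but
    included in the Kruskal-Wallis/Dunn comparisons across windows.
    """
    windows = tuple(sorted(datasets_props))
    if windows != WINDOW_SIZES:
        raise ValueError(f"need exactly windows {WINDOW_SIZES}, got {windows}")
    result = StudyResult(name="window_correlation")
    for prop in segment_analysis.DESCRIPTIVE_PERCENTILE:
        values = [
            descriptive_value(
                [p.fraction(prop) for p in datasets_props[w]], prop
            )
            for w in windows
        ]
        result.descriptives[prop] = dict(zip(windows, values))
        try:
            rho = stats.spearman_rho(list(windows), values)
        except ValueError:
            rho = None
            result.notes.append(f"{prop}: no trend (constant descriptive values)")
        result.correlations[prop] = rho
    for prop in PROPERTIES:
        groups = [
            [p.fraction(prop) for p in datasets_props[w]] for w in windows
        ]
        kw = stats.kruskal_wallis(groups)
        dunn = stats.dunn_pairwise(groups, labels=[str(w) for w in windows])
        result.tests[prop] = {"kruskal_wallis": kw, "dunn": dunn}
    return result


def peptides_from_segments(
    segments: Sequence[ProteinSegment], proteome: Mapping[str, str]
) -> list[str]:
    """Amino-acid sequences encoded by the segments."""
    return [proteome[s.protein_id][s.start : s.end] for s in segments]


def classify_overlap(
    segment: tuple[int, int], regions: Sequence[tuple[int, int]]
) -> str:
    """'complete' if the segment lies inside a region, 'partial' if it shares
    at least one residue, else 'none'."""
    s, e = segment
    best = "none"
    for rs, re_ in regions:
        if s >= rs and e <= re_:
            return "complete"
        if e > rs and s < re_:
            best = "partial"
    return best


_CLASS_RANK = {"none": 0, "partial": 1, "complete": 2}


def count_peptide_overlaps(
    peptides: Sequence[str],
    region_sets: Sequence[tuple[str, Sequence[tuple[int, int]]]],
    proteome: Mapping[str, str],
) -> dict[str, int]:
    """Best overlap class per peptide across all annotated proteins.

    Every occurrence of a peptide in every listed protein is considered; a
    multi-match peptide counts once with its best class
    (complete > partial > none).
    """
    n_complete = n_partial = n_matched = 0
    for pep in peptides:
        best = None
        for pid, regions in region_sets:
            seq = proteome.get(pid)
            if not seq:
                continue
            pos = seq.find(pep)
            while pos != -1:
                cls = classify_overlap((pos, pos + len(pep)), regions)
                if best is None or _CLASS_RANK[cls] > _CLASS_RANK[best]:
                    best = cls
                pos = seq.find(pep, pos + 1)
        if best is not None:
            n_matched += 1
            if best == "complete":
                n_complete += 1
            elif best == "partial":
                n_partial += 1
    return {
        "matched": n_matched,
        "complete": n_complete,
        "partial": n_partial,
        "overlapping": n_complete + n_partial,
    }


def run_disprot_analysis(
    sce_peptides: Sequence[str],
    disprot_annotations: Sequence[DisorderRegionAnnotation],
    proteome: Mapping[str, str],
    n_reps: int = 5,
    seed: int = 0,
    length_band: str = "one_sided",
    band: float = 0.05,
) -> StudyResult:
    """Match SCE-encoded peptides against validated disordered regions.

    Observed: the number of peptides overlapping (completely or partially) an
    annotated region.  Control: for every annotated protein a random protein
    of matching length (within +``band`` one-sided, or +/-``band`` when
    ``length_band='symmetric'``) receives the region boundaries verbatim, and
    the peptides are re-matched; the procedure is repeated ``n_reps`` times
    and the median control count is the expected value of a Yates
    goodness-of-fit chi-square over the total number of peptides.
    """
    if length_band not in ("one_sided", "symmetric"):
        raise ValueError("length_band must be 'one_sided' or 'symmetric'")
    total = len(sce_peptides)
    if total == 0:
        raise ValueError("no peptides supplied")
    annotated = [
        (ann.protein_id, ann.regions)
        for ann in disprot_annotations
        if ann.protein_id in proteome
    ]
    observed = count_peptide_overlaps(sce_peptides, annotated, proteome)
    ids = sorted(proteome)
    lengths = np.array([len(proteome[i]) for i in ids])
    control_counts = []
    skipped = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, rep))
        control_sets = []
        for pid, regions in annotated:
            L = len(proteome[pid])
            if length_band == "one_sided":
                lo_len, hi_len = L, int(np.floor(L * (1 + band)))
            else:
                lo_len, hi_len = int(np.ceil(L * (1 - band))), int(
                    np.floor(L * (1 + band))
                )
            mask = (lengths >= max(lo_len, max(e for _, e in regions))) & (
                lengths <= hi_len
            )
            candidates = [i for i in np.flatnonzero(mask) if ids[i] != pid]
            if not candidates:
                skipped.append((rep, pid))
                continue
            pick = ids[candidates[int(rng.integers(len(candidates)))]]
            control_sets.append((pick, regions))
        control_counts.append(
            count_peptide_overlaps(sce_peptides, control_sets, proteome)[
                "overlapping"
            ]
        )
    expected = float(np.median(control_counts))
    result = StudyResult(
        name="disprot_analysis",
        counts={
            "total_peptides": total,
            "observed_overlapping": observed["overlapping"],
            "observed_complete": observed["complete"],
            "observed_partial": observed["partial"],
            "control_counts": control_counts,
            "expected": expected,
            "skipped_controls": len(skipped),
        },
        metadata={"seed": seed, "n_reps": n_reps, "length_band": length_band},
    )
    if expected <= 0 or expected >= total:
        result.notes.append("degenerate expected count; chi-square skipped")
        return result
    obs_o = observed["overlapping"]
    result.tests["overlap"] = stats.yates_chi_square(
        [obs_o, total - obs_o], [expected, total - expected]
    )
    return result


def proteome_property_fractions(
    annotations: Mapping[str, StructuralAnnotation],
    max_protein_length: int = genomic_mapping.DEFAULT_MAX_PROTEIN_LENGTH,
) -> dict[str, float]:
    """Proteome-wide fraction of residues assigned to each property."""
    totals = {prop: 0 for prop in PROPERTIES}
    n_residues = 0
    for pid in sorted(annotations):
        ann = annotations[pid]
        if len(ann) > max_protein_length:
            continue
        n_residues += len(ann)
        totals["disorder"] += int(np.count_nonzero(ann.disorder_scores >= 0.5))
        totals["low_complexity"] += int(np.count_nonzero(ann.low_complexity_mask))
        totals["secondary_structure"] += int(
            np.count_nonzero((ann.ss_states == "H") | (ann.ss_states == "E"))
        )
        totals["domain"] += int(np.count_nonzero(ann.domain_mask))
    if n_residues == 0:
        raise ValueError("no annotations")
    return {prop: totals[prop] / n_residues for prop in PROPERTIES}


def _segment_residue_counts(
    measured: Sequence[tuple[ProteinSegment, SegmentProperties]]
) -> dict[str, float]:
    out = {prop: 0.0 for prop in PROPERTIES}
    for seg, props in measured:
        for prop in PROPERTIES:
            out[prop] += props.fraction(prop) * seg.length
    return out


def run_sfbs_analysis(
    sites: Sequence[SFBSRecord],
    transcript_set: TranscriptSet,
    annotations: Mapping[str, StructuralAnnotation],
    seed: int = 0,
    alpha: float = 0.05,
    ref_weighting: str = "protein",
    min_length_nt: int = 5,
    max_length_nt: int = 49,
) -> StudyResult:
    """Splicing-factor binding-site analysis.

    Filtering: mutant-gene sites and chromosomal-location duplicates are
    dropped, and only sites spanning more than 4 but fewer than 50
    nucleotides are kept.  Mapping allows two transcripts per site when they
    represent distinct coding frames.  Segment-level comparison draws
    length-matched references from the whole canonical proteome
    (Mann-Whitney per property, Bonferroni m=4); residue-level comparison
    tests observed assigned-residue counts against expectations from
    proteome-wide fractions (Yates goodness-of-fit per property).
    """
    result = StudyResult(name="sfbs_analysis", metadata={"seed": seed})
    n_raw = len(sites)
    non_mutant = [s for s in sites if not s.is_mutant_gene]
    seen_loc: set[tuple] = set()
    unique: list[SFBSRecord] = []
    for s in non_mutant:
        key = (s.interval.chrom, s.interval.start, s.interval.end, s.interval.strand)
        if key in seen_loc:
            continue
        seen_loc.add(key)
        unique.append(s)
    kept = [
        s for s in unique if min_length_nt <= s.length_nt <= max_length_nt
    ]
    result.counts["filtering"] = {
        "raw": n_raw,
        "after_mutant_filter": len(non_mutant),
        "after_dedup": len(unique),
        "after_length_filter": len(kept),
    }
    if not kept:
        raise ValueError("no SFBS sites left after filtering")
    segments: list[ProteinSegment] = []
    exclusions: list[ExclusionRecord] = []
    for site in kept:
        out = genomic_mapping.map_sfbs(site, transcript_set)
        if isinstance(out, ExclusionRecord):
            exclusions.append(out)
        else:
            segments.extend(out)
    result.counts["mapped_sites"] = len(kept) - len(exclusions)
    result.counts["segments"] = len(segments)
    result.exclusions["sites"] = exclusions
    if not segments:
        raise ValueError("no SFBS site could be mapped")
    measured = measure_segments(segments, annotations)
    props = [p for _, p in measured]
    candidates = {pid: len(annotations[pid]) for pid in sorted(annotations)}
    plan = SamplingPlan(
        lengths=[s.length for s in segments],
        candidate_proteins=candidates,
        seed=_child_seed(seed, 97),
        weighting=ref_weighting,
    )
    ref_segments = sample_reference_segments(plan)
    ref_props = [p for _, p in measure_segments(ref_segments, annotations)]
    table = build_comparison_table(props, ref_props)
    result.tables["segment_level"] = table
    threshold = stats.bonferroni_threshold(alpha, len(PROPERTIES))
    result.metadata["bonferroni_threshold"] = threshold
    seg_tests = {}
    for prop in PROPERTIES:
        cmp_ = table[prop]
        mwu = stats.mann_whitney_u(cmp_.test_fractions, cmp_.ref_fractions)
        seg_tests[prop] = {
            "mann_whitney": mwu,
            "direction": int(
                np.sign(
                    float(np.mean(cmp_.test_fractions))
                    - float(np.mean(cmp_.ref_fractions))
                )
            ),
            "significant": mwu.p_value < threshold,
        }
    result.tests["segment_level"] = seg_tests
    # residue-level: observed assigned residues vs proteome-wide expectation.
    # Residues of one site share their structural context (a site falls
    # wholly inside or outside a domain or disordered run), so the raw
    # chi-square treats correlated residues as independent and is
    # anticonservative; the adjusted variant divides the statistic by the
    # cluster design effect sum(l^2)/sum(l) (exact under full within-site
    # correlation, conservative under partial).
    fractions = proteome_property_fractions(annotations)
    seg_lengths = np.array([s.length for s in segments], dtype=float)
    total_len = float(seg_lengths.sum())
    design_effect = float((seg_lengths**2).sum() / total_len)
    observed = _segment_residue_counts(measured)
    residue_tests = {}
    residue_tests_adjusted = {}
    for prop in PROPERTIES:
        exp_assigned = total_len * fractions[prop]
        if exp_assigned <= 0 or exp_assigned >= total_len:
            result.notes.append(f"residue-level {prop}: degenerate expectation")
            continue
        raw = stats.yates_chi_square(
            [observed[prop], total_len - observed[prop]],
            [exp_assigned, total_len - exp_assigned],
        )
        residue_tests[prop] = raw
        adj_stat = raw.statistic / design_effect
        residue_tests_adjusted[prop] = TestResult(
            "yates_chi_square_design_effect",
            adj_stat,
            float(_chi2_dist.sf(adj_stat, 1)),
            df=1,
            notes=f"design effect {design_effect:.2f}",
        )
    result.tests["residue_level"] = residue_tests
    result.tests["residue_level_adjusted"] = residue_tests_adjusted
    result.metadata["residue_design_effect"] = design_effect
    result.counts["residue_level"] = {
        "total_residues": total_len,
        "observed": observed,
        "proteome_fractions": fractions,
    }
    return result
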