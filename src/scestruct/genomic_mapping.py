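"""Map genomic elements through transcript CDS space onto protein residues.

The mapping rules mirror the study design: an element is projected onto the
spliced CDS of each transcript of its gene (canonical isoform first, then the
rest in CDS-length-descending order), every residue with at least one
overlapping nucleotide is included, only one segment is accepted per element,
and proteins above a length cap are skipped entirely.  When the recorded
coordinates and the transcript sequence disagree (assembly/annotation
mismatches), a gapped local alignment relocates the element; matches with
identity < 0.9 or a gap run longer than one nucleotide are rejected, which
operationalises the exclusion of elements with "multiple consecutive gaps".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align

from .types import (
    ExclusionRecord,
    GenomicInterval,
    MatchOutcome,
    ProteinSegment,
    SCERecord,
    SFBSRecord,
    TranscriptModel,
    TranscriptSet,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_PROTEIN_LENGTH = 10_000
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MAX_GAP_RUN = 1

__all__ = [
    "CdsProjection",
    "project_interval_to_cds",
    "cds_range_to_residues",
    "locate_element_in_cds",
    "map_element_to_protein",
    "map_sfbs",
]


class OutsideCdsError(ValueError):
    """The interval overlaps no CDS nucleotide of the transcript."""


@dataclass(frozen=True)
class CdsProjection:
    """Half-open nt range in CDS space plus clipping diagnostics."""

    cds_start: int
    cds_end: int
    covered_nt: int  # CDS nucleotides actually overlapped
    clipped_nt: int  # intronic/UTR nucleotides clipped away

    @property
    def span(self) -> int:
        return self.cds_end - self.cds_start


def project_interval_to_cds(
    interval: GenomicInterval, transcript: TranscriptModel
) -> CdsProjection:
    """Project one genomic interval onto transcript CDS coordinates.

    Returns the half-open CDS-offset range covering all CDS nucleotides of
    the interval in 5'->3' transcript orientation.  Intronic or UTR overhang
    is clipped (and counted); an interval with no CDS overlap raises
    :class:`OutsideCdsError`.
    """
    minus = transcript.strand == "-"
    acc = 0
    lo: Optional[int] = None
    hi: Optional[int] = None
    covered = 0
    for block in transcript.cds_blocks:
        ov_s = max(interval.start, block.start)
        ov_e = min(interval.end, block.end)
        if ov_e > ov_s:
            if minus:
                o1 = acc + (block.end - ov_e)
                o2 = acc + (block.end - ov_s)
            else:
                o1 = acc + (ov_s - block.start)
                o2 = acc + (ov_e - block.start)
            lo = o1 if lo is None else min(lo, o1)
            hi = o2 if hi is None else max(hi, o2)
            covered += ov_e - ov_s
        acc += block.length
    if lo is None:
        raise OutsideCdsError(
            f"interval {interval} outside CDS of {transcript.transcript_id}"
        )
    return CdsProjection(lo, hi, covered, interval.length - covered)


def project_element_to_cds(
    intervals: Sequence[GenomicInterval], transcript: TranscriptModel
) -> CdsProjection:
    """Project a (possibly multi-interval) element; exon-split pieces are
    contiguous in CDS space, so the union is a single half-open range."""
    lo = hi = None
    covered = clipped = 0
    for iv in intervals:
        try:
            p = project_interval_to_cds(iv, transcript)
        except OutsideCdsError:
            clipped += iv.length
            continue
        lo = p.cds_start if lo is None else min(lo, p.cds_start)
        hi = p.cds_end if hi is None else max(hi, p.cds_end)
        covered += p.covered_nt
        clipped += p.clipped_nt
    if lo is None:
        raise OutsideCdsError("element outside CDS")
    return CdsProjection(lo, hi, covered, clipped)


def cds_range_to_residues(cds_start: int, cds_end: int) -> tuple[int, int]:
    """Residue range covered by a CDS nt range; partial codons count.

    [start, end) in nucleotides maps to [floor(start/3), floor((end-1)/3)+1)
    in residues, so any residue with at least one overlapping nucleotide is
    included.
    """
    if not (0 <= cds_start < cds_end):
        raise ValueError(f"empty or invalid CDS range [{cds_start},{cds_end})")
    return cds_start // 3, (cds_end - 1) // 3 + 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_diagnostics(alignment, elem_len: int) -> tuple[float, int]:
    """(identity over the element, longest gap run in nt) of a local alignment."""
    target_blocks, query_blocks = alignment.aligned
    matches = 0
    target = alignment.target
    query = alignment.query
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        for t, q in zip(target[ts:te], query[qs:qe]):
            if t == q:
                matches += 1
    max_gap = 0
    for i in range(1, len(target_blocks)):
        gap_t = target_blocks[i][0] - target_blocks[i - 1][1]
        gap_q = query_blocks[i][0] - query_blocks[i - 1][1]
        max_gap = max(max_gap, gap_t, gap_q)
    # element overhang beyond the local alignment counts as unmatched
    identity = matches / elem_len if elem_len else 0.0
    return identity, max_gap


def locate_element_in_cds(
    element_nt_sequence: str,
    cds_sequence: str,
    predicted_offset: Optional[int] = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gap_run: int = DEFAULT_MAX_GAP_RUN,
) -> MatchOutcome:
    """Locate an element's nucleotide sequence on a CDS.

    Tries an exact match at the coordinate-predicted offset, then an exact
    substring search anywhere, then a gapped local alignment (match +1,
    mismatch -2, gap open -5, gap extend -2) accepted iff the identity over
    the element is >= ``min_identity`` and the longest gap run is
    <= ``max_gap_run``.  Rejection is a status, never an exception.
    """
    elem = element_nt_sequence.upper()
    cds = cds_sequence.upper()
    L = len(elem)
    if L == 0 or L > len(cds):
        return MatchOutcome("rejected", note="element empty or longer than CDS")
    if predicted_offset is not None and 0 <= predicted_offset <= len(cds) - L:
        if cds[predicted_offset : predicted_offset + L] == elem:
            return MatchOutcome(
                "exact", predicted_offset, predicted_offset + L, 1.0, 0
            )
    pos = cds.find(elem)
    if pos != -1:
        return MatchOutcome("exact", pos, pos + L, 1.0, 0)
    aligner = _make_aligner()
    alignments = aligner.align(cds, elem)
    try:
        best = alignments[0]
    except IndexError:
        return MatchOutcome("rejected", note="no local alignment")
    identity, gap_run = _alignment_diagnostics(best, L)
    t_blocks = best.aligned[0]
    cds_start, cds_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    if identity >= min_identity and gap_run <= max_gap_run:
        return MatchOutcome("aligned", cds_start, cds_end, identity, gap_run)
    return MatchOutcome(
        "rejected",
        cds_start,
        cds_end,
        identity,
        gap_run,
        note=f"identity {identity:.3f} / max gap run {gap_run}",
    )


def _candidate_transcripts(
    tset: TranscriptSet, gene_id: str, max_protein_length: int
):
    """Translatable transcripts in preference order, with skip reasons."""
    usable = []
    reasons = {}
    for t in tset.gene_transcripts(gene_id):
        if not t.translation_ok:
            reasons[t.transcript_id] = f"untranslatable: {t.notes or 'flagged'}"
            continue
        if t.protein_length > max_protein_length:
            reasons[t.transcript_id] = (
                f"protein longer than {max_protein_length} residues"
            )
            continue
        usable.append(t)
    return usable, reasons


def map_element_to_protein(
    element: SCERecord,
    transcript_set: TranscriptSet,
    element_seq: Optional[str] = None,
    max_protein_length: int = DEFAULT_MAX_PROTEIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gap_run: int = DEFAULT_MAX_GAP_RUN,
    min_cds_overlap_nt: int = 3,
) -> ProteinSegment | ExclusionRecord:
    """Map one SCE onto exactly one protein segment (or an exclusion record).

    The canonical transcript has preference; remaining transcripts are tried
    in CDS-length-descending order and only the first acceptable match is
    emitted.  When ``element_seq`` is supplied, the coordinate projection is
    verified against the transcript sequence and the alignment fallback
    handles mismatches; elements clipped to fewer than ``min_cds_overlap_nt``
    CDS nucleotides are rejected.
    """
    usable, reasons = _candidate_transcripts(
        transcript_set, element.gene_id, max_protein_length
    )
    for t in usable:
        try:
            proj = project_element_to_cds(element.intervals, t)
        except OutsideCdsError:
            proj = None
            if element_seq is None:
                reasons[t.transcript_id] = "outside CDS"
                continue
        if proj is not None and proj.covered_nt < min_cds_overlap_nt:
            reasons[t.transcript_id] = (
                f"only {proj.covered_nt} nt overlap CDS (< {min_cds_overlap_nt})"
            )
            continue
        if element_seq is None:
            res_start, res_end = cds_range_to_residues(proj.cds_start, proj.cds_end)
            return ProteinSegment(
                protein_id=t.protein_id,
                start=res_start,
                end=min(res_end, t.protein_length),
                provenance="SCE",
                source_element_id=element.element_id,
                window_codons=element.window_codons,
            )
        outcome = locate_element_in_cds(
            element_seq,
            t.cds_sequence,
            predicted_offset=None if proj is None else proj.cds_start,
            min_identity=min_identity,
            max_gap_run=max_gap_run,
        )
        if outcome.status != "rejected":
            res_start, res_end = cds_range_to_residues(
                outcome.cds_start, outcome.cds_end
            )
            return ProteinSegment(
                protein_id=t.protein_id,
                start=res_start,
                end=min(res_end, t.protein_length),
                provenance="SCE",
                source_element_id=element.element_id,
                window_codons=element.window_codons,
            )
        reasons[t.transcript_id] = outcome.note or "no reliable match"
    return ExclusionRecord(element.element_id, reasons)


def map_sfbs(
    site: SFBSRecord,
    transcript_set: TranscriptSet,
    max_protein_length: int = DEFAULT_MAX_PROTEIN_LENGTH,
) -> list[ProteinSegment] | ExclusionRecord:
    """Map one SFBS onto protein segments; up to two distinct coding frames.

    Transcripts are tried canonical-first; a second segment is accepted only
    when it encodes a different peptide (overlapping exons read in shifted
    frames), mirroring the dual-coding special case.
    """
    usable, reasons = _candidate_transcripts(
        transcript_set, site.gene_id, max_protein_length
    )
    segments: list[ProteinSegment] = []
    peptides: set[str] = set()
    for t in usable:
        if len(segments) >= 2:
            break
        try:
            proj = project_interval_to_cds(site.interval, t)
        except OutsideCdsError:
            reasons[t.transcript_id] = "outside CDS"
            continue
        if proj.covered_nt < 1:
            reasons[t.transcript_id] = "no CDS overlap"
            continue
        res_start, res_end = cds_range_to_residues(proj.cds_start, proj.cds_end)
        res_end = min(res_end, t.protein_length)
        if res_end <= res_start:
            reasons[t.transcript_id] = "maps beyond protein end"
            continue
        peptide = t.protein_sequence[res_start:res_end]
        if peptide in peptides:
            continue
        peptides.add(peptide)
        segments.append(
            ProteinSegment(
                protein_id=t.protein_id,
                start=res_start,
                end=res_end,
                provenance="SFBS",
                source_element_id=site.site_id,
            )
        )
    if segments:
        return segments
    return ExclusionRecord(site.site_id, reasons)
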