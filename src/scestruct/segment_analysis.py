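"""Per-segment structural properties and the length-matched reference null.

A segment's four property fractions are excised from full-length protein
annotations (segments are scored in their natural sequence context, never
re-predicted in isolation).  The null model draws, for every observed segment
length, a random same-length segment from a candidate protein population
without crossing protein boundaries, preserving the observed length multiset
exactly.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import (
    PROPERTIES,
    ProteinSegment,
    SegmentProperties,
    StructuralAnnotation,
)

__all__ = [
    "SamplingPlan",
    "segment_fractions",
    "sample_reference_segments",
    "descriptive_value",
    "build_comparison_table",
    "PropertyComparison",
    "DESCRIPTIVE_PERCENTILE",
]

ASSIGNMENT_THRESHOLD = 0.5

#: percentile summarising each property's fraction distribution: third
#: quartile for disorder, median for secondary structure, 90th percentile for
#: low complexity.  Domain content is binary-like and has no single
#: descriptive value.
DESCRIPTIVE_PERCENTILE = {
    "disorder": 75.0,
    "secondary_structure": 50.0,
    "low_complexity": 90.0,
}


def segment_fractions(
    segment: ProteinSegment,
    annotation: StructuralAnnotation,
    threshold: float = ASSIGNMENT_THRESHOLD,
) -> SegmentProperties:
    """The four property fractions of a segment plus >=50% assignments.

    Disorder counts residues scoring >= 0.5 (a residue at exactly 0.5 is
    disordered); secondary structure counts states H and E; the
    low-complexity and domain masks are counted directly.  A segment is
    assigned a property when at least ``threshold`` of its residues carry it.
    """
    if not (0 <= segment.start < segment.end <= len(annotation)):
        raise ValueError(
            f"segment [{segment.start},{segment.end}) outside protein "
            f"{annotation.protein_id} (length {len(annotation)})"
        )
    sl = slice(segment.start, segment.end)
    n = segment.length
    disorder = float(np.count_nonzero(annotation.disorder_scores[sl] >= 0.5)) / n
    lc = float(np.count_nonzero(annotation.low_complexity_mask[sl])) / n
    ss_states = annotation.ss_states[sl]
    ss = float(np.count_nonzero((ss_states == "H") | (ss_states == "E"))) / n
    dom = float(np.count_nonzero(annotation.domain_mask[sl])) / n
    return SegmentProperties(
        disorder_fraction=disorder,
        low_complexity_fraction=lc,
        ss_fraction=ss,
        domain_fraction=dom,
        is_disordered=disorder >= threshold,
        is_low_complexity=lc >= threshold,
        is_ss=ss >= threshold,
        is_domain=dom >= threshold,
    )


@dataclass
class SamplingPlan:
    """Length-matched reference sampling plan.

    ``lengths``: the observed segment lengths (the multiset to reproduce);
    ``candidate_proteins``: protein id -> length of the population to sample
    from; ``seed`` fixes the output exactly.
    """

    lengths: Sequence[int]
    candidate_proteins: Mapping[str, int]
    seed: int
    weighting: str = "protein"  # 'protein' or 'residue'

    def __post_init__(self) -> None:
        if self.weighting not in ("protein", "residue"):
            raise ValueError("weighting must be 'protein' or 'residue'")
        if not self.candidate_proteins:
            raise ValueError("candidate set is empty")


def sample_reference_segments(plan: SamplingPlan) -> list[ProteinSegment]:
    """Draw one random same-length segment per observed length.

    For each length l a host protein is drawn uniformly among candidates of
    length >= l (or weighted by the number of valid start positions when
    ``weighting='residue'``), then a start position uniformly in
    [0, length - l].  The output length multiset equals the input multiset
    exactly, and the draw is fully reproducible from the seed.
    """
    rng = np.random.default_rng(plan.seed)
    ids = sorted(plan.candidate_proteins)
    lengths = np.array([plan.candidate_proteins[i] for i in ids])
    order = np.argsort(lengths, kind="stable")
    sorted_lengths = lengths[order]
    max_len = int(sorted_lengths[-1])
    out: list[ProteinSegment] = []
    for k, l in enumerate(plan.lengths):
        if l < 1:
            raise ValueError(f"segment length {l} < 1")
        if l > max_len:
            raise ValueError(
                f"segment length {l} exceeds every candidate protein length"
            )
        first = bisect_left(sorted_lengths.tolist(), l)
        eligible = order[first:]
        if plan.weighting == "protein":
            pick = eligible[rng.integers(0, eligible.size)]
        else:
            weights = lengths[eligible] - l + 1
            pick = rng.choice(eligible, p=weights / weights.sum())
        pid = ids[int(pick)]
        start = int(rng.integers(0, plan.candidate_proteins[pid] - l + 1))
        out.append(
            ProteinSegment(
                protein_id=pid,
                start=start,
                end=start + l,
                provenance="reference",
                source_element_id=f"ref_{k}",
            )
        )
    return out


def descriptive_value(values: Iterable[float], property_kind: str) -> float:
    """Single summary value of a property's fraction distribution.

    Uses linear interpolation between order statistics (the spreadsheet-era
    percentile definition).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no values")
    try:
        q = DESCRIPTIVE_PERCENTILE[property_kind]
    except KeyError:
        raise ValueError(
            f"no descriptive value defined for property {property_kind!r}"
        ) from None
    return float(np.percentile(vals, q, method="linear"))


@dataclass
class PropertyComparison:
    """Counts and fraction vectors for one property, test vs reference."""

    property: str
    n_test: int
    n_test_assigned: int
    n_ref: int
    n_ref_assigned: int
    test_fractions: np.ndarray
    ref_fractions: np.ndarray

    @property
    def test_rate(self) -> float:
        return self.n_test_assigned / self.n_test

    @property
    def ref_rate(self) -> float:
        return self.n_ref_assigned / self.n_ref


def build_comparison_table(
    test_props: Sequence[SegmentProperties],
    ref_props: Sequence[SegmentProperties],
) -> dict[str, PropertyComparison]:
    """Per-property assigned counts and raw fraction vectors for rank tests."""
    if not test_props or not ref_props:
        raise ValueError("both segment property lists must be non-empty")
    out = {}
    for prop in PROPERTIES:
        out[prop] = PropertyComparison(
            property=prop,
            n_test=len(test_props),
            n_test_assigned=sum(p.assigned(prop) for p in test_props),
            n_ref=len(ref_props),
            n_ref_assigned=sum(p.assigned(prop) for p in ref_props),
            test_fractions=np.array([p.fraction(prop) for p in test_props]),
            ref_fractions=np.array([p.fraction(prop) for p in ref_props]),
        )
    return out
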