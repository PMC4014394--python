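"""Shared domain types.

Coordinate convention: every genomic or residue interval held in memory is
0-based, half-open.  File dialects that use other conventions (GTF, PfamScan,
1-based SCE tables) are converted exactly once, at the parsing boundary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np


class GenomicInterval(NamedTuple):
    """Half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SCERecord:
    """One synonymous constraint element.

    ``intervals`` are sorted 5'->3' in transcript orientation: ascending
    genomic start on '+', descending on '-'.
    """

    element_id: str
    window_codons: int
    gene_id: str
    intervals: tuple[GenomicInterval, ...]

    @property
    def span_nt(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom


@dataclass(frozen=True)
class SFBSRecord:
    """One experimentally validated splicing-factor binding site."""

    site_id: str
    gene_id: str
    interval: GenomicInterval
    factor_name: str
    is_mutant_gene: bool = False

    @property
    def length_nt(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class DisorderRegionAnnotation:
    """Experimentally validated disordered regions of one protein.

    Residue ranges are 0-based half-open and non-overlapping after
    normalization at parse time.
    """

    protein_id: str
    regions: tuple[tuple[int, int], ...]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript plus derived sequences.

    ``cds_blocks`` and ``exons`` are ordered in transcript (5'->3')
    orientation.  ``cds_sequence`` has the stop codon stripped, so
    ``len(cds_sequence) == 3 * len(protein_sequence)``.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_blocks: tuple[GenomicInterval, ...]
    cds_sequence: str
    protein_sequence: str
    protein_id: str = ""
    is_canonical: bool = False
    translation_ok: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            self.protein_id = self.transcript_id

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def protein_length(self) -> int:
        return len(self.protein_sequence)


class TranscriptSet:
    """Transcripts grouped by gene, with deterministic preference order."""

    def __init__(self, transcripts: Sequence[TranscriptModel] = ()) -> None:
        self._by_id: dict[str, TranscriptModel] = {}
        self._by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_id:
            raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
        self._by_id[t.transcript_id] = t
        self._by_gene.setdefault(t.gene_id, []).append(t)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        """Transcripts of a gene: canonical first, then CDS length descending,
        ties broken by transcript id."""
        txs = self._by_gene.get(gene_id, [])
        return sorted(
            txs,
            key=lambda t: (not t.is_canonical, -t.cds_length, t.transcript_id),
        )

    def canonical(self, gene_id: str) -> Optional[TranscriptModel]:
        txs = self.gene_transcripts(gene_id)
        return txs[0] if txs else None

    def proteome(self, canonical_only: bool = True) -> dict[str, str]:
        """protein_id -> sequence for translatable transcripts."""
        out: dict[str, str] = {}
        for gene in self.genes():
            txs = self.gene_transcripts(gene)
            if canonical_only:
                txs = txs[:1]
            for t in txs:
                if t.translation_ok:
                    out[t.protein_id] = t.protein_sequence
        return out


@dataclass(frozen=True)
class ProteinSegment:
    """Half-open residue range on one protein, with provenance."""

    protein_id: str
    start: int
    end: int
    provenance: str  # 'SCE' | 'SFBS' | 'reference' | 'control'
    source_element_id: str = ""
    window_codons: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment range [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MatchOutcome:
    """Result of locating an element's nucleotide sequence on a CDS."""

    status: str  # 'exact' | 'aligned' | 'rejected'
    cds_start: int = -1
    cds_end: int = -1
    identity: float = 0.0
    max_gap_run: int = 0
    note: str = ""


@dataclass
class StructuralAnnotation:
    """Per-residue structural tracks of one protein.

    The four tracks are independent of each other (no cross-derivation) and
    all have the same length as the protein.
    """

    protein_id: str
    disorder_scores: np.ndarray  # float, in [0, 1]
    low_complexity_mask: np.ndarray  # bool
    ss_states: np.ndarray  # '<U1', values 'H'/'E'/'C'
    domain_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.disorder_scores)
        for track in (self.low_complexity_mask, self.ss_states, self.domain_mask):
            if len(track) != n:
                raise ValueError(
                    f"{self.protein_id}: annotation tracks have unequal lengths"
                )

    def __len__(self) -> int:
        return len(self.disorder_scores)


@dataclass(frozen=True)
class SegmentProperties:
    """Per-segment structural property fractions and >=50% assignments."""

    disorder_fraction: float
    low_complexity_fraction: float
    ss_fraction: float
    domain_fraction: float
    is_disordered: bool
    is_low_complexity: bool
    is_ss: bool
    is_domain: bool

    def fraction(self, prop: str) -> float:
        return getattr(self, _FRACTION_FIELD[prop])

    def assigned(self, prop: str) -> bool:
        return getattr(self, _FLAG_FIELD[prop])


#: canonical property order used throughout the pipelines
PROPERTIES = ("disorder", "low_complexity", "secondary_structure", "domain")

#: direction of the enrichment the analysis expects for SCE segments
EXPECTED_SIGN = {
    "disorder": +1,
    "low_complexity": +1,
    "secondary_structure": -1,
    "domain": -1,
}

_FRACTION_FIELD = {
    "disorder": "disorder_fraction",
    "low_complexity": "low_complexity_fraction",
    "secondary_structure": "ss_fraction",
    "domain": "domain_fraction",
}
_FLAG_FIELD = {
    "disorder": "is_disordered",
    "low_complexity": "is_low_complexity",
    "secondary_structure": "is_ss",
    "domain": "is_domain",
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    __test__ = False  # not a pytest class despite the name

    method: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    two_sided: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ExclusionRecord:
    """Why an element could not be mapped to a protein segment."""

    element_id: str
    reasons: dict[str, str] = field(default_factory=dict)


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
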