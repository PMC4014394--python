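"""Self-contained toy study generator.

Produces a genome, multi-exon gene models on both strands, an exactly
consistent proteome, SCE tables at the three detection resolutions, an SFBS
site table (with the filter-exercising special cases), DisProt-style region
annotations, and ground-truth structural tracks in the external predictors'
file dialects.

The stated world: background residues are drawn uniformly over the 20 amino
acids; each planted SCE window resamples its codons from the mixture
``(1 - delta) * background + delta * disorder-promoting-only`` with the
window-size-dependent effect law ``delta(w) = delta0 * 9 / w``, so smaller
detection windows carry a stronger planted bias.  The disorder-promoting
component concentrates (weight 0.8) on one window-specific favored residue,
which gives planted windows the homorepeat character of real low-complexity
disordered regions - without it no amount of i.i.d. compositional bias at
``delta0 = 0.5`` drops a 12-mer window below the 2.2-bit entropy trigger,
and the low-complexity arm of the analysis would have nothing to detect.
Residues whose codons took the disorder-promoting branch are the ground-truth
disordered residues; secondary-structure elements and domain spans are
planted only inside ground-truth ordered regions.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from . import io_formats, predictors
from .types import (
    DisorderRegionAnnotation,
    GenomicInterval,
    SCERecord,
    SFBSRecord,
    StructuralAnnotation,
    TranscriptModel,
    TranscriptSet,
)

AA = predictors.AMINO_ACIDS
_CODONS_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

_NT = np.array(list("ACGT"))

__all__ = [
    "SyntheticConfig",
    "ProteinTruth",
    "StudyBundle",
    "generate_study",
    "plant_sce",
    "annotations_from_truth",
    "emit_ground_truth_tracks",
    "write_bundle",
]


@dataclass
class SyntheticConfig:
    """Tunable parameters of the toy study (defaults are the stated world)."""

    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (1, 4)
    protein_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (60, 300)
    intergenic_length_range: tuple[int, int] = (100, 300)
    n_chromosomes: int = 4
    strand_fraction: float = 0.5
    background_frequencies: Optional[dict[str, float]] = None  # uniform if None
    disorder_promoting: str = "ARGQSPEK"
    delta0: float = 0.5
    favored_weight: float = 0.8
    sce_counts: dict[int, int] = field(
        default_factory=lambda: {9: 300, 15: 300, 30: 300}
    )
    mutation_rate: float = 0.0
    n_sfbs: int = 40
    sfbs_length_p: float = 0.2  # nt length = min(49, 4 + geometric(p))
    disprot_region_prob: float = 0.5
    disprot_table_fraction: float = 0.6
    background_repeat_prob: float = 0.25
    noise_sd: float = 0.2
    truth_smoothing: int = 3
    special_cases: bool = True
    seed: int = 0

    def delta(self, window_codons: int) -> float:
        """Window-size effect law: delta(w) = delta0 * 9 / w, clipped to [0,1]."""
        return float(np.clip(self.delta0 * 9.0 / window_codons, 0.0, 1.0))

    def background_p(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(20, 0.05)
        p = np.array([self.background_frequencies[a] for a in AA], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("background frequencies must be a distribution")
        return p

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("exons_per_gene", "protein_length_range",
                    "intron_length_range", "intergenic_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "sce_counts" in d:
            d["sce_counts"] = {int(k): int(v) for k, v in d["sce_counts"].items()}
        return cls(**d)


@dataclass
class ProteinTruth:
    """Ground-truth per-residue structure of one synthetic protein."""

    disorder_mask: np.ndarray  # bool
    ss_states: np.ndarray  # '<U1'
    domain_spans: list[tuple[int, int, str]]  # (start, end, class)
    #: (window_codons, start_residue, end_residue, element_id)
    sce_windows: list[tuple[int, int, int, str]]

    def domain_mask(self) -> np.ndarray:
        mask = np.zeros(self.disorder_mask.size, dtype=bool)
        for s, e, cls in self.domain_spans:
            if cls == "A":
                mask[s:e] = True
        return mask


@dataclass
class _Gene:
    """Internal layout of one synthetic gene (single transcript)."""

    gene_id: str
    transcript_id: str
    protein_id: str
    chrom: str
    strand: str
    aa: np.ndarray  # '<U1'
    codons: list[str]
    cds_breaks: list[int]  # exon boundaries in CDS nt space (exclusive ends)
    genomic_blocks: list[tuple[int, int]] = field(default_factory=list)
    introns: list[str] = field(default_factory=list)
    region: tuple[int, int] = (0, 0)

    @property
    def protein(self) -> str:
        return "".join(self.aa)

    @property
    def cds(self) -> str:
        return "".join(self.codons)

    def cds_to_genomic(self, a: int, b: int) -> list[GenomicInterval]:
        """Genomic intervals (transcript order) of CDS nt range [a, b)."""
        out = []
        acc = 0
        for gs, ge in self.genomic_blocks:
            bl = ge - gs
            s = max(a, acc)
            e = min(b, acc + bl)
            if e > s:
                if self.strand == "+":
                    out.append(
                        GenomicInterval(self.chrom, gs + (s - acc), gs + (e - acc), "+")
                    )
                else:
                    out.append(
                        GenomicInterval(self.chrom, ge - (e - acc), ge - (s - acc), "-")
                    )
            acc += bl
        return out


@dataclass
class StudyBundle:
    """In-memory synthetic study: inputs plus ground truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    transcripts: TranscriptSet
    proteome: dict[str, str]  # canonical proteins
    sce_records: dict[int, list[SCERecord]]
    element_seqs: dict[str, str]
    sfbs_records: list[SFBSRecord]
    disprot: list[DisorderRegionAnnotation]
    truth: dict[str, ProteinTruth]


def _draw_background(rng, p: np.ndarray, size: int) -> np.ndarray:
    return np.array(list(AA))[rng.choice(20, size=size, p=p)]


def _resample_disordered(
    aa: np.ndarray,
    mask: np.ndarray,
    start: int,
    n: int,
    delta: float,
    rng,
    cfg: SyntheticConfig,
    bg_p: np.ndarray,
) -> list[int]:
    """Resample ``n`` residues from the planted mixture; returns the indices
    whose draw took the disorder-promoting branch (= true disordered).

    The background branch keeps the residue already in place (which is a
    background draw), so ``delta = 0`` leaves the sequence untouched and a
    null study's SCE windows are exchangeable with reference segments."""
    dp = cfg.disorder_promoting
    favored = dp[rng.integers(len(dp))]
    hits = []
    for i in range(start, start + n):
        if rng.random() < delta:
            if rng.random() < cfg.favored_weight:
                aa[i] = favored
            else:
                aa[i] = dp[rng.integers(len(dp))]
            mask[i] = True
            hits.append(i)
    return hits


def plant_sce(
    gene: _Gene,
    truth_mask: np.ndarray,
    start_codon: int,
    window_codons: int,
    delta: float,
    rng,
    cfg: SyntheticConfig,
    element_id: str,
) -> SCERecord:
    """Plant one SCE window in a laid-out gene and emit its genomic record.

    Each codon of the window is drawn from the mixture
    ``(1-delta)*background + delta*disorder-promoting-only``, the background
    component realised by keeping the background draw already in place;
    synonymous codons are kept where the amino acid is unchanged.  The record
    spans exon junctions when the window crosses one (multiple intervals).
    """
    L = gene.aa.size
    if not (0 <= start_codon and start_codon + window_codons <= L):
        raise ValueError("window exceeds CDS")
    bg_p = cfg.background_p()
    old = gene.aa[start_codon : start_codon + window_codons].copy()
    _resample_disordered(
        gene.aa, truth_mask, start_codon, window_codons, delta, rng, cfg, bg_p
    )
    for i in range(start_codon, start_codon + window_codons):
        if gene.aa[i] != old[i - start_codon]:
            options = _CODONS_FOR[str(gene.aa[i])]
            gene.codons[i] = options[rng.integers(len(options))]
    intervals = gene.cds_to_genomic(3 * start_codon, 3 * (start_codon + window_codons))
    return SCERecord(
        element_id=element_id,
        window_codons=window_codons,
        gene_id=gene.gene_id,
        intervals=tuple(intervals),
    )


def _random_nt(rng, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alternatives = [c for c in "ACGT" if c != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _plant_structure(
    truth_mask: np.ndarray, rng
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Secondary-structure states and domain spans inside ordered regions."""
    L = truth_mask.size
    ss = np.full(L, "C", dtype="<U1")
    spans: list[tuple[int, int, str]] = []
    i = 0
    while i < L:
        if truth_mask[i]:
            i += 1
            continue
        j = i
        while j < L and not truth_mask[j]:
            j += 1
        # ordered run [i, j)
        pos = i
        while pos < j:
            state = ("H", "E", "C")[rng.choice(3, p=[0.4, 0.25, 0.35])]
            if state == "H":
                ln = int(rng.integers(6, 15))
            elif state == "E":
                ln = int(rng.integers(4, 9))
            else:
                ln = int(rng.integers(3, 9))
            ln = min(ln, j - pos)
            if state != "C" and ln >= 3:
                ss[pos : pos + ln] = state
            pos += ln
        run = j - i
        if run >= 40 and rng.random() < 0.7:
            dl = int(rng.integers(30, min(81, run + 1)))
            off = int(rng.integers(0, run - dl + 1))
            cls = "A" if rng.random() < 0.9 else "B"
            spans.append((i + off, i + off + dl, cls))
        i = j
    return ss, spans


def _make_dual_gene(rng, chrom: str, start: int) -> tuple[list[TranscriptModel], dict]:
    """A single-exon gene read in two shifted frames (dual-coding), as in the
    FAS case: transcript B's CDS is transcript A's shifted by one nucleotide."""
    n_codons = 80
    L = 3 * n_codons + 1  # room for the +1 frame
    seq = _random_nt(rng, L)
    for _ in range(500):
        dirty = False
        for off in (0, 1):
            for k in range(off, L - 2, 3):
                if seq[k : k + 3] in io_formats.STOP_CODONS:
                    seq = seq[:k] + _random_nt(rng, 3) + seq[k + 3 :]
                    dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("could not build a stop-free dual-coding region")
    cds_a = seq[: 3 * n_codons]
    cds_b = seq[1 : 1 + 3 * (n_codons - 1)]
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    block_a = GenomicInterval(chrom, start, start + len(cds_a), "+")
    block_b = GenomicInterval(chrom, start + 1, start + 1 + len(cds_b), "+")
    tx_a = TranscriptModel(
        transcript_id="t_dualA", gene_id="g_dual", strand="+",
        exons=(block_a,), cds_blocks=(block_a,), cds_sequence=cds_a,
        protein_sequence=prot_a, protein_id="p_dualA", is_canonical=True,
    )
    tx_b = TranscriptModel(
        transcript_id="t_dualB", gene_id="g_dual", strand="+",
        exons=(block_b,), cds_blocks=(block_b,), cds_sequence=cds_b,
        protein_sequence=prot_b, protein_id="p_dualB",
    )
    return [tx_a, tx_b], {"seq": seq, "start": start, "chrom": chrom}


_FACTORS = ("SRSF1", "SRSF2", "hnRNPA1", "hnRNPH1", "TRA2B", "PTBP1", "TIA1")


def generate_study(config: SyntheticConfig | None = None) -> StudyBundle:
    """Generate the full toy study deterministically from ``config.seed``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    bg_p = cfg.background_p()
    lo, hi = cfg.protein_length_range
    genes: list[_Gene] = []
    truth_masks: list[np.ndarray] = []
    occupied: list[np.ndarray] = []
    disprot_regions: list[list[tuple[int, int]]] = []

    # --- stage 1: protein sequences with background features -------------
    for g in range(cfg.n_genes):
        L = int(rng.integers(lo, hi + 1))
        aa = _draw_background(rng, bg_p, L)
        aa[0] = "M"
        mask = np.zeros(L, dtype=bool)
        occ = np.zeros(L, dtype=bool)
        occ[0] = True
        regions: list[tuple[int, int]] = []
        if rng.random() < cfg.background_repeat_prob and L > 40:
            ln = int(rng.integers(10, 17))
            s = int(rng.integers(1, L - ln))
            aa[s : s + ln] = cfg.disorder_promoting[
                rng.integers(len(cfg.disorder_promoting))
            ]
            # SCE windows may overlap background repeats (as references can)
        if rng.random() < cfg.disprot_region_prob and L > 70:
            ln = int(rng.integers(20, min(61, L // 2 + 1)))
            s = int(rng.integers(1, L - ln))
            _resample_disordered(aa, mask, s, ln, 0.7, rng, cfg, bg_p)
            mask[s : s + ln] = True  # the whole region is annotated disordered
            regions.append((s, s + ln))
        strand = "+" if rng.random() < cfg.strand_fraction else "-"
        chrom = f"chr{g % cfg.n_chromosomes + 1}"
        genes.append(
            _Gene(
                gene_id=f"g{g}",
                transcript_id=f"t{g}",
                protein_id=f"p{g}",
                chrom=chrom,
                strand=strand,
                aa=aa,
                codons=[],
                cds_breaks=[],
            )
        )
        truth_masks.append(mask)
        occupied.append(occ)
        disprot_regions.append(regions)

    # --- stage 2: allocate SCE windows (positions only) -------------------
    placements: dict[int, list[tuple[int, int]]] = {}
    for w in sorted(cfg.sce_counts):
        n_elems = cfg.sce_counts[w]
        placements[w] = []
        for _ in range(n_elems):
            placed = False
            for _attempt in range(400):
                gi = int(rng.integers(cfg.n_genes))
                L = genes[gi].aa.size
                if L < w + 2:
                    continue
                s = int(rng.integers(1, L - w))
                # windows may overlap DisProt-style regions but not each other
                if occupied[gi][s : s + w].any():
                    continue
                occupied[gi][s : s + w] = True
                placements[w].append((gi, s))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"infeasible config: cannot place a {w}-codon SCE window"
                )

    # --- stage 3: back-translate ------------------------------------------
    for gene in genes:
        gene.codons = [
            _CODONS_FOR[str(a)][rng.integers(len(_CODONS_FOR[str(a)]))]
            for a in gene.aa
        ]

    # --- stage 4: exon structure and genomic layout ------------------------
    cursors = {f"chr{c + 1}": 0 for c in range(cfg.n_chromosomes)}
    for gene in genes:
        cds_len = 3 * gene.aa.size
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_ex = min(n_ex, cds_len // 2)
        breaks = sorted(
            int(b) for b in rng.choice(np.arange(1, cds_len), n_ex - 1, replace=False)
        ) if n_ex > 1 else []
        gene.cds_breaks = breaks
        bounds = [0] + breaks + [cds_len]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        gene.introns = [
            _random_nt(rng, int(rng.integers(*cfg.intron_length_range)))
            for _ in range(len(exon_lens) - 1)
        ]
        spacer = int(rng.integers(*cfg.intergenic_length_range))
        gene_start = cursors[gene.chrom] + spacer
        region_len = sum(exon_lens) + sum(len(i) for i in gene.introns)
        gene.region = (gene_start, gene_start + region_len)
        cursors[gene.chrom] = gene_start + region_len
        blocks = []
        if gene.strand == "+":
            pos = gene_start
            for i, el in enumerate(exon_lens):
                blocks.append((pos, pos + el))
                pos += el
                if i < len(gene.introns):
                    pos += len(gene.introns[i])
        else:
            pos = gene_start + region_len
            for i, el in enumerate(exon_lens):
                blocks.append((pos - el, pos))
                pos -= el
                if i < len(gene.introns):
                    pos -= len(gene.introns[i])
        gene.genomic_blocks = blocks

    # --- stage 5: plant SCEs ----------------------------------------------
    sce_records: dict[int, list[SCERecord]] = {}
    sce_ranges: dict[str, list[tuple[int, int, int]]] = {
        g.protein_id: [] for g in genes
    }
    for w in sorted(placements):
        delta = cfg.delta(w)
        records = []
        for idx, (gi, s) in enumerate(placements[w]):
            gene = genes[gi]
            rec = plant_sce(
                gene, truth_masks[gi], s, w, delta, rng, cfg, f"sce{w}_{idx}"
            )
            records.append(rec)
            sce_ranges[gene.protein_id].append((w, s, s + w, rec.element_id))
        sce_records[w] = records

    # --- stage 6: special cases and SFBS sites -----------------------------
    extra_transcripts: list[TranscriptModel] = []
    dual_info = None
    if cfg.special_cases:
        dual_chrom = "chr1"
        dual_start = cursors[dual_chrom] + 200
        extra_transcripts, dual_info = _make_dual_gene(rng, dual_chrom, dual_start)
        cursors[dual_chrom] = dual_start + len(dual_info["seq"])

    sfbs_records: list[SFBSRecord] = []

    def _site_in_gene(gene: _Gene, length_nt: int, site_id: str, **kw) -> Optional[SFBSRecord]:
        bounds = [0] + gene.cds_breaks + [3 * gene.aa.size]
        eligible = [
            i
            for i in range(len(bounds) - 1)
            if bounds[i + 1] - bounds[i] >= length_nt
        ]
        if not eligible:
            return None
        bi = eligible[int(rng.integers(len(eligible)))]
        off = int(rng.integers(bounds[bi], bounds[bi + 1] - length_nt + 1))
        iv = gene.cds_to_genomic(off, off + length_nt)[0]
        return SFBSRecord(
            site_id=site_id,
            gene_id=gene.gene_id,
            interval=iv,
            factor_name=_FACTORS[int(rng.integers(len(_FACTORS)))],
            **kw,
        )

    for i in range(cfg.n_sfbs):
        length = int(min(49, 5 + rng.geometric(cfg.sfbs_length_p) - 1))
        for _ in range(50):
            gene = genes[int(rng.integers(cfg.n_genes))]
            site = _site_in_gene(gene, length, f"sfbs{i}")
            if site is not None:
                sfbs_records.append(site)
                break
    if cfg.special_cases and sfbs_records:
        gene0 = genes[0]
        mutant = _site_in_gene(gene0, 8, "sfbs_mut", is_mutant_gene=True)
        if mutant:
            sfbs_records.append(mutant)
        first = sfbs_records[0]
        sfbs_records.append(
            SFBSRecord(
                site_id="sfbs_dup",
                gene_id=first.gene_id,
                interval=first.interval,
                factor_name=first.factor_name,
            )
        )
        for ln, sid in ((4, "sfbs_len4"), (50, "sfbs_len50")):
            for gene in genes:
                site = _site_in_gene(gene, ln, sid)
                if site is not None:
                    sfbs_records.append(site)
                    break
        if dual_info is not None:
            s0 = dual_info["start"]
            for k, (off, ln) in enumerate(((6, 9), (21, 6))):
                sfbs_records.append(
                    SFBSRecord(
                        site_id=f"sfbs_dual{k}",
                        gene_id="g_dual",
                        interval=GenomicInterval(
                            dual_info["chrom"], s0 + off, s0 + off + ln, "+"
                        ),
                        factor_name="TIA1",
                    )
                )

    # --- stage 7: assemble the genome --------------------------------------
    chrom_parts: dict[str, list[tuple[int, str]]] = {
        f"chr{c + 1}": [] for c in range(cfg.n_chromosomes)
    }
    for gene in genes:
        bounds = [0] + gene.cds_breaks + [3 * gene.aa.size]
        cds = gene.cds
        pieces = []
        for i in range(len(bounds) - 1):
            pieces.append(cds[bounds[i] : bounds[i + 1]])
            if i < len(gene.introns):
                pieces.append(gene.introns[i])
        tx_seq = "".join(pieces)
        region_seq = (
            tx_seq
            if gene.strand == "+"
            else str(Seq(tx_seq).reverse_complement())
        )
        chrom_parts[gene.chrom].append((gene.region[0], region_seq))
    if dual_info is not None:
        chrom_parts[dual_info["chrom"]].append(
            (dual_info["start"], dual_info["seq"])
        )
    genome: dict[str, str] = {}
    for chrom, parts in chrom_parts.items():
        parts.sort()
        end = max((s + len(seq) for s, seq in parts), default=0) + 100
        arr = np.array(list(_random_nt(rng, end)))
        for s, seq in parts:
            arr[s : s + len(seq)] = list(seq)
        genome[chrom] = "".join(arr)

    # --- stage 8: transcript models, truth, element sequences --------------
    tset = TranscriptSet()
    truth: dict[str, ProteinTruth] = {}
    proteome: dict[str, str] = {}
    for gene, mask in zip(genes, truth_masks):
        blocks = tuple(
            GenomicInterval(gene.chrom, s, e, gene.strand)
            for s, e in gene.genomic_blocks
        )
        model = TranscriptModel(
            transcript_id=gene.transcript_id,
            gene_id=gene.gene_id,
            strand=gene.strand,
            exons=blocks,
            cds_blocks=blocks,
            cds_sequence=gene.cds,
            protein_sequence=gene.protein,
            protein_id=gene.protein_id,
            is_canonical=True,
        )
        tset.add(model)
        proteome[gene.protein_id] = gene.protein
        ss, spans = _plant_structure(mask, rng)
        truth[gene.protein_id] = ProteinTruth(
            disorder_mask=mask,
            ss_states=ss,
            domain_spans=spans,
            sce_windows=sce_ranges[gene.protein_id],
        )
    for tx in extra_transcripts:
        tset.add(tx)
        proteome[tx.protein_id] = tx.protein_sequence
        m = np.zeros(tx.protein_length, dtype=bool)
        ss, spans = _plant_structure(m, rng)
        truth[tx.protein_id] = ProteinTruth(m, ss, spans, [])

    element_seqs: dict[str, str] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for w, records in sce_records.items():
        for rec in records:
            gene = gene_by_id[rec.gene_id]
            proj_seq = []
            for iv in rec.intervals:
                piece = genome[iv.chrom][iv.start : iv.end]
                if iv.strand == "-":
                    piece = str(Seq(piece).reverse_complement())
                proj_seq.append(piece)
            element_seqs[rec.element_id] = _mutate(
                "".join(proj_seq), cfg.mutation_rate, rng
            )

    disprot = []
    for gene, regions in zip(genes, disprot_regions):
        if regions and rng.random() < cfg.disprot_table_fraction:
            disprot.append(
                DisorderRegionAnnotation(gene.protein_id, tuple(regions))
            )

    return StudyBundle(
        config=cfg,
        genome=genome,
        transcripts=tset,
        proteome=proteome,
        sce_records=sce_records,
        element_seqs=element_seqs,
        sfbs_records=sfbs_records,
        disprot=disprot,
        truth=truth,
    )


def _smooth_mask(mask: np.ndarray, window: int) -> np.ndarray:
    vals = mask.astype(float)
    if window <= 1:
        return vals
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = vals.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def annotations_from_truth(
    bundle: StudyBundle,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
) -> dict[str, StructuralAnnotation]:
    """Ground-truth structural tracks, perturbed the way the emitted files are.

    Disorder scores are the (lightly smoothed) true mask plus Gaussian noise,
    clamped to [0, 1] and rounded to 3 decimals so that the file round trip
    is lossless; secondary structure and domains are the planted truth; the
    low-complexity mask is always computed internally from the sequence.
    """
    cfg = bundle.config
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    out: dict[str, StructuralAnnotation] = {}
    params = predictors.default_complexity_params()
    for pid in sorted(bundle.proteome):
        seq = bundle.proteome[pid]
        t = bundle.truth[pid]
        scores = _smooth_mask(t.disorder_mask, cfg.truth_smoothing)
        if sd > 0:
            scores = scores + rng.normal(0.0, sd, size=scores.size)
        scores = np.round(np.clip(scores, 0.0, 1.0), 3)
        out[pid] = StructuralAnnotation(
            protein_id=pid,
            disorder_scores=scores,
            low_complexity_mask=predictors.low_complexity_mask(seq, params),
            ss_states=t.ss_states.copy(),
            domain_mask=t.domain_mask(),
        )
    return out


def emit_ground_truth_tracks(
    bundle: StudyBundle,
    outdir,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
) -> dict[str, StructuralAnnotation]:
    """Write the annotation tracks in the external predictors' dialects.

    Emits one 2-column disorder score file and one PSIPRED-style ``.ss2``
    per protein plus a single PfamScan-style table (class-B entries included
    so that the parser's A-class filter is exercised).  Returns the same
    annotations the files encode.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = annotations_from_truth(bundle, noise_sd=noise_sd, seed=seed)
    pfam_rows = []
    for pid in sorted(annotations):
        ann = annotations[pid]
        io_formats.write_disorder_scores(ann.disorder_scores, outdir / f"{pid}.diso")
        io_formats.write_ss2(bundle.proteome[pid], ann.ss_states, outdir / f"{pid}.ss2")
        for k, (s, e, cls) in enumerate(bundle.truth[pid].domain_spans):
            pfam_rows.append(
                (pid, s, e, f"SYN{k:04d}", f"synth_dom_{k}", "Domain", cls)
            )
    io_formats.write_pfamscan(pfam_rows, outdir / "pfamscan.tsv")
    return annotations


def write_bundle(bundle: StudyBundle, outdir, tracks: bool = True) -> dict[str, Path]:
    """Serialize the study to its on-disk file formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    io_formats.write_fasta(bundle.genome, paths["genome"])
    paths["gtf"] = outdir / "genes.gtf"
    io_formats.write_gtf(list(bundle.transcripts), paths["gtf"])
    proteins = {
        t.protein_id: t.protein_sequence
        for t in bundle.transcripts
        if t.translation_ok
    }
    paths["proteins"] = outdir / "proteins.fa"
    io_formats.write_fasta(proteins, paths["proteins"])
    for w, records in sorted(bundle.sce_records.items()):
        p = outdir / f"sce_{w}.tsv"
        io_formats.write_sce_table(records, p)
        paths[f"sce_{w}"] = p
    paths["elements"] = outdir / "elements.fa"
    io_formats.write_fasta(bundle.element_seqs, paths["elements"])
    paths["sfbs"] = outdir / "sfbs.tsv"
    io_formats.write_sfbs_table(bundle.sfbs_records, paths["sfbs"])
    paths["disprot"] = outdir / "disprot.tsv"
    io_formats.write_disprot_table(bundle.disprot, paths["disprot"])
    paths["config"] = outdir / "config.yaml"
    bundle.config.to_yaml(paths["config"])
    if tracks:
        paths["tracks"] = outdir / "tracks"
        emit_ground_truth_tracks(bundle, paths["tracks"])
    return paths
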