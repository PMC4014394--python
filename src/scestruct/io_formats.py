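"""Readers and writers for every file dialect the pipeline touches.

Parsing policy: malformed rows are rejected and logged with a reason, never
silently repaired; every reader reports its rejected-row count.  All
coordinates are converted to the internal 0-based half-open convention
exactly once, here.

Dialects handled: BED-like SCE tables (configurable 0/1-based), SFBS site
tables, DisProt-style region TSVs, GTF gene models (via gffutils) with
genome/protein FASTA (via Biopython), PSIPRED ``.ss2`` vertical files,
PfamScan-style tabular domain files, 2-column per-residue disorder score
files, and the package's own segment TSV (which round-trips bit-identically
through its reader).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from . import predictors
from .types import (
    DisorderRegionAnnotation,
    GenomicInterval,
    ProteinSegment,
    SCERecord,
    SegmentProperties,
    SFBSRecord,
    StructuralAnnotation,
    TranscriptModel,
    TranscriptSet,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_SCE_COLUMNS = {
    "chrom": 0,
    "start": 1,
    "end": 2,
    "strand": 3,
    "gene_id": 4,
    "element_id": 5,
}

DEFAULT_SFBS_COLUMNS = {
    "site_id": 0,
    "gene_id": 1,
    "chrom": 2,
    "start": 3,
    "end": 4,
    "strand": 5,
    "factor_name": 6,
    "is_mutant_gene": 7,
}


@dataclass
class ParseReport:
    """Bookkeeping for one parsed file: kept and rejected row counts."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def reject(self, line_no: int, reason: str) -> None:
        self.rejected.append((line_no, reason))
        logger.warning("%s line %d rejected: %s", self.path, line_no, reason)


def normalize_interval(start: int, end: int, coord_base: int) -> tuple[int, int]:
    """Convert a file interval to internal 0-based half-open coordinates.

    ``coord_base=0`` means the file already is 0-based half-open (identity);
    ``coord_base=1`` means 1-based fully-closed (start-1, end unchanged).
    """
    if coord_base == 0:
        return start, end
    if coord_base == 1:
        return start - 1, end
    raise ValueError(f"unsupported coordinate base {coord_base!r}")


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line.split("\t")


# ---------------------------------------------------------------------------
# SCE / SFBS / DisProt tables
# ---------------------------------------------------------------------------

def read_sce_table(
    path,
    window_codons: int,
    column_map: Optional[dict[str, int]] = None,
    coord_base: int = 0,
) -> tuple[list[SCERecord], ParseReport]:
    """Read a BED-like SCE table; rows sharing an element id form one record.

    Rows that violate the record invariants (empty interval, unknown strand,
    mixed chrom/strand within an element, overlapping intervals, total span
    < 3 nt) are dropped and logged with the reason.
    """
    cols = column_map or DEFAULT_SCE_COLUMNS
    report = ParseReport(str(path))
    raw: dict[str, list[tuple[int, GenomicInterval, str]]] = {}
    order: list[str] = []
    for line_no, fields in _data_lines(path):
        report.n_rows += 1
        try:
            chrom = fields[cols["chrom"]]
            start = int(fields[cols["start"]])
            end = int(fields[cols["end"]])
            strand = fields[cols["strand"]]
            gene_id = fields[cols["gene_id"]]
            element_id = fields[cols["element_id"]]
        except (IndexError, ValueError) as exc:
            report.reject(line_no, f"malformed row: {exc}")
            continue
        if strand not in ("+", "-"):
            report.reject(line_no, f"unknown strand symbol {strand!r}")
            continue
        s, e = normalize_interval(start, end, coord_base)
        if e <= s:
            report.reject(line_no, "empty interval")
            continue
        if element_id not in raw:
            order.append(element_id)
        raw.setdefault(element_id, []).append(
            (line_no, GenomicInterval(chrom, s, e, strand), gene_id)
        )
    records: list[SCERecord] = []
    for element_id in order:
        rows = raw[element_id]
        line_no = rows[0][0]
        ivs = [iv for _, iv, _ in rows]
        genes = {g for _, _, g in rows}
        if len({(iv.chrom, iv.strand) for iv in ivs}) > 1 or len(genes) > 1:
            report.reject(line_no, f"{element_id}: mixed chrom/strand/gene")
            continue
        ivs.sort(key=lambda iv: iv.start)
        if any(a.end > b.start for a, b in zip(ivs, ivs[1:])):
            report.reject(line_no, f"{element_id}: overlapping intervals")
            continue
        if sum(iv.length for iv in ivs) < 3:
            report.reject(line_no, f"{element_id}: total span < 3 nt")
            continue
        if ivs[0].strand == "-":
            ivs = ivs[::-1]  # transcript orientation
        records.append(
            SCERecord(
                element_id=element_id,
                window_codons=window_codons,
                gene_id=next(iter(genes)),
                intervals=tuple(ivs),
            )
        )
        report.n_kept += 1
    return records, report


def write_sce_table(records: Sequence[SCERecord], path) -> None:
    """Write SCE records in the package's 0-based half-open dialect."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tstrand\tgene_id\telement_id\n")
        for rec in records:
            for iv in rec.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}"
                    f"\t{rec.gene_id}\t{rec.element_id}\n"
                )


def read_sfbs_table(
    path,
    column_map: Optional[dict[str, int]] = None,
    coord_base: int = 0,
) -> tuple[list[SFBSRecord], ParseReport]:
    """Read an SFBS site table (one interval per site)."""
    cols = column_map or DEFAULT_SFBS_COLUMNS
    report = ParseReport(str(path))
    records: list[SFBSRecord] = []
    for line_no, fields in _data_lines(path):
        report.n_rows += 1
        try:
            site_id = fields[cols["site_id"]]
            gene_id = fields[cols["gene_id"]]
            chrom = fields[cols["chrom"]]
            start = int(fields[cols["start"]])
            end = int(fields[cols["end"]])
            strand = fields[cols["strand"]]
            factor = fields[cols["factor_name"]]
            mutant = fields[cols["is_mutant_gene"]] in ("1", "true", "True", "yes")
        except (IndexError, ValueError) as exc:
            report.reject(line_no, f"malformed row: {exc}")
            continue
        if strand not in ("+", "-"):
            report.reject(line_no, f"unknown strand symbol {strand!r}")
            continue
        s, e = normalize_interval(start, end, coord_base)
        if e - s < 1:
            report.reject(line_no, "empty interval")
            continue
        records.append(
            SFBSRecord(
                site_id=site_id,
                gene_id=gene_id,
                interval=GenomicInterval(chrom, s, e, strand),
                factor_name=factor,
                is_mutant_gene=mutant,
            )
        )
        report.n_kept += 1
    return records, report


def write_sfbs_table(records: Sequence[SFBSRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# site_id\tgene_id\tchrom\tstart\tend\tstrand\tfactor\tmutant\n"
        )
        for r in records:
            iv = r.interval
            fh.write(
                f"{r.site_id}\t{r.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{iv.strand}\t{r.factor_name}\t{int(r.is_mutant_gene)}\n"
            )


def read_disprot_table(
    path, coord_base: int = 1
) -> tuple[list[DisorderRegionAnnotation], ParseReport]:
    """Read DisProt-style region annotations (default 1-based inclusive).

    Overlapping or adjacent regions of the same protein are merged during
    normalization.
    """
    report = ParseReport(str(path))
    raw: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for line_no, fields in _data_lines(path):
        report.n_rows += 1
        try:
            pid, start, end = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError) as exc:
            report.reject(line_no, f"malformed row: {exc}")
            continue
        s, e = normalize_interval(start, end, coord_base)
        if e <= s:
            report.reject(line_no, "empty region")
            continue
        if pid not in raw:
            order.append(pid)
        raw.setdefault(pid, []).append((s, e))
        report.n_kept += 1
    annotations = []
    for pid in order:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(raw[pid]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        annotations.append(DisorderRegionAnnotation(pid, tuple(merged)))
    return annotations, report


def write_disprot_table(annotations: Sequence[DisorderRegionAnnotation], path) -> None:
    """Write regions in the conventional 1-based inclusive dialect."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tstart\tend\n")
        for ann in annotations:
            for s, e in ann.regions:
                fh.write(f"{ann.protein_id}\t{s + 1}\t{e}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _truthy_attr(feature, key: str) -> bool:
    vals = feature.attributes.get(key, [])
    return any(str(v).lower() in ("1", "true", "yes") for v in vals)


def read_gene_models(
    gtf_path,
    genome_fasta,
    protein_fasta=None,
) -> tuple[TranscriptSet, ParseReport]:
    """Build a TranscriptSet from a GTF plus genome (and optional protein) FASTA.

    Each transcript's spliced CDS is extracted (reverse-complemented on '-'),
    the initial phase trimmed, a trailing stop codon stripped, and the
    translation checked against the supplied protein FASTA entry when one
    exists; a mismatch flags the transcript and excludes it from mapping.
    """
    report = ParseReport(str(gtf_path))
    genome = read_fasta(genome_fasta)
    proteins = read_fasta(protein_fasta) if protein_fasta else {}
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        if tid not in per_tx:
            order.append(tid)
            per_tx[tid] = {
                "gene_id": feat.attributes["gene_id"][0],
                "protein_id": feat.attributes.get("protein_id", [tid])[0],
                "strand": feat.strand,
                "chrom": feat.seqid,
                "canonical": False,
                "exons": [],
                "cds": [],
            }
        info = per_tx[tid]
        if _truthy_attr(feat, "canonical"):
            info["canonical"] = True
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            info["exons"].append(iv)
        else:
            frame = 0
            if feat.frame not in (None, ".", ""):
                frame = int(feat.frame)
            info["cds"].append((iv, frame))

    tset = TranscriptSet()
    for tid in order:
        info = per_tx[tid]
        report.n_rows += 1
        if not info["cds"]:
            report.reject(0, f"{tid}: no CDS features")
            continue
        if info["chrom"] not in genome:
            report.reject(0, f"{tid}: chromosome {info['chrom']!r} not in genome")
            continue
        minus = info["strand"] == "-"
        cds_sorted = sorted(
            info["cds"], key=lambda x: x[0].start, reverse=minus
        )
        exons = tuple(
            sorted(info["exons"], key=lambda iv: iv.start, reverse=minus)
        )
        chrom_seq = genome[info["chrom"]]
        pieces = []
        for iv, _frame in cds_sorted:
            piece = chrom_seq[iv.start : iv.end]
            if minus:
                piece = str(Seq(piece).reverse_complement())
            pieces.append(piece)
        cds_seq = "".join(pieces)
        first_frame = cds_sorted[0][1]
        if first_frame:
            cds_seq = cds_seq[first_frame:]
        translation_ok = True
        notes = ""
        if len(cds_seq) % 3 != 0:
            translation_ok = False
            notes = "CDS length not divisible by 3"
            protein = ""
        else:
            if cds_seq[-3:] in STOP_CODONS:
                cds_seq = cds_seq[:-3]
            protein = str(Seq(cds_seq).translate())
            if "*" in protein:
                translation_ok = False
                notes = "internal stop codon"
        pid = info["protein_id"]
        if translation_ok and pid in proteins and proteins[pid] != protein:
            translation_ok = False
            notes = "translation mismatches supplied protein FASTA"
            logger.warning("%s: %s", tid, notes)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            strand=info["strand"],
            exons=exons,
            cds_blocks=tuple(iv for iv, _ in cds_sorted),
            cds_sequence=cds_seq,
            protein_sequence=protein,
            protein_id=pid,
            is_canonical=info["canonical"],
            translation_ok=translation_ok,
            notes=notes,
        )
        tset.add(model)
        if translation_ok:
            report.n_kept += 1
        else:
            report.reject(0, f"{tid}: {notes}")
    return tset, report


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write exon and CDS features (GTF is 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'protein_id "{t.protein_id}";'
            )
            if t.is_canonical:
                attrs += ' canonical "1";'
            for ftype, blocks in (("exon", t.exons), ("CDS", t.cds_blocks)):
                for iv in blocks:
                    frame = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{iv.chrom}\tscestruct\t{ftype}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{iv.strand}\t{frame}\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# External predictor dialects
# ---------------------------------------------------------------------------

def read_disorder_scores(path, protein_length: int) -> np.ndarray:
    """2-column per-residue disorder score file (1-based index, score)."""
    scores = np.full(protein_length, np.nan)
    for line_no, fields in _data_lines(path):
        try:
            idx = int(fields[0])
            val = float(fields[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path} line {line_no}: malformed row ({exc})")
        if not (1 <= idx <= protein_length):
            raise ValueError(f"{path} line {line_no}: residue index {idx} out of range")
        scores[idx - 1] = val
    if np.any(np.isnan(scores)):
        raise ValueError(f"{path}: track length mismatch with protein")
    return scores


def write_disorder_scores(scores: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue\tscore\n")
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.3f}\n")


def read_ss2(path, protein_length: int) -> np.ndarray:
    """PSIPRED vertical ``.ss2`` dialect: index, residue, state, 3 scores."""
    states = np.full(protein_length, "", dtype="<U1")
    for line_no, raw in _data_lines(path):
        fields = " ".join(raw).split()
        if not fields or not fields[0].isdigit():
            continue  # the VFORMAT banner line
        idx = int(fields[0])
        state = fields[2]
        if state not in ("H", "E", "C"):
            raise ValueError(f"{path} line {line_no}: unknown state {state!r}")
        if not (1 <= idx <= protein_length):
            raise ValueError(f"{path} line {line_no}: residue index out of range")
        states[idx - 1] = state
    if np.any(states == ""):
        raise ValueError(f"{path}: track length mismatch with protein")
    return states


def write_ss2(sequence: str, states: np.ndarray, path) -> None:
    conf = {"C": (0.8, 0.1, 0.1), "H": (0.1, 0.8, 0.1), "E": (0.1, 0.1, 0.8)}
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (scestruct synthetic tracks)\n\n")
        for i, (aa, st) in enumerate(zip(sequence, states), start=1):
            c, h, e = conf[str(st)]
            fh.write(f"{i:4d} {aa} {st}  {c:.3f} {h:.3f} {e:.3f}\n")


def read_pfamscan(path, protein_id: str, protein_length: int) -> np.ndarray:
    """Domain mask from a PfamScan-style table; only class-"A" rows count.

    Columns: seq_id, env_start, env_end (1-based inclusive), accession,
    name, entry_type, class.
    """
    mask = np.zeros(protein_length, dtype=bool)
    for line_no, raw in _data_lines(path):
        fields = " ".join(raw).split()
        if len(fields) < 7:
            raise ValueError(f"{path} line {line_no}: malformed row")
        if fields[0] != protein_id:
            continue
        env_start, env_end = int(fields[1]), int(fields[2])
        domain_class = fields[6]
        if domain_class != "A":
            continue
        s, e = normalize_interval(env_start, env_end, coord_base=1)
        if not (0 <= s < e <= protein_length):
            raise ValueError(
                f"{path} line {line_no}: envelope outside protein ({protein_id})"
            )
        mask[s:e] = True
    return mask


def write_pfamscan(rows: Sequence[tuple], path) -> None:
    """rows: (protein_id, start0, end0, accession, name, entry_type, class)."""
    with open(path, "w") as fh:
        fh.write("# seq_id env_start env_end hmm_acc hmm_name type class\n")
        for pid, s, e, acc, name, etype, cls in rows:
            fh.write(f"{pid} {s + 1} {e} {acc} {name} {etype} {cls}\n")


def read_annotation_tracks(
    protein_id: str,
    sequence: str,
    sources: dict,
    complexity_params: Optional[predictors.ComplexityParams] = None,
) -> StructuralAnnotation:
    """Assemble a StructuralAnnotation from external track files.

    ``sources`` maps track names to file paths: ``disorder`` (2-column score
    file), ``ss2`` (PSIPRED vertical), ``pfamscan`` (tabular, class-A entries
    only).  Missing tracks default to a neutral value; the low-complexity
    mask is always computed internally from the sequence.  A track whose
    length disagrees with the protein is fatal for this protein.
    """
    n = len(sequence)
    disorder = None
    ss = None
    domains = None
    if "disorder" in sources:
        disorder = read_disorder_scores(sources["disorder"], n)
    if "ss2" in sources:
        ss = read_ss2(sources["ss2"], n)
    if "pfamscan" in sources:
        domains = read_pfamscan(sources["pfamscan"], protein_id, n)
    return predictors.build_annotation(
        protein_id,
        sequence,
        disorder=disorder,
        ss_states=ss,
        domain_mask=domains,
        complexity_params=complexity_params,
    )


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

_SEGMENT_HEADER = (
    "# protein_id\tstart\tend\tlength\tprovenance\tsource_element_id"
    "\twindow_codons\tdisorder_fraction\tlow_complexity_fraction"
    "\tss_fraction\tdomain_fraction\tis_disordered\tis_low_complexity"
    "\tis_ss\tis_domain\n"
)


def write_segment_table(
    segments_with_properties: Sequence[tuple[ProteinSegment, SegmentProperties]],
    path,
) -> None:
    """Write the per-segment property table (TSV, '#'-prefixed header).

    Floats are written with ``repr`` so that write -> read -> write is
    byte-identical.
    """
    with open(path, "w") as fh:
        fh.write(_SEGMENT_HEADER)
        for seg, props in segments_with_properties:
            w = "" if seg.window_codons is None else str(seg.window_codons)
            fh.write(
                "\t".join(
                    [
                        seg.protein_id,
                        str(seg.start),
                        str(seg.end),
                        str(seg.length),
                        seg.provenance,
                        seg.source_element_id,
                        w,
                        repr(props.disorder_fraction),
                        repr(props.low_complexity_fraction),
                        repr(props.ss_fraction),
                        repr(props.domain_fraction),
                        str(int(props.is_disordered)),
                        str(int(props.is_low_complexity)),
                        str(int(props.is_ss)),
                        str(int(props.is_domain)),
                    ]
                )
                + "\n"
            )


def read_segment_table(path) -> list[tuple[ProteinSegment, SegmentProperties]]:
    out = []
    for line_no, fields in _data_lines(path):
        if len(fields) != 15:
            raise ValueError(f"{path} line {line_no}: expected 15 columns")
        seg = ProteinSegment(
            protein_id=fields[0],
            start=int(fields[1]),
            end=int(fields[2]),
            provenance=fields[4],
            source_element_id=fields[5],
            window_codons=int(fields[6]) if fields[6] else None,
        )
        props = SegmentProperties(
            disorder_fraction=float(fields[7]),
            low_complexity_fraction=float(fields[8]),
            ss_fraction=float(fields[9]),
            domain_fraction=float(fields[10]),
            is_disordered=bool(int(fields[11])),
            is_low_complexity=bool(int(fields[12])),
            is_ss=bool(int(fields[13])),
            is_domain=bool(int(fields[14])),
        )
        out.append((seg, props))
    return out
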