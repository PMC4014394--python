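"""Run manifests and human-readable reports.

The manifest records everything needed to reproduce a run bit-identically:
a hash of the configuration, the seeds, checksums of the input files, and
the per-stage record counts (mapped / excluded / filtered with reasons),
mirroring the bookkeeping style of the original study (counts and
percentages of unmapped elements per resolution).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .enrichment_pipelines import StudyResult
from .types import ProteinSegment, StructuralAnnotation, TestResult

__all__ = [
    "RunManifest",
    "config_hash",
    "file_checksum",
    "protein_report",
    "study_report",
    "result_summary",
]


def config_hash(config) -> str:
    """Stable SHA-256 over a config dataclass/dict (sorted YAML dump)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    dumped = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(dumped.encode()).hexdigest()


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_digest: str
    seeds: dict[str, int] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    package_version: str = "0.1.0"
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def comparable(self) -> dict:
        """Everything except the timestamp (identical runs match on this)."""
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _render_mask(mask: np.ndarray, on: str = "#", off: str = ".") -> str:
    return "".join(on if m else off for m in mask)


def protein_report(
    protein_id: str,
    sequence: str,
    annotation: StructuralAnnotation,
    segments: Sequence[ProteinSegment] = (),
    width: int = 60,
) -> str:
    """Plain-text per-protein track report (sequence, disorder, low
    complexity, secondary structure, domains, and any overlapping segments)."""
    n = len(sequence)
    disorder_mask = annotation.disorder_scores >= 0.5
    seg_mask = np.zeros(n, dtype=bool)
    for seg in segments:
        if seg.protein_id == protein_id:
            seg_mask[seg.start : seg.end] = True
    lines = [f"# {protein_id} ({n} residues)"]
    for start in range(0, n, width):
        sl = slice(start, min(n, start + width))
        lines.append(f"@ {start + 1}")
        lines.append("seq  " + sequence[sl])
        lines.append("dis  " + _render_mask(disorder_mask[sl], "D"))
        lines.append("lcx  " + _render_mask(annotation.low_complexity_mask[sl], "L"))
        lines.append("ss   " + "".join(
            s if s in "HE" else "." for s in annotation.ss_states[sl]
        ))
        lines.append("dom  " + _render_mask(annotation.domain_mask[sl], "M"))
        if seg_mask.any():
            lines.append("seg  " + _render_mask(seg_mask[sl], "S"))
    for seg in segments:
        if seg.protein_id == protein_id:
            lines.append(
                f"segment {seg.source_element_id or seg.provenance}: "
                f"residues {seg.start + 1}-{seg.end} ({seg.provenance})"
            )
    return "\n".join(lines) + "\n"


def _fmt_test(t: TestResult) -> str:
    df = f", df={t.df}" if t.df is not None else ""
    note = f" [{t.notes}]" if t.notes else ""
    return f"{t.method}: stat={t.statistic:.4g}{df}, p={t.p_value:.4g}{note}"


def result_summary(result: StudyResult) -> dict:
    """JSON-serializable summary of a StudyResult."""

    def _clean(obj):
        if isinstance(obj, TestResult):
            return {
                "method": obj.method,
                "statistic": obj.statistic,
                "p_value": obj.p_value,
                "df": obj.df,
                "notes": obj.notes,
            }
        if isinstance(obj, Mapping):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return None  # raw vectors stay out of the summary
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(
                {
                    k: v
                    for k, v in dataclasses.asdict(obj).items()
                    if not isinstance(v, np.ndarray)
                }
            )
        return obj

    return {
        "name": result.name,
        "tests": _clean(result.tests),
        "descriptives": _clean(result.descriptives),
        "correlations": _clean(result.correlations),
        "counts": _clean(result.counts),
        "metadata": _clean(result.metadata),
        "notes": list(result.notes),
    }


def study_report(result: StudyResult) -> str:
    """Human-readable plain-text rendering of a StudyResult."""
    lines = [f"== {result.name} =="]
    if result.metadata:
        lines.append("metadata: " + json.dumps(result_summary(result)["metadata"]))
    for key in sorted(result.counts, key=str):
        lines.append(f"counts[{key}]: {json.dumps(result_summary(result)['counts'][str(key)])}")
    for scope, tests in result.tests.items():
        if isinstance(tests, TestResult):
            lines.append(f"[{scope}] {_fmt_test(tests)}")
            continue
        for prop, entry in tests.items():
            if isinstance(entry, TestResult):
                lines.append(f"[{scope}] {prop}: {_fmt_test(entry)}")
            elif isinstance(entry, Mapping):
                parts = []
                for k, v in entry.items():
                    if isinstance(v, TestResult):
                        parts.append(_fmt_test(v))
                    elif isinstance(v, list):
                        parts.extend(_fmt_test(t) for t in v if isinstance(t, TestResult))
                    else:
                        parts.append(f"{k}={v}")
                lines.append(f"[{scope}] {prop}: " + "; ".join(parts))
    for prop, rho in result.correlations.items():
        shown = "n/a" if rho is None else f"{rho:+.3f}"
        lines.append(f"spearman[{prop} vs window size]: {shown}")
    for prop, vals in result.descriptives.items():
        lines.append(f"descriptive[{prop}]: {vals}")
    for note in result.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
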