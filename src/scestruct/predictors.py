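"""Internally computed per-residue structural tracks.

Two predictors are implemented here:

* a Wootton-Federhen window-entropy low-complexity mask (the role SEG plays
  on real data): the Shannon entropy K2 (bits) of the residue counts in a
  sliding window seeds low-complexity contigs below a trigger threshold and
  extends them through windows below a looser extension threshold;
* a windowed composition/propensity disorder score (the role IUPred's
  pairwise-energy estimate plays): a per-residue energy-like value is
  smoothed by a moving average and mapped to [0, 1] by a logistic
  calibration; residues scoring >= 0.5 are treated as disordered downstream.

The genuine IUPred energy matrix is not public, so the default model is the
published TOP-IDP propensity scale shipped with the package; a 20x20 pairwise
matrix can be loaded instead, and externally produced per-residue score files
can bypass these predictors entirely (see io_formats.read_annotation_tracks).

The canonical SEG refinement stage (minimal-probability subsequence
optimisation) is intentionally not implemented: the analyses consume SEG as a
residue-level boolean mask, which the two-threshold contig logic reproduces.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .types import StructuralAnnotation

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

__all__ = [
    "AMINO_ACIDS",
    "ComplexityParams",
    "DisorderModel",
    "window_entropy",
    "low_complexity_mask",
    "disorder_scores",
    "load_energy_model",
    "default_complexity_params",
    "default_disorder_model",
    "build_annotation",
]


def _load_defaults() -> dict:
    with resources.files("scestruct.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ComplexityParams:
    """Window-entropy low-complexity parameters (K2 thresholds in bits)."""

    window_length: int = 12
    trigger_k: float = 2.2
    extension_k: float = 2.5
    alphabet_size: int = 20

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.trigger_k > self.extension_k:
            raise ValueError("trigger threshold must not exceed extension threshold")


@dataclass
class DisorderModel:
    """Disorder score model: a 20-vector propensity scale or a 20x20 matrix.

    ``calibration`` is the (midpoint, steepness) of the logistic map from the
    smoothed energy-like value to a [0, 1] score; higher = more disordered.
    """

    scale: Optional[np.ndarray] = None  # shape (20,)
    pair_energy_matrix: Optional[np.ndarray] = None  # shape (20, 20), symmetric
    composition_window: int = 100
    smoothing_window: int = 21
    calibration: tuple[float, float] = (0.225, 15.0)
    name: str = "scale"

    def __post_init__(self) -> None:
        if (self.scale is None) == (self.pair_energy_matrix is None):
            raise ValueError("provide exactly one of scale / pair_energy_matrix")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.pair_energy_matrix is not None:
            m = np.asarray(self.pair_energy_matrix, dtype=float)
            if m.shape != (20, 20):
                raise ValueError("pair energy matrix must be 20x20")
            asym = np.max(np.abs(m - m.T))
            if asym > 1e-9:
                logger.warning(
                    "pair energy matrix asymmetric (max |M-M'| = %.3g); symmetrizing",
                    asym,
                )
            self.pair_energy_matrix = (m + m.T) / 2.0


def window_entropy(residue_counts) -> float:
    """Shannon entropy K2 (bits) of a window's residue counts.

    K2 = -sum_i (n_i/L) log2 (n_i/L) over the non-zero counts, where L is the
    window length (the sum of the counts).
    """
    counts = np.asarray(residue_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative residue count")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty window")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _window_entropies(seq: str, L: int) -> np.ndarray:
    """K2 of every length-L window of ``seq`` (sliding counts)."""
    n = len(seq)
    # every distinct letter gets its own class; unknown letters are rare and
    # counting them separately only raises the entropy estimate
    letters = sorted(set(seq))
    idx = {c: i for i, c in enumerate(letters)}
    codes = np.fromiter((idx[c] for c in seq), dtype=np.int64, count=n)
    k = len(letters)
    n_windows = n - L + 1
    out = np.empty(n_windows)
    counts = np.zeros(k, dtype=np.int64)
    for i in range(L):
        counts[codes[i]] += 1
    out[0] = window_entropy(counts)
    for w in range(1, n_windows):
        counts[codes[w - 1]] -= 1
        counts[codes[w + L - 1]] += 1
        out[w] = window_entropy(counts)
    return out


def low_complexity_mask(sequence: str, params: ComplexityParams | None = None) -> np.ndarray:
    """Boolean low-complexity mask over ``sequence``.

    Windows with K2 <= trigger seed contigs; maximal runs of windows with
    K2 <= extension that contain at least one trigger window become
    low-complexity contigs, and the mask covers every residue those windows
    span.  Sequences shorter than the window are scored as a single window of
    their own length.
    """
    if params is None:
        params = default_complexity_params()
    n = len(sequence)
    if n == 0:
        return np.zeros(0, dtype=bool)
    L = min(params.window_length, n)
    k2 = _window_entropies(sequence, L)
    trigger = k2 <= params.trigger_k
    extend = k2 <= params.extension_k
    mask = np.zeros(n, dtype=bool)
    i = 0
    n_windows = len(k2)
    while i < n_windows:
        if not extend[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_windows and extend[j + 1]:
            j += 1
        if trigger[i : j + 1].any():
            mask[i : j + L] = True
        i = j + 1
    return mask


def _smooth_nan(values: np.ndarray, window: int, fill: float) -> np.ndarray:
    """Centered moving average ignoring NaNs, truncated at the termini."""
    n = values.size
    h = window // 2
    out = np.empty(n)
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        cnt = ccnt[hi] - ccnt[lo]
        out[i] = (csum[hi] - csum[lo]) / cnt if cnt else fill
    return out


def disorder_scores(sequence: str, model: DisorderModel | None = None) -> np.ndarray:
    """Per-residue disorder scores in [0, 1]; higher = more disordered.

    Scale mode: the raw energy-like value of residue i is its scale
    propensity.  Matrix mode: it is sum_j M[aa_i, j] * c_i[j] with c_i the
    composition of the ``composition_window`` residues centred at i
    (truncated at the termini).  The raw profile is averaged over
    ``smoothing_window`` residues and passed through the logistic
    calibration.  Ambiguous residues (X, U, B, ...) contribute nothing to
    compositions and inherit the local window-mean value.
    """
    if model is None:
        model = default_disorder_model()
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    codes = np.fromiter(
        (_AA_INDEX.get(c, -1) for c in sequence), dtype=np.int64, count=n
    )
    known = codes >= 0
    e = np.full(n, np.nan)
    if model.scale is not None:
        e[known] = model.scale[codes[known]]
    else:
        M = model.pair_energy_matrix
        cw = model.composition_window
        h = cw // 2
        onehot = np.zeros((n, 20))
        onehot[np.arange(n)[known], codes[known]] = 1.0
        csum = np.vstack([np.zeros(20), np.cumsum(onehot, axis=0)])
        for i in np.flatnonzero(known):
            lo = max(0, i - h)
            hi = min(n, i + h + 1)
            comp = csum[hi] - csum[lo]
            tot = comp.sum()
            if tot > 0:
                e[i] = float(M[codes[i]] @ (comp / tot))
    midpoint, steepness = model.calibration
    smoothed = _smooth_nan(e, model.smoothing_window, fill=midpoint)
    scores = 1.0 / (1.0 + np.exp(-steepness * (smoothed - midpoint)))
    return np.clip(scores, 0.0, 1.0)


def load_energy_model(path, **kwargs) -> DisorderModel:
    """Load a disorder model from a TSV file.

    Accepted layouts: a 20-row, 2-column ``<aa>\\t<value>`` propensity scale,
    or a 20x20 matrix with single-letter row and column headers.  All 20
    standard amino acids must be present.  An asymmetric matrix is
    symmetrized by averaging with its transpose (with a warning).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty model file")
    if len(rows[0]) >= 20 and all(f.strip() in _AA_INDEX for f in rows[0] if f.strip()):
        # matrix with header row of amino-acid letters
        header = [f.strip() for f in rows[0] if f.strip()]
        if sorted(header) != sorted(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(header)
            raise ValueError(f"{path}: missing amino acid(s) {sorted(missing)}")
        m = np.zeros((20, 20))
        seen = set()
        for row in rows[1:]:
            aa = row[0].strip()
            if aa not in _AA_INDEX:
                raise ValueError(f"{path}: unknown row label {aa!r}")
            seen.add(aa)
            vals = [float(v) for v in row[1:] if v.strip() != ""]
            if len(vals) != 20:
                raise ValueError(f"{path}: row {aa} has {len(vals)} values, need 20")
            for col_aa, v in zip(header, vals):
                m[_AA_INDEX[aa], _AA_INDEX[col_aa]] = v
        if seen != set(AMINO_ACIDS):
            raise ValueError(
                f"{path}: missing amino acid(s) {sorted(set(AMINO_ACIDS) - seen)}"
            )
        return DisorderModel(pair_energy_matrix=m, name=str(path), **kwargs)
    # two-column scale
    scale = np.full(20, np.nan)
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: malformed scale row {row!r}")
        aa = row[0].strip()
        if aa not in _AA_INDEX:
            raise ValueError(f"{path}: unknown amino acid {aa!r}")
        scale[_AA_INDEX[aa]] = float(row[1])
    if np.any(np.isnan(scale)):
        missing = [aa for aa in AMINO_ACIDS if np.isnan(scale[_AA_INDEX[aa]])]
        raise ValueError(f"{path}: missing amino acid(s) {missing}")
    return DisorderModel(scale=scale, name=str(path), **kwargs)


def default_complexity_params() -> ComplexityParams:
    cfg = _load_defaults()["complexity"]
    return ComplexityParams(
        window_length=cfg["window_length"],
        trigger_k=cfg["trigger_k"],
        extension_k=cfg["extension_k"],
        alphabet_size=cfg["alphabet_size"],
    )


def default_disorder_model() -> DisorderModel:
    cfg = _load_defaults()["disorder"]
    path = resources.files("scestruct.data").joinpath(cfg["scale_file"])
    with resources.as_file(path) as p:
        model = load_energy_model(
            p,
            composition_window=cfg["composition_window"],
            smoothing_window=cfg["smoothing_window"],
            calibration=(
                cfg["calibration_midpoint"],
                cfg["calibration_steepness"],
            ),
        )
    model.name = "top-idp"
    return model


def build_annotation(
    protein_id: str,
    sequence: str,
    disorder: Optional[np.ndarray] = None,
    ss_states: Optional[np.ndarray] = None,
    domain_mask: Optional[np.ndarray] = None,
    complexity_params: ComplexityParams | None = None,
    disorder_model: DisorderModel | None = None,
) -> StructuralAnnotation:
    """Assemble the four per-residue tracks of one protein.

    Externally supplied tracks (parsed predictor outputs or synthetic ground
    truth) take precedence; the low-complexity mask is always computed
    internally from the sequence, and the disorder track falls back to the
    internal propensity model when no external scores are given.
    """
    n = len(sequence)
    if disorder is None:
        disorder = disorder_scores(sequence, disorder_model)
    if ss_states is None:
        ss_states = np.full(n, "C", dtype="<U1")
    if domain_mask is None:
        domain_mask = np.zeros(n, dtype=bool)
    lc = low_complexity_mask(sequence, complexity_params)
    return StructuralAnnotation(
        protein_id=protein_id,
        disorder_scores=np.asarray(disorder, dtype=float),
        low_complexity_mask=lc,
        ss_states=np.asarray(ss_states, dtype="<U1"),
        domain_mask=np.asarray(domain_mask, dtype=bool),
    )
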