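"""Position-specific scoring matrices: log-odds scanning and FPR thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PSSMMotif",
    "pssm_from_probabilities",
    "pssm_scan",
    "calibrate_threshold",
    "read_pwm_tsv",
    "read_meme_minimal",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_BASE_INDEX["U"] = _BASE_INDEX["T"]


@dataclass
class PSSMMotif:
    """A log-odds scoring matrix with background and optional FPR threshold.

    ``matrix`` has shape (4, L) with rows A, C, G, T (U folds into T).
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x L")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def pssm_from_probabilities(
    name: str,
    probs: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> PSSMMotif:
    """Log2-odds matrix from a (4, L) position probability matrix."""
    probs = np.asarray(probs, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    p = probs + pseudocount
    p = p / p.sum(axis=0, keepdims=True)
    return PSSMMotif(name=name, matrix=np.log2(p / bg[:, None]), background=bg)


def pssm_scan(seq: str, motif: PSSMMotif) -> np.ndarray:
    """Log-odds score at every offset of ``seq``.

    Ambiguous bases (anything outside ACGTU) contribute 0 at their position.
    """
    L = motif.length
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=int)
    n = len(seq) - L + 1
    scores = np.zeros(n)
    for pos in range(L):
        col = motif.matrix[:, pos]
        window = idx[pos : pos + n]
        ok = window >= 0
        scores[ok] += col[window[ok]]
    return scores


def calibrate_threshold(
    motif: PSSMMotif, fpr: float = 0.01, scale: int = 10_000
) -> float:
    """Smallest score whose background tail probability is below ``fpr``.

    Computed by dynamic programming over integer-discretized per-position
    scores; the returned threshold includes the worst-case rounding slack so
    that ``P(score >= threshold | background) < fpr`` holds for the exact
    real-valued score distribution as well.
    """
    if not 0 < fpr <= 1:
        raise ValueError("fpr must be in (0, 1]")
    if fpr >= 1.0:
        return float(motif.matrix.min(axis=0).sum())  # every word qualifies
    q = np.rint(motif.matrix * scale).astype(np.int64)  # (4, L)
    L = motif.length
    offsets = q.min(axis=0)
    q_shift = q - offsets  # non-negative per column
    max_total = int(q_shift.max(axis=0).sum())

    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    for pos in range(L):
        nxt = np.zeros_like(dist)
        for b in range(4):
            step = int(q_shift[b, pos])
            if step == 0:
                nxt += motif.background[b] * dist
            else:
                nxt[step:] += motif.background[b] * dist[:-step]
        dist = nxt

    min_int = int(offsets.sum())
    tail = np.cumsum(dist[::-1])[::-1]  # tail[v] = P(shifted score >= v)
    below = np.flatnonzero(tail < fpr)
    v = int(below[0]) if len(below) else max_total + 1
    # rounding slack: each position's real score differs from q/scale by <= 0.5/scale
    return (v + min_int) / scale + L * 0.5 / scale


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pwm_tsv(
    path: str | Path,
    name: str | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> PSSMMotif:
    """Read a tab-delimited PWM: columns A, C, G, T(/U); one row per position.

    Values may be probabilities or counts; rows are renormalized.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.upper().replace("U", "T") for c in df.columns]
    try:
        order = [cols.index(b) for b in ALPHABET]
    except ValueError as exc:
        raise ValueError(f"{path}: need A/C/G/T(U) columns") from exc
    probs = df.to_numpy(dtype=float)[:, order].T  # (4, L)
    probs = probs / probs.sum(axis=0, keepdims=True)
    return pssm_from_probabilities(
        name or path.stem, probs, background=background, pseudocount=pseudocount
    )


def read_meme_minimal(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> list[PSSMMotif]:
    """Read motifs from a MEME minimal-format file."""
    motifs: list[PSSMMotif] = []
    name, rows = None, []
    bg = background

    def flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            motifs.append(
                pssm_from_probabilities(
                    name, np.array(rows).T, background=bg, pseudocount=pseudocount
                )
            )
        name, rows = None, []

    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            stripped = line.strip()
            if stripped.startswith("Background letter frequencies") and background is None:
                freq_line = next(lines).split()
                vals = {freq_line[i]: float(freq_line[i + 1]) for i in range(0, len(freq_line), 2)}
                bg = np.array([vals.get(b, vals.get("U", 0.25)) for b in ALPHABET])
            elif stripped.startswith("MOTIF"):
                flush()
                name = stripped.split()[1]
            elif name is not None:
                parts = stripped.split()
                if len(parts) == 4 and all(_is_float(p) for p in parts):
                    rows.append([float(p) for p in parts])
                elif rows and stripped == "":
                    flush()
    flush()
    return motifs


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
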