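"""PSSM scan for pyrimidine-tract RNA-binding motifs with local z-scores.

PTBP1 represses microexon inclusion by binding CU-rich (polypyrimidine)
tracts upstream of 3' splice sites; its consensus element is modelled here as
CUUUCU.  The scanner is a plain position-specific scoring matrix: every
window of the sequence gets a log-odds score, which is standardized against
the distribution of window scores in a local background window around it.
Hits with z > 3 are called, and a sliding pyrimidine-content track annotates
whether hits fall inside polypyrimidine tracts.

This is a deliberately simple scorer: no weighted-rank statistics or
conservation filtering, just PSSM log-odds plus a local z-score threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pssm",
    "MotifHit",
    "build_pssm",
    "scan",
    "filter_hits",
    "polypyrimidine_content",
    "hits_table",
]

RNA_ALPHABET = "ACGU"
_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
# IUPAC codes expanded over the RNA alphabet (Y = pyrimidine is what the
# PTBP1 consensus needs; the rest cost nothing to support)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "Y": "CU", "R": "AG", "W": "AU", "S": "CG", "K": "GU", "M": "AC",
    "N": "ACGU",
}
LOG_ODDS_FLOOR = -10.0  # per-position guard against -inf at zero frequency
DEFAULT_Z_MIN = 3.0


@dataclasses.dataclass(frozen=True)
class Pssm:
    """Log-odds matrix over ACGU, shape (width, 4)."""

    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[0])

    def score(self, window: str) -> float:
        """Log-odds score of one width-length window (direct summation)."""
        w = _normalize(window)
        if len(w) != self.width:
            raise ValueError("window length must equal PSSM width")
        return float(sum(self.log_odds[i, _INDEX[b]] for i, b in enumerate(w)))


@dataclasses.dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based offset in the scanned sequence
    raw_score: float
    z_score: float  # NaN when the local background has zero score variance
    passes: bool


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def build_pssm(
    sites: Sequence[str] | None = None,
    consensus: str | None = None,
    pseudocount: float = 0.01,
    background: Mapping[str, float] | None = None,
) -> Pssm:
    """Build a PSSM from aligned sites or from an IUPAC consensus.

    Position frequencies get a pseudocount (``f = (f0 + pc) / (1 + 4 pc)``)
    and are converted to log2-odds against the background (uniform by
    default); log-odds are floored at -10 so zero frequencies at zero
    pseudocount stay finite.  A consensus expands IUPAC codes uniformly
    (Y -> C/U at 0.5 each).
    """
    if (sites is None) == (consensus is None):
        raise ValueError("provide exactly one of sites or consensus")
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.array([background[b] for b in RNA_ALPHABET], dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    if consensus is not None:
        cons = _normalize(consensus)
        freqs = np.zeros((len(cons), 4))
        for i, letter in enumerate(cons):
            try:
                bases = _IUPAC[letter]
            except KeyError:
                raise ValueError(f"invalid letter {letter!r} in consensus") from None
            for b in bases:
                freqs[i, _INDEX[b]] = 1.0 / len(bases)
    else:
        widths = {len(s) for s in sites}
        if len(widths) != 1:
            raise ValueError("ragged sites: all sites must have equal length")
        width = widths.pop()
        freqs = np.zeros((width, 4))
        for s in sites:
            s = _normalize(s)
            for i, letter in enumerate(s):
                if letter not in _INDEX:
                    raise ValueError(f"invalid letter {letter!r} in site")
                freqs[i, _INDEX[letter]] += 1.0
        freqs /= len(sites)

    if freqs.shape[0] < 4:
        raise ValueError("PSSM width must be >= 4")
    freqs = (freqs + pseudocount) / (1.0 + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / bg)
    log_odds = np.maximum(log_odds, LOG_ODDS_FLOOR)
    return Pssm(log_odds=log_odds, background=bg, pseudocount=float(pseudocount))


def scan(
    sequence: str,
    pssm: Pssm,
    background_window: int = 500,
    z_min: float = DEFAULT_Z_MIN,
) -> list[MotifHit]:
    """Score every window of a sequence and standardize against a local background.

    DNA input is transliterated T -> U.  For each window start the z-score is
    (raw - mean) / sd over the raw scores of all window starts within
    +/- ``background_window``/2, clipped at the sequence ends; sd is the
    population standard deviation.  Windows containing letters outside ACGUN
    raise; N scores as the position's mean log-odds.  Hits are returned for
    every window, sorted by position, with ``passes`` set by strict z >
    ``z_min``.
    """
    seq = _normalize(sequence)
    w = pssm.width
    if len(seq) < w:
        raise ValueError("sequence shorter than motif")
    lo_ext = np.column_stack([pssm.log_odds, pssm.log_odds.mean(axis=1)])  # col 4 = N
    idx = np.empty(len(seq), dtype=np.int64)
    for i, letter in enumerate(seq):
        if letter in _INDEX:
            idx[i] = _INDEX[letter]
        elif letter == "N":
            idx[i] = 4
        else:
            raise ValueError(f"invalid letter {letter!r} in sequence")
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    raw = lo_ext[np.arange(w)[None, :], windows].sum(axis=1)

    half = background_window // 2
    s = pd.Series(raw)
    roll = s.rolling(window=2 * half + 1, center=True, min_periods=2)
    mean = roll.mean().to_numpy()
    sd = roll.std(ddof=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mean) / sd
    z = np.where(sd > 0, z, np.nan)
    return [
        MotifHit(start=i, raw_score=float(raw[i]), z_score=float(z[i]),
                 passes=bool(np.isfinite(z[i]) and z[i] > z_min))
        for i in range(raw.size)
    ]


def filter_hits(hits: Iterable[MotifHit], z_min: float = DEFAULT_Z_MIN) -> list[MotifHit]:
    """Hits with finite z strictly greater than ``z_min``."""
    return [h for h in hits if np.isfinite(h.z_score) and h.z_score > z_min]


def polypyrimidine_content(sequence: str, window: int = 25) -> np.ndarray:
    """Per-position C/U fraction in a centered sliding window (clipped at ends)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = _normalize(sequence)
    ind = np.array([1.0 if b in "CU" else 0.0 for b in seq])
    return pd.Series(ind).rolling(window=window, center=True, min_periods=1).mean().to_numpy()


def hits_table(
    hits: Sequence[MotifHit],
    sequence: str,
    pssm: Pssm,
    tract_window: int = 25,
    tract_min_fraction: float = 0.7,
) -> pd.DataFrame:
    """Tabulate hits with motif sequence, pyrimidine context and tract membership."""
    seq = _normalize(sequence)
    pyr = polypyrimidine_content(seq, tract_window)
    rows = []
    for h in hits:
        center = h.start + pssm.width // 2
        rows.append(
            {
                "start": h.start,
                "end": h.start + pssm.width,
                "motif": seq[h.start : h.start + pssm.width],
                "raw_score": h.raw_score,
                "z": h.z_score,
                "passes": h.passes,
                "pyrimidine_fraction": float(pyr[min(center, len(seq) - 1)]),
            }
        )
    df = pd.DataFrame(rows, columns=["start", "end", "motif", "raw_score", "z", "passes", "pyrimidine_fraction"])
    if len(df):
        df["in_tract"] = df["pyrimidine_fraction"] >= tract_min_fraction
    else:
        df["in_tract"] = pd.Series(dtype=bool)
    return df
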