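"""Capillary-electrophoresis fragment-analysis quantification.

Fluorescent PCR across the microexon region yields one amplicon per splice
combination; capillary electrophoresis separates them by size (down to 3 nt
apart) and the area under each peak measures that isoform's abundance.  This
module simulates calibrated electropherogram traces, detects and fits peaks,
assigns peaks to expected amplicon sizes and converts peak areas into isoform
proportions.

Traces are assumed already size-calibrated (the size axis is in nt); a simple
ladder-based linear calibrator is provided for raw scan axes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .gene_model import IsoformCombination, MicroexonGeneModel, enumerate_isoforms
from .sj import IsoformCounts

__all__ = [
    "Trace",
    "Peak",
    "simulate_trace",
    "call_peaks",
    "assign_peaks",
    "peak_proportions",
    "calibrate_axis",
    "trace_from_tsv",
    "plot_electropherogram",
]

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclasses.dataclass
class Trace:
    """A calibrated electropherogram: fragment size (nt) vs fluorescence."""

    size_axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = "trace"

    def __post_init__(self) -> None:
        self.size_axis = np.asarray(self.size_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size_axis.shape != self.intensity.shape or self.size_axis.ndim != 1:
            raise ValueError("size_axis and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.size_axis) <= 0):
            raise ValueError("size_axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclasses.dataclass
class Peak:
    apex_size: float
    area: float
    width_sigma: float
    height: float
    assigned_label: str | None = None
    area_fraction: float | None = None


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def amplicon_sizes(model: MicroexonGeneModel, base_amplicon: float) -> dict[str, float]:
    """Expected amplicon size per combination label for a given base amplicon."""
    return {c.label: base_amplicon + c.transcript_length_delta for c in enumerate_isoforms(model)}


def simulate_trace(
    proportions: Mapping[str, float],
    model: MicroexonGeneModel,
    base_amplicon: float,
    sigma: float = 0.35,
    snr: float | None = 50.0,
    seed: int = 0,
    step: float = 0.05,
    padding: float = 15.0,
    total_area: float = 1000.0,
    sample_id: str = "simulated",
) -> Trace:
    """Simulate an electropherogram as a sum of Gaussian peaks plus baseline noise.

    Peak centers are the amplicon sizes of the labelled combinations, areas are
    proportional to ``proportions`` and white Gaussian noise with standard
    deviation ``max_signal / snr`` is added (``snr=None`` for a noiseless
    trace).  Deterministic for a fixed seed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    total_p = sum(proportions.values())
    if not math.isclose(total_p, 1.0, abs_tol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {total_p}")
    sizes = amplicon_sizes(model, base_amplicon)
    centers = {}
    for label, p in proportions.items():
        if label not in sizes:
            raise ValueError(f"no amplicon size for label {label!r}")
        centers[label] = sizes[label]
    lo = min(centers.values()) - padding
    hi = max(centers.values()) + padding
    axis = np.arange(lo, hi + step / 2, step)
    signal = np.zeros_like(axis)
    for label, p in proportions.items():
        amp = p * total_area / (sigma * math.sqrt(2 * math.pi))
        signal += _gauss(axis, amp, centers[label], sigma)
    if snr is not None:
        rng = np.random.default_rng(seed)
        noise_sd = signal.max() / snr if signal.max() > 0 else 0.0
        signal = signal + rng.normal(0.0, noise_sd, size=axis.size)
    return Trace(size_axis=axis, intensity=np.clip(signal, 0.0, None), sample_id=sample_id)


def _fit_peak(x: np.ndarray, y: np.ndarray, idx: int, baseline: float, step: float) -> Peak:
    """Refine one local maximum by a Gaussian fit (trapezoid fallback)."""
    amp0 = y[idx] - baseline
    mu0 = x[idx]
    # crude sigma from the half-maximum crossings
    half = baseline + amp0 / 2.0
    left = idx
    while left > 0 and y[left] > half:
        left -= 1
    right = idx
    while right < y.size - 1 and y[right] > half:
        right += 1
    hwhm = max((x[right] - x[left]) / 2.0, step)
    sigma0 = hwhm / math.sqrt(2 * math.log(2))
    mask = np.abs(x - mu0) <= max(3 * sigma0, 5 * step)
    try:
        popt, _ = curve_fit(
            lambda xx, a, m, s: _gauss(xx, a, m, s) + baseline,
            x[mask],
            y[mask],
            p0=(amp0, mu0, sigma0),
            bounds=([0.0, mu0 - 3 * sigma0, step / 10], [np.inf, mu0 + 3 * sigma0, 50 * sigma0]),
            maxfev=2000,
        )
        amp, mu, sig = popt
        area = amp * sig * math.sqrt(2 * math.pi)
        return Peak(apex_size=float(mu), area=float(area), width_sigma=float(sig), height=float(amp))
    except RuntimeError:
        area = float(np.trapezoid(np.clip(y[mask] - baseline, 0, None), x[mask]))
        return Peak(apex_size=float(mu0), area=area, width_sigma=float(sigma0), height=float(amp0))


def call_peaks(
    trace: Trace,
    min_snr: float = 5.0,
    min_separation: float = 1.0,
    smoothing: float = 0.15,
) -> list[Peak]:
    """Detect and fit peaks in a trace.

    Detection runs on a lightly Gaussian-smoothed copy of the trace (a
    matched-filter step: kernel sd ``smoothing`` nt, narrow relative to the
    instrument peak width so 3-nt-separated peaks stay resolved).  Per-sample
    noise is estimated from the median absolute first difference of the raw
    trace, which is insensitive both to peaks and to the zero-clipping of the
    lower noise tail; candidates must rise ``min_snr`` x (smoothed noise)
    above the baseline.  Each candidate is then refined by a Gaussian fit on
    the raw trace.  Peaks closer than ``min_separation`` are merged into the
    taller one (areas summed).  A flat trace yields no peaks.
    """
    from scipy.ndimage import gaussian_filter1d

    x, y = trace.size_axis, trace.intensity
    step = float(np.median(np.diff(x)))
    k = max(smoothing / step, 1.0)  # kernel sd in samples
    ys = gaussian_filter1d(y, k)
    baseline = float(np.median(ys))
    # white-noise sd of the raw trace from successive differences
    noise_raw = float(np.median(np.abs(np.diff(y)))) / (0.6745 * math.sqrt(2))
    # Gaussian smoothing with kernel sd k shrinks white-noise sd by (2 sqrt(pi) k)^-1/2
    noise = noise_raw / math.sqrt(2 * math.sqrt(math.pi) * k)
    kwargs: dict = {"distance": max(1, int(round(min_separation / step)))}
    if noise > 0:
        kwargs["height"] = baseline + min_snr * noise
        kwargs["prominence"] = min_snr * noise
    else:
        span = ys.max() - ys.min()
        kwargs["prominence"] = max(1e-12, 1e-6 * span)
    idxs, _ = find_peaks(ys, **kwargs)
    peaks = [_fit_peak(x, y, i, float(np.median(y)), step) for i in idxs]
    peaks.sort(key=lambda p: p.apex_size)
    # merge any residual close pairs into the taller peak
    merged: list[Peak] = []
    for pk in peaks:
        if merged and pk.apex_size - merged[-1].apex_size < min_separation:
            keep, drop = (merged[-1], pk) if merged[-1].height >= pk.height else (pk, merged[-1])
            keep = dataclasses.replace(keep, area=keep.area + drop.area)
            merged[-1] = keep
        else:
            merged.append(pk)
    return merged


def _absent_microexons(model: MicroexonGeneModel, evidence: IsoformCounts) -> set[str]:
    """Microexons whose own donor-anchored junction has zero read support."""
    absent = set()
    for m in model.microexons:
        label = f"{model.donor_exon_id}:{m.length}bp"
        if evidence.counts.get(label, 0) == 0:
            absent.add(m.exon_id)
    return absent


def assign_peaks(
    peaks: Sequence[Peak],
    model: MicroexonGeneModel,
    base_amplicon: float,
    tolerance: float = 1.0,
    junction_evidence: IsoformCounts | None = None,
) -> list[Peak]:
    """Match each peak to the nearest expected amplicon size.

    Candidates are all enumerated splice combinations whose expected size lies
    within ``tolerance`` of the peak apex.  When several candidates tie, the
    tie is broken with junction evidence if provided — combinations containing
    microexons whose own junction shows zero reads are removed — otherwise the
    peak is labelled ``"ambiguous"``.  Peaks with no candidate in tolerance are
    ``"unassigned"``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    combos = enumerate_isoforms(model)
    expected = [(c.label, base_amplicon + c.transcript_length_delta, c) for c in combos]
    out = []
    for pk in peaks:
        cands = [(label, size, c) for label, size, c in expected if abs(size - pk.apex_size) <= tolerance]
        if junction_evidence is not None and len(cands) > 1:
            absent = _absent_microexons(model, junction_evidence)
            cands = [t for t in cands if not (set(t[2].included) & absent)]
        if not cands:
            label = UNASSIGNED
        elif len(cands) == 1:
            label = cands[0][0]
        else:
            cands.sort(key=lambda t: (abs(t[1] - pk.apex_size), t[0]))
            # a genuine tie only when more than one candidate remains in tolerance
            label = AMBIGUOUS
        out.append(dataclasses.replace(pk, assigned_label=label))
    return out


def peak_proportions(peaks: Sequence[Peak]) -> tuple[dict[str, float], list[Peak]]:
    """Per-label area fractions over assigned peaks.

    Ambiguous and unassigned peaks are excluded from the denominator and
    returned separately.  Raises if no peak is assigned.
    """
    assigned = [p for p in peaks if p.assigned_label not in (None, AMBIGUOUS, UNASSIGNED)]
    excluded = [p for p in peaks if p.assigned_label in (None, AMBIGUOUS, UNASSIGNED)]
    if not assigned:
        raise ValueError("zero assigned peaks")
    total = sum(p.area for p in assigned)
    fractions: dict[str, float] = {}
    for p in assigned:
        p.area_fraction = p.area / total
        fractions[p.assigned_label] = fractions.get(p.assigned_label, 0.0) + p.area / total
    return fractions, excluded


def calibrate_axis(
    raw_axis: Sequence[float],
    ladder_raw: Sequence[float],
    ladder_sizes: Sequence[float],
) -> np.ndarray:
    """Linear-interpolation size calibration from ladder peak positions.

    Maps a raw scan axis to nt using the known ladder fragment sizes;
    extrapolates linearly beyond the outermost ladder peaks.
    """
    from scipy.interpolate import interp1d

    f = interp1d(ladder_raw, ladder_sizes, kind="linear", fill_value="extrapolate")
    return np.asarray(f(np.asarray(raw_axis, dtype=float)))


def trace_from_tsv(path, sample_id: str | None = None) -> Trace:
    """Read a two-column (size, intensity) TSV trace."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("trace TSV needs two columns: size, intensity")
    return Trace(
        size_axis=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        sample_id=sample_id or str(path),
    )


def plot_electropherogram(trace: Trace, peaks: Iterable[Peak] | None = None, path=None):
    """Plot a trace with optional peak annotations; writes PNG when ``path`` given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.size_axis, trace.intensity, lw=0.8, color="0.2")
    if peaks:
        for pk in peaks:
            ax.axvline(pk.apex_size, color="crimson", lw=0.6, ls="--")
            label = pk.assigned_label or f"{pk.apex_size:.1f} nt"
            ax.annotate(label, (pk.apex_size, pk.height), fontsize=7, rotation=90,
                        ha="right", va="bottom")
    ax.set_xlabel("fragment size (nt)")
    ax.set_ylabel("fluorescence (a.u.)")
    ax.set_title(trace.sample_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
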