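"""Glottal dynamic indices from the glottal area waveform.

Cycle detection (minima-to-minima, autocorrelation-guided) followed by
the six standard indices over a 30-cycle analysis window:

==== =============================== =========================
GGI  glottal gap index               [0,1], 0 = full closure
CQ   closing quotient (open-time)    [0,1], 1 = completely open
AP   amplitude periodicity           [0,1], 1 = periodic
TP   time periodicity                [0,1], 1 = periodic
PAI  phase asymmetry index           [0,1], 0 = symmetric
ASI  amplitude symmetry index        [0,1], 1 = symmetric
==== =============================== =========================

All indices are ratios of areas or times, so they are invariant to
uniform rescaling of the area units.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .datatypes import GlottalAreaWaveform

logger = logging.getLogger(__name__)

__all__ = [
    "F0UndetectableError",
    "CycleSet",
    "GlottalDynamicMetrics",
    "detect_gaw_cycles",
    "compute_ggi",
    "compute_cq",
    "compute_periodicity",
    "compute_symmetry",
    "analyze_gaw",
    "coarse_f0_autocorr",
]

DEFAULT_F0_BAND_HZ = (40.0, 400.0)
ANALYSIS_WINDOW_CYCLES = 30


class F0UndetectableError(ValueError):
    """Raised when no periodic structure is found in the search band;
    drives the record-exclusion rule upstream."""


def coarse_f0_autocorr(
    x: np.ndarray,
    fs: float,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    min_peak: float = 0.3,
) -> float:
    """Coarse fundamental frequency from the normalized autocorrelation.

    Searches lags within the band and requires the best local maximum to
    reach ``min_peak`` of the zero-lag value, otherwise raises
    :class:`F0UndetectableError`.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if x.size < 4 or not np.any(x):
        raise F0UndetectableError("signal empty or constant")
    lo, hi = f0_band_hz
    lag_min = max(2, int(np.floor(fs / hi)))
    lag_max = int(np.ceil(fs / lo))
    if lag_max >= x.size - 1:
        lag_max = x.size - 2
    if lag_max <= lag_min:
        raise F0UndetectableError("record shorter than two periods at the band's lower edge")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
    ac = ac / ac[0]
    seg = ac[lag_min : lag_max + 1]
    # local maxima only: an F0 below the band must not alias in via a slope
    interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    cand = np.where(interior)[0] + 1
    if cand.size == 0:
        raise F0UndetectableError("no autocorrelation maximum inside the F0 band")
    best = cand[np.argmax(seg[cand])]
    if seg[best] < min_peak:
        raise F0UndetectableError(
            f"autocorrelation peak {seg[best]:.2f} below threshold {min_peak}"
        )
    lag = lag_min + best
    # parabolic refinement of the autocorrelation peak
    if 1 <= lag < ac.size - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return fs / lag


@dataclass
class CycleSet:
    """Cycle boundaries (minima-to-minima) plus per-cycle features.

    ``boundaries`` holds n+1 sample indices for n cycles.  Peak times for
    the left and right hemi-areas are parabolic-refined to sub-sample
    precision, needed at video rate for phase-asymmetry estimates.
    """

    boundaries: np.ndarray
    fs_hz: float
    periods_s: np.ndarray
    amp_total: np.ndarray
    amp_left: Optional[np.ndarray] = None
    amp_right: Optional[np.ndarray] = None
    t_max_left: Optional[np.ndarray] = None
    t_max_right: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.periods_s.size

    @property
    def f0_hz(self) -> float:
        return 1.0 / float(np.mean(self.periods_s))

    @property
    def has_hemi(self) -> bool:
        return self.amp_left is not None and self.amp_right is not None


@dataclass
class GlottalDynamicMetrics:
    ggi: float
    cq: float
    ap: float
    tp: float
    pai: float
    asi: float
    f0_hsi_hz: float
    n_cycles: int


def _refined_peak(x: np.ndarray, fs: float, start: int) -> Tuple[float, float]:
    """Location (s) and height of the maximum of ``x`` with parabolic
    sub-sample refinement; ties break toward the earlier sample."""
    i = int(np.argmax(x))
    t, v = start + float(i), float(x[i])
    if 0 < i < x.size - 1:
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = 0.5 * (y0 - y2) / denom
            if abs(d) <= 1:
                t += d
                v = y1 - 0.25 * (y0 - y2) * d
    return t / fs, v


def detect_gaw_cycles(
    gaw: GlottalAreaWaveform,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    window_cycles: int = ANALYSIS_WINDOW_CYCLES,
    min_peak: float = 0.3,
) -> CycleSet:
    """Detect oscillation cycles on the glottal area waveform.

    Coarse F0 from the autocorrelation peak within ``f0_band_hz``; cycle
    boundaries at the local area minimum nearest each expected boundary;
    the first ``window_cycles`` consecutive cycles form the analysis
    window (all cycles, with a warning, if fewer were found).  Raises
    :class:`F0UndetectableError` for aperiodic records.
    """
    a = np.asarray(gaw.area_total, dtype=float)
    fs = gaw.fs_video_hz
    f0 = coarse_f0_autocorr(a, fs, f0_band_hz, min_peak=min_peak)
    period = fs / f0

    # first boundary: global minimum within the first expected period
    first = int(np.argmin(a[: max(2, int(round(period)))]))
    bounds = [first]
    while True:
        lo = bounds[-1] + int(round(0.5 * period))
        hi = bounds[-1] + int(round(1.5 * period)) + 1
        if hi > a.size:
            break
        nxt = lo + int(np.argmin(a[lo:hi]))
        bounds.append(nxt)
    if len(bounds) < 3:
        raise F0UndetectableError("fewer than two complete cycles in the record")
    bounds = np.asarray(bounds)
    n_avail = bounds.size - 1
    if n_avail < window_cycles:
        warnings.warn(
            f"only {n_avail} cycles available; analysis window shortened "
            f"from {window_cycles}"
        )
    else:
        bounds = bounds[: window_cycles + 1]

    # Sub-sample refinement of cycle-start times by waveform matching:
    # at video rate one sample is several percent of a period, so
    # integer minima would quantize the period sequence and swamp small
    # cycle-to-cycle variation (time periodicity, jitter of F0_HSI).
    t_bounds = bounds.astype(float)
    L = max(4, int(np.min(np.diff(bounds))))
    shift_max = max(1, int(round(0.25 * period)))
    segs = [a[s : s + L] for s in bounds[:-1] if s + L <= a.size]
    if len(segs) >= 2:
        template = np.mean(segs, axis=0)
        for k, s in enumerate(bounds[:-1]):
            lo = max(0, s - shift_max)
            hi = min(a.size, s + L + shift_max)
            if hi - lo < L + 2:
                continue
            score = np.correlate(a[lo:hi], template, mode="valid")
            j = int(np.argmax(score))
            t_new = float(lo + j)
            if 0 < j < score.size - 1:
                y0, y1, y2 = score[j - 1], score[j], score[j + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    d = 0.5 * (y0 - y2) / denom
                    if abs(d) <= 1:
                        t_new += d
            t_bounds[k] = t_new
    # last boundary: extrapolate with the same refinement offset pattern
    if t_bounds.size >= 3:
        t_bounds[-1] = bounds[-1] + float(np.median(t_bounds[:-1] - bounds[:-1]))
    periods = np.diff(t_bounds) / fs
    if np.any(periods <= 0):
        periods = np.diff(bounds) / fs
    n = periods.size
    amp_tot = np.empty(n)
    has_hemi = gaw.has_hemi
    amp_l = np.empty(n) if has_hemi else None
    amp_r = np.empty(n) if has_hemi else None
    t_l = np.empty(n) if has_hemi else None
    t_r = np.empty(n) if has_hemi else None
    for i in range(n):
        s, e = bounds[i], bounds[i + 1] + 1
        seg = a[s:e]
        amp_tot[i] = seg.max() - seg.min()
        if has_hemi:
            sl, sr = gaw.area_left[s:e], gaw.area_right[s:e]
            t_l[i], top_l = _refined_peak(sl, fs, s)
            t_r[i], top_r = _refined_peak(sr, fs, s)
            amp_l[i] = top_l - sl.min()
            amp_r[i] = top_r - sr.min()
    return CycleSet(
        boundaries=bounds, fs_hz=fs, periods_s=periods, amp_total=amp_tot,
        amp_left=amp_l, amp_right=amp_r, t_max_left=t_l, t_max_right=t_r,
    )


def compute_ggi(cycles: CycleSet, gaw: GlottalAreaWaveform) -> float:
    """Glottal gap index: mean over cycles of (min area)/(max area);
    0 = full closure during vibration, 1 = no oscillation."""
    a = gaw.area_total
    ratios = []
    for i in range(cycles.n_cycles):
        seg = a[cycles.boundaries[i] : cycles.boundaries[i + 1] + 1]
        mx = seg.max()
        ratios.append(0.0 if mx == 0 else seg.min() / mx)
    if not np.any(a):
        warnings.warn("all-zero glottal area waveform; GGI = 0")
        return 0.0
    return float(np.mean(ratios))


def compute_cq(
    cycles: CycleSet, gaw: GlottalAreaWaveform, open_threshold_frac: float = 0.02
) -> float:
    """Closing quotient, open-quotient reading: mean fraction of each
    cycle during which the area exceeds ``open_threshold_frac`` of the
    cycle maximum; 1 = completely open."""
    a = gaw.area_total
    fracs = []
    for i in range(cycles.n_cycles):
        seg = a[cycles.boundaries[i] : cycles.boundaries[i + 1]]
        mx = seg.max()
        fracs.append(0.0 if mx <= 0 else float(np.mean(seg > open_threshold_frac * mx)))
    return float(np.mean(fracs))


def _pair_ratio_mean(values: np.ndarray) -> float:
    """Mean over consecutive pairs of min/max; a zero in a pair
    contributes 0 for that pair."""
    v = np.asarray(values, dtype=float)
    a, b = v[:-1], v[1:]
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(hi > 0, lo / hi, 0.0)
    return float(np.mean(r))


def compute_periodicity(cycles: CycleSet) -> Tuple[float, float]:
    """(AP, TP): cycle-to-cycle similarity of peak-to-peak amplitudes and
    of periods, as mean consecutive-pair min/max ratios; 1 = periodic."""
    if cycles.n_cycles < 2:
        raise ValueError("periodicity needs at least 2 cycles")
    ap = _pair_ratio_mean(cycles.amp_total)
    tp = _pair_ratio_mean(cycles.periods_s)
    return ap, tp


def compute_symmetry(cycles: CycleSet) -> Tuple[float, float]:
    """(ASI, PAI) from the hemi-area cycle features.

    ASI: mean per-cycle min/max ratio of left/right amplitudes
    (1 = symmetric).  PAI: mean |right peak time - left peak time|
    wrapped into half a period and normalized by T/2 (0 = symmetric).
    With one hemi-signal identically zero, ASI is 0 and PAI undefined
    (returned as NaN).
    """
    if not cycles.has_hemi:
        raise ValueError("hemi-area signals are required for symmetry indices")
    al, ar = cycles.amp_left, cycles.amp_right
    if np.all(al == 0) or np.all(ar == 0):
        return 0.0, float("nan")
    hi = np.maximum(al, ar)
    lo = np.minimum(al, ar)
    with np.errstate(invalid="ignore", divide="ignore"):
        asi = float(np.mean(np.where(hi > 0, lo / hi, 0.0)))
    dt = cycles.t_max_right - cycles.t_max_left
    half = cycles.periods_s / 2.0
    wrapped = np.mod(dt + half, cycles.periods_s) - half  # into [-T/2, T/2)
    pai = float(np.mean(np.abs(wrapped) / half))
    return asi, pai


def analyze_gaw(
    gaw: GlottalAreaWaveform,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    window_cycles: int = ANALYSIS_WINDOW_CYCLES,
) -> GlottalDynamicMetrics:
    """Full glottal-dynamics evaluation of one area waveform."""
    cycles = detect_gaw_cycles(gaw, f0_band_hz, window_cycles)
    ap, tp = compute_periodicity(cycles)
    if cycles.has_hemi:
        asi, pai = compute_symmetry(cycles)
    else:
        asi = pai = float("nan")
    return GlottalDynamicMetrics(
        ggi=compute_ggi(cycles, gaw),
        cq=compute_cq(cycles, gaw),
        ap=ap, tp=tp, pai=pai, asi=asi,
        f0_hsi_hz=cycles.f0_hz,
        n_cycles=cycles.n_cycles,
    )
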