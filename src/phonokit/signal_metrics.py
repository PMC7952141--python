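"""Signal-quality metrics for acoustic and subglottal pressure signals.

Both channels run through the identical chain: zero-phase Butterworth
band-pass (20 Hz - 20 kHz), autocorrelation-guided cycle detection with
parabolic peak refinement, then perturbation (jitter, shimmer), noise
(HNR, NNE via a cycle-ensemble decomposition), and harmonic-structure
(CPP) measures.  SPL and the glottal flow resistance R_B = mean(P_sub)/
mean(Q) complete the aerodynamic picture.

Jitter and shimmer use the *local* variant: the mean absolute
consecutive difference of periods (amplitudes) over their mean, in
percent.  For HNR/NNE the signal is decomposed into a harmonic estimate
H (energy of the ensemble-mean cycle) and a noise estimate N (mean
residual energy); cycles are extracted at integer sample marks and
truncated to the common minimum length, which preserves broadband noise
energy exactly (interpolation onto a fixed grid would not).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .datatypes import SignalRecording
from .gaw_metrics import F0UndetectableError, coarse_f0_autocorr

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodSequence",
    "SignalQualityMetrics",
    "AeroMetrics",
    "bandpass",
    "detect_cycles",
    "jitter_pct",
    "shimmer_pct",
    "hnr_db",
    "nne_db",
    "cpp_db",
    "spl_db",
    "rb",
    "analyze_signal",
]

P_REF_PA = 20e-6
HNR_CAP_DB = 60.0
NNE_FLOOR_DB = -60.0
DEFAULT_F0_BAND_HZ = (40.0, 400.0)


@dataclass
class PeriodSequence:
    """Cycle marks and per-cycle features of a pressure signal.

    ``marks_s`` are the refined times of the dominant positive peak of
    each cycle; ``marks_idx`` the integer sample indices used for
    ensemble extraction.  Periods are successive mark differences.
    """

    marks_s: np.ndarray
    marks_idx: np.ndarray
    fs_hz: float
    periods_s: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.periods_s <= 0):
            raise ValueError("periods must be positive")

    @property
    def n_cycles(self) -> int:
        return self.periods_s.size

    @property
    def f0_hz(self) -> float:
        return 1.0 / float(np.mean(self.periods_s))


@dataclass
class SignalQualityMetrics:
    f0_hz: float
    jitt_pct: float
    shim_pct: float
    hnr_db: float
    nne_db: float
    cpp_db: float
    n_cycles: int
    spl_db: float = math.nan       # acoustic channel
    psub_mean_pa: float = math.nan  # subglottal channel


@dataclass
class AeroMetrics:
    rb_pa_per_slm: float
    q_mean_slm: float
    psub_mean_pa: float


def bandpass(
    rec: SignalRecording, lo_hz: float = 20.0, hi_hz: float = 20000.0, order: int = 4
) -> SignalRecording:
    """Zero-phase Butterworth band-pass; removes DC by construction."""
    if hi_hz >= rec.fs_hz / 2:
        raise ValueError(
            f"upper edge {hi_hz} Hz must be below Nyquist ({rec.fs_hz / 2} Hz)"
        )
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    return SignalRecording(
        samples=sps.sosfiltfilt(sos, rec.samples), fs_hz=rec.fs_hz, channel=rec.channel
    )


def detect_cycles(
    rec: SignalRecording,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    min_peak: float = 0.3,
) -> PeriodSequence:
    """Cycle detection on a (filtered) pressure signal.

    Coarse F0 from the autocorrelation within the band, then one mark per
    expected period at the dominant positive peak, refined by parabolic
    interpolation to sub-sample precision (period quantization at 96 kHz
    would otherwise dominate small jitter values).  Raises
    :class:`F0UndetectableError` for aperiodic records.
    """
    x = np.asarray(rec.samples, dtype=float)
    x = x - x.mean()
    fs = rec.fs_hz
    f0 = coarse_f0_autocorr(x, fs, f0_band_hz, min_peak=min_peak)
    period = fs / f0

    # Marks are found on a differentiated, F0-proportionate band-limited
    # copy: differentiation weights the sharp intra-cycle feature (the
    # closure transient) that actually carries timing, while the
    # [0.3 f0, 12 f0] prefilter keeps broadband noise from competing
    # with it.  Amplitudes are still read from the unfiltered signal.
    hi_pre = min(12.0 * f0, 0.45 * fs)
    sos_pre = sps.butter(2, [0.3 * f0, hi_pre], btype="bandpass", fs=fs, output="sos")
    xd = np.gradient(sps.sosfiltfilt(sos_pre, x))
    first = int(np.argmax(xd[: max(2, int(round(period)))]))
    idx_marks = [first]
    while True:
        lo = idx_marks[-1] + int(round(0.5 * period))
        hi = idx_marks[-1] + int(round(1.5 * period)) + 1
        if hi > x.size:
            break
        idx_marks.append(lo + int(np.argmax(xd[lo:hi])))
    if len(idx_marks) < 3:
        raise F0UndetectableError("fewer than two complete cycles detected")
    idx_marks = np.asarray(idx_marks)

    # Waveform-matching refinement: align every mark to the ensemble-mean
    # cycle of the differentiated signal by local cross-correlation, with
    # parabolic sub-sample interpolation of the correlation maximum.
    L = max(4, int(round(0.8 * period)))
    half = L // 4
    shift_max = max(2, int(round(0.25 * period)))
    frac = np.zeros(idx_marks.size)
    for _ in range(2):
        segs = [
            xd[m - half : m - half + L]
            for m in idx_marks
            if m - half >= 0 and m - half + L <= x.size
        ]
        if len(segs) < 3:
            break
        template = np.mean(segs, axis=0)
        new_marks = idx_marks.copy()
        frac = np.zeros(idx_marks.size)
        for k, m in enumerate(idx_marks):
            lo = max(0, m - half - shift_max)
            hi = min(x.size, m - half + L + shift_max)
            if hi - lo < L + 2:
                continue
            score = np.correlate(xd[lo:hi], template, mode="valid")
            j = int(np.argmax(score))
            new_marks[k] = lo + j + half
            if 0 < j < score.size - 1:
                y0, y1, y2 = score[j - 1], score[j], score[j + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    d = 0.5 * (y0 - y2) / denom
                    frac[k] = d if abs(d) <= 1 else 0.0
        if np.array_equal(new_marks, idx_marks):
            break
        idx_marks = new_marks
    order = np.argsort(idx_marks, kind="stable")
    idx_marks, frac = idx_marks[order], frac[order]
    keep = np.concatenate(([True], np.diff(idx_marks) > 0))
    idx_marks, frac = idx_marks[keep], frac[keep]
    if idx_marks.size < 3:
        raise F0UndetectableError("fewer than two complete cycles detected")
    t_marks = (idx_marks + frac) / fs

    # Per-cycle amplitude: the waveform maximum sits at a fixed offset
    # from the (feature-aligned) marks — locate it once on the ensemble
    # mean, then parabolic-refine the local peak of every cycle there,
    # so each cycle contributes exactly one pulse.
    Lc = int(np.median(np.diff(idx_marks)))
    segs = [x[m : m + Lc] for m in idx_marks if m + Lc <= x.size]
    peak_off = int(np.argmax(np.mean(segs, axis=0))) if segs else 0
    win = max(2, int(round(0.15 * period)))
    amps = np.empty(idx_marks.size)
    for k, m in enumerate(idx_marks):
        m = m + peak_off
        lo = max(0, m - win)
        seg = x[lo : min(x.size, m + win + 1)]
        i = int(np.argmax(seg))
        v = float(seg[i])
        if 0 < i < seg.size - 1:
            y0, y1, y2 = seg[i - 1], seg[i], seg[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                d = 0.5 * (y0 - y2) / denom
                if abs(d) <= 1:
                    v = y1 - 0.25 * (y0 - y2) * d
        amps[k] = v
    periods = np.diff(t_marks)
    if np.any(periods <= 0):
        raise F0UndetectableError("non-monotone cycle marks")
    return PeriodSequence(
        marks_s=t_marks, marks_idx=idx_marks, fs_hz=fs,
        periods_s=periods, amplitudes=amps[:-1],
    )


def jitter_pct(periods_s: np.ndarray) -> float:
    """Local jitter: 100 * mean|T_i - T_{i+1}| / mean(T_i)."""
    t = np.asarray(periods_s, dtype=float)
    if t.size < 2:
        return float("nan")
    return 100.0 * float(np.mean(np.abs(np.diff(t)))) / float(np.mean(t))


def shimmer_pct(amplitudes: np.ndarray) -> float:
    """Local shimmer: 100 * mean|A_i - A_{i+1}| / mean(A_i)."""
    return jitter_pct(amplitudes)


def _ensemble_energies(
    x: np.ndarray,
    marks_idx: np.ndarray,
    resample_len: Optional[int] = None,
) -> Tuple[float, float, int]:
    """Harmonic/noise energy split over the cycle ensemble.

    Cycles run mark-to-mark.  By default they are truncated to the
    common minimum length (no interpolation, so broadband noise energy
    per sample is preserved); ``resample_len`` switches to linear
    resampling onto a fixed grid for callers that want equal weighting
    of stretched cycles.
    """
    starts, ends = marks_idx[:-1], marks_idx[1:]
    if resample_len is None:
        L = int(np.min(ends - starts))
        cyc = np.stack([x[s : s + L] for s in starts])
    else:
        L = int(resample_len)
        grid = np.arange(L) / L
        cyc = np.stack(
            [np.interp(grid * (e - s), np.arange(e - s + 1), x[s : e + 1]) for s, e in zip(starts, ends)]
        )
    mean_cycle = cyc.mean(axis=0)
    h = float(np.sum(mean_cycle**2))
    n = float(np.mean(np.sum((cyc - mean_cycle) ** 2, axis=1)))
    return h, n, cyc.shape[0]


def hnr_db(
    rec: SignalRecording,
    periods: PeriodSequence,
    resample_len: Optional[int] = None,
) -> float:
    """Harmonics-to-noise ratio via the cycle-ensemble decomposition,
    capped at +60 dB for (near-)noiseless records."""
    if periods.n_cycles < 10:
        raise ValueError("HNR needs at least 10 cycles")
    x = np.asarray(rec.samples, dtype=float) - float(np.mean(rec.samples))
    h, n, _ = _ensemble_energies(x, periods.marks_idx, resample_len)
    if n <= 0 or 10 * math.log10(max(h, 1e-300) / n) > HNR_CAP_DB:
        logger.info("noise energy ~0; HNR capped at %+.0f dB", HNR_CAP_DB)
        return HNR_CAP_DB
    return 10.0 * math.log10(h / n)


def nne_db(
    rec: SignalRecording,
    periods: PeriodSequence,
    resample_len: Optional[int] = None,
) -> float:
    """Normalized noise energy 10*log10(N/(H+N)), floored at -60 dB."""
    if periods.n_cycles < 10:
        raise ValueError("NNE needs at least 10 cycles")
    x = np.asarray(rec.samples, dtype=float) - float(np.mean(rec.samples))
    h, n, _ = _ensemble_energies(x, periods.marks_idx, resample_len)
    if n <= 0:
        return NNE_FLOOR_DB
    val = 10.0 * math.log10(n / (h + n))
    return max(val, NNE_FLOOR_DB)


def cpp_db(
    rec: SignalRecording,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    frame_s: float = 0.08192,
    hop_frac: float = 0.5,
) -> float:
    """Cepstral peak prominence, averaged over Hann-windowed frames.

    Per frame: real cepstrum of the dB power spectrum; a straight line is
    fit to cepstrum vs. quefrency from 1 ms up to the period of the
    band's lower edge, and CPP is the tallest cepstral value inside the
    expected-period band minus the regression line at that quefrency.
    The default 81.92 ms frame holds >=4 periods at 48 Hz.
    """
    x = np.asarray(rec.samples, dtype=float)
    fs = rec.fs_hz
    nwin = int(round(frame_s * fs))
    hop = max(1, int(round(nwin * hop_frac)))
    if x.size < nwin:
        raise ValueError("record shorter than one CPP frame")
    if not np.any(x - x.mean()):
        return float("nan")
    lo, hi = f0_band_hz
    window = np.hanning(nwin)
    nfft = int(2 ** np.ceil(np.log2(nwin)))
    q = np.arange(nfft) / fs
    fit_sel = (q >= 1e-3) & (q <= 1.0 / lo)
    peak_sel = (q >= 1.0 / hi) & (q <= 1.0 / lo)
    vals = []
    for s in range(0, x.size - nwin + 1, hop):
        frame = x[s : s + nwin] * window
        spec_db = 20.0 * np.log10(np.maximum(np.abs(np.fft.fft(frame, nfft)), 1e-300))
        cep = np.real(np.fft.ifft(spec_db))
        slope, intercept = np.polyfit(q[fit_sel], cep[fit_sel], 1)
        i = np.argmax(cep[peak_sel])
        q_peak = q[peak_sel][i]
        vals.append(cep[peak_sel][i] - (slope * q_peak + intercept))
    return float(np.mean(vals))


def spl_db(rec: SignalRecording) -> float:
    """Sound pressure level re 20 uPa of the time-resolved signal."""
    rms = float(np.sqrt(np.mean(np.square(rec.samples))))
    if rms <= 0:
        return float("nan")
    return 20.0 * math.log10(rms / P_REF_PA)


def rb(psub_mean_pa: float, q_mean_slm: float) -> float:
    """Glottal flow resistance R_B = mean(P_sub) / mean(Q) in Pa/SLM."""
    if q_mean_slm <= 0:
        raise ValueError("mean airflow must be positive")
    return psub_mean_pa / q_mean_slm


def analyze_signal(
    rec: SignalRecording,
    f0_band_hz: Tuple[float, float] = DEFAULT_F0_BAND_HZ,
    lo_hz: float = 20.0,
    hi_hz: float = 20000.0,
) -> SignalQualityMetrics:
    """Full signal-quality evaluation of one channel.

    The processing chain is channel-agnostic (both channels are
    "processed and evaluated in the same way"); only the auxiliary level
    differs: SPL for the acoustic channel, the DC mean for the
    subglottal one.  Raises :class:`F0UndetectableError` for aperiodic
    records.
    """
    psub_mean = float(np.mean(rec.samples)) if rec.channel == "subglottal" else math.nan
    filtered = bandpass(rec, lo_hz=lo_hz, hi_hz=hi_hz)
    periods = detect_cycles(filtered, f0_band_hz)
    return SignalQualityMetrics(
        f0_hz=periods.f0_hz,
        jitt_pct=jitter_pct(periods.periods_s),
        shim_pct=shimmer_pct(periods.amplitudes),
        hnr_db=hnr_db(filtered, periods),
        nne_db=nne_db(filtered, periods),
        cpp_db=cpp_db(filtered, f0_band_hz),
        n_cycles=periods.n_cycles,
        spl_db=spl_db(rec) if rec.channel == "acoustic" else math.nan,
        psub_mean_pa=psub_mean,
    )
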