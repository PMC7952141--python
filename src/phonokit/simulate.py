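"""Synthetic phonation generator.

A kinematic pulse model produces coupled, ground-truth-labelled channels
mimicking an excised-larynx phonation measurement: the glottal area
waveform with left/right hemi-areas (video rate, default 4 kHz), the
supraglottal acoustic signal and the subglottal pressure signal (default
96 kHz), and optionally a rendered high-speed frame stack with known
segmentation masks.

The model is phenomenological, not a self-oscillating tissue model: each
vocal-fold side contributes a half-wave pulse ``sin(pi*phi)**q`` per
cycle on top of half the posterior-gap baseline area, with per-cycle
period and amplitude perturbations drawn once and shared by all
channels.  The acoustic channel is the time derivative of the area
(a flow-derivative source); the subglottal pressure is a DC offset plus
a modulated component anti-correlated with the glottal opening, as the
myoelastic-aerodynamic picture of a superposition of unmodulated airflow
and glottally modulated components suggests.  Broadband sensor noise is
added per channel at a requested level relative to the harmonic part.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .datatypes import FrameStack, GlottalAreaWaveform, SignalRecording

__all__ = [
    "PhonationParameters",
    "CycleSequence",
    "MultimodalRecording",
    "draw_cycle_sequence",
    "synth_gaw",
    "synth_acoustic",
    "synth_psub",
    "render_frames",
    "simulate_recording",
]


@dataclass(frozen=True)
class PhonationParameters:
    """Ground-truth generator settings for one synthetic recording.

    Parameters
    ----------
    f0_hz : float
        Target fundamental frequency (study range roughly 48-280 Hz).
    duration_s : float
        Record length; 2 s of signal and 0.6 s of video in the study.
    gap_area_mm2 : float
        Baseline open area from the posterior pre-phonatory gap; the DC
        floor of the glottal area waveform.
    amp_left_mm2, amp_right_mm2 : float
        Hemi-area oscillation amplitudes; unequal values create
        left-right amplitude asymmetry.
    phase_offset_cycles : float
        Right-side phase lag as a fraction of the period, in [0, 0.5].
    jitter_cv, shimmer_cv : float
        Coefficients of variation of per-cycle periods and amplitudes.
    harmonic_richness : float
        Pulse sharpness exponent q in sin(pi*phi)**q; larger q gives a
        narrower pulse and a richer harmonic spectrum.
    open_quotient : float
        Open-phase fraction of the nominal period; the remainder is a
        closed phase, whose corner discontinuities give the realistic
        slowly decaying harmonic series.
    closing_exponent : float
        Pulse exponent on the closing half.  The default 1.0 ends the
        pulse with a non-zero slope (abrupt closure, Rosenberg-style),
        which puts a step into the area derivative and hence a slowly
        decaying (~1/f) harmonic comb into the acoustic channel, as
        observed for real glottal flow; set equal to
        ``harmonic_richness`` for the symmetric smooth pulse.
    noise_db_audio, noise_db_psub : float
        Broadband noise level relative to the harmonic part of each
        channel, in dB (-20 means noise 20 dB below the harmonic RMS;
        ``-inf`` disables relative noise).
    noise_band_hz : tuple of float
        Band of the turbulence noise (glottal jet noise is concentrated
        at low-to-mid audio frequencies, not spread to the instrumental
        Nyquist); the level above is the total RMS within this band.
    noise_floor_audio_pa, noise_floor_psub_pa : float
        Absolute sensor noise floors, so a non-oscillating record still
        contains realistic measurement noise.
    psub_dc_pa : float
        Mean subglottal pressure.
    psub_mod_pa_per_mm2 : float
        Coupling of the modulated pressure component to the area deficit.
    psub_deriv_pa_s_per_mm2 : float
        Inertive part of the subglottal modulation, proportional to the
        area derivative; gives the pressure channel the sharp closure
        feature seen in real subglottal recordings.
    acoustic_scale : float
        Scale from area derivative (mm^2/s) to acoustic pressure (Pa);
        default yields SPL in the study's 75-100 dB range.
    f0_drift_cv : float
        Optional random-walk drift of the period (per-cycle step CV), for
        erratic-oscillation fixtures; 0 disables drift.
    """

    f0_hz: float = 110.0
    duration_s: float = 2.0
    gap_area_mm2: float = 0.0
    amp_left_mm2: float = 5.0
    amp_right_mm2: float = 5.0
    phase_offset_cycles: float = 0.0
    jitter_cv: float = 0.0
    shimmer_cv: float = 0.0
    harmonic_richness: float = 2.0
    closing_exponent: float = 1.0
    open_quotient: float = 0.9
    noise_db_audio: float = -30.0
    noise_db_psub: float = -30.0
    noise_band_hz: Tuple[float, float] = (50.0, 5000.0)
    noise_floor_audio_pa: float = 2e-4
    noise_floor_psub_pa: float = 0.2
    psub_dc_pa: float = 1000.0
    psub_mod_pa_per_mm2: float = 30.0
    psub_deriv_pa_s_per_mm2: float = 0.02
    acoustic_scale: float = 1e-4
    flow_slm: float = 50.0
    fs_signal_hz: float = 96000.0
    fs_video_hz: float = 4000.0
    video_duration_s: Optional[float] = 0.6
    f0_drift_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_hz <= 0 or self.duration_s <= 0:
            raise ValueError("f0_hz and duration_s must be positive")
        if self.amp_left_mm2 < 0 or self.amp_right_mm2 < 0 or self.gap_area_mm2 < 0:
            raise ValueError("areas and amplitudes must be >= 0")
        if not (0.0 <= self.phase_offset_cycles <= 0.5):
            raise ValueError("phase_offset_cycles must lie in [0, 0.5]")
        if self.jitter_cv < 0 or self.shimmer_cv < 0:
            raise ValueError("jitter_cv and shimmer_cv must be >= 0")
        if self.jitter_cv >= 0.33:
            raise ValueError(
                "jitter_cv >= 0.33 not supported: +/-3 sigma truncation would "
                "distort the realized coefficient of variation"
            )
        if not (0.0 < self.open_quotient <= 1.0):
            raise ValueError("open_quotient must lie in (0, 1]")
        # Pulse bandwidth grows with richness; demand a generous margin.
        if self.fs_signal_hz < 2 * self.f0_hz * (self.harmonic_richness + 10):
            raise ValueError("fs_signal_hz too low for the requested harmonic content")


@dataclass
class CycleSequence:
    """Realized per-cycle periods and per-side amplitudes."""

    periods_s: np.ndarray
    amp_left_mm2: np.ndarray
    amp_right_mm2: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.periods_s.size


@dataclass
class MultimodalRecording:
    """One synthetic measurement: three channels plus ground truth."""

    audio: SignalRecording
    psub: SignalRecording
    gaw: GlottalAreaWaveform
    truth: PhonationParameters
    cycles: CycleSequence
    frames: Optional[FrameStack] = None
    masks: Optional[np.ndarray] = None


def draw_cycle_sequence(params: PhonationParameters, n_cycles: Optional[int] = None) -> CycleSequence:
    """Draw per-cycle periods and per-side amplitudes.

    Periods are ``(1/f0) * (1 + eps)`` with ``eps ~ N(0, jitter_cv)``
    truncated at +/-3 sigma; amplitudes analogously with ``shimmer_cv``.
    The same relative amplitude fluctuation is applied to both sides so
    that shimmer does not masquerade as left-right asymmetry.  With
    ``f0_drift_cv`` set, a random walk is added to the period sequence
    (erratic-oscillation fixtures).
    """
    rng = np.random.default_rng(params.seed)
    t0 = 1.0 / params.f0_hz
    if n_cycles is None:
        # enough cycles to cover the record even with negative jitter draws
        n_cycles = int(math.ceil(params.duration_s / t0 * 1.2)) + 5

    def truncated_normal(sigma: float, n: int) -> np.ndarray:
        if sigma == 0:
            return np.zeros(n)
        draws = rng.normal(0.0, sigma, size=n)
        bad = np.abs(draws) > 3 * sigma
        while np.any(bad):
            draws[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
            bad = np.abs(draws) > 3 * sigma
        return draws

    eps = truncated_normal(params.jitter_cv, n_cycles)
    if params.f0_drift_cv > 0:
        eps = eps + np.cumsum(rng.normal(0.0, params.f0_drift_cv, size=n_cycles))
    eta = truncated_normal(params.shimmer_cv, n_cycles)
    periods = t0 * np.clip(1.0 + eps, 0.05, None)
    return CycleSequence(
        periods_s=periods,
        amp_left_mm2=params.amp_left_mm2 * np.clip(1.0 + eta, 0.0, None),
        amp_right_mm2=params.amp_right_mm2 * np.clip(1.0 + eta, 0.0, None),
    )


def _phase(t: np.ndarray, periods: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Continuous cycle phase: integer part = cycle index, fractional part
    = position within the cycle."""
    bounds = np.concatenate(([0.0], np.cumsum(periods)))
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, periods.size - 1)
    frac = (t - bounds[idx]) / periods[idx]
    return idx, np.clip(frac, 0.0, 1.0)


def _hemi_area(
    t: np.ndarray,
    cycles: CycleSequence,
    params: PhonationParameters,
    side: str,
) -> np.ndarray:
    """Evaluate one hemi-area at arbitrary times (the right side lags by
    ``phase_offset_cycles`` of the nominal period).

    Each cycle's pulse has the fixed nominal width 1/f0 (truncated when a
    short period would overlap the next pulse) and is anchored at the
    cycle-start event, so period perturbation modulates the closed
    interval between pulses.  Stretching the pulse itself would make the
    injected period CV unrecoverable in principle: any event marker at a
    fraction c of a uniformly stretched cycle sees a (1-c, c) moving
    average of the period sequence, attenuating measured jitter.
    """
    t_nom = 1.0 / params.f0_hz
    # period draws are truncated at 3 sigma, so this width fits every cycle
    # and all pulses share one shape: event times then carry the full jitter
    w_nom = t_nom * max(min(params.open_quotient, 1.0 - 3.0 * params.jitter_cv), 0.05)
    if side == "left":
        amps, t_eval = cycles.amp_left_mm2, t
    else:
        amps = cycles.amp_right_mm2
        t_eval = t - params.phase_offset_cycles * t_nom
    idx, _ = _phase(np.clip(t_eval, 0.0, None), cycles.periods_s)
    bounds = np.concatenate(([0.0], np.cumsum(cycles.periods_s)))
    width = np.minimum(cycles.periods_s[idx], w_nom)
    frac = np.clip((t_eval - bounds[idx]) / width, 0.0, 1.0)
    # opening half uses the richness exponent, closing half the closing
    # exponent; both halves are C1-continuous at the peak (phi = 0.5)
    s = np.sin(np.pi * frac)
    pulse = np.where(
        frac <= 0.5,
        s ** params.harmonic_richness,
        s ** params.closing_exponent,
    )
    a = params.gap_area_mm2 / 2.0 + amps[idx] * pulse
    a[t_eval < 0] = params.gap_area_mm2 / 2.0
    return np.maximum(a, 0.0)


def _area_series(
    params: PhonationParameters, cycles: CycleSequence, fs: float, duration: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.arange(int(round(duration * fs))) / fs
    left = _hemi_area(t, cycles, params, "left")
    right = _hemi_area(t, cycles, params, "right")
    return t, left, right


def synth_gaw(
    params: PhonationParameters, cycles: Optional[CycleSequence] = None
) -> GlottalAreaWaveform:
    """Sample the glottal area waveform at the video rate."""
    if cycles is None:
        cycles = draw_cycle_sequence(params)
    dur = params.video_duration_s or params.duration_s
    _, left, right = _area_series(params, cycles, params.fs_video_hz, dur)
    return GlottalAreaWaveform(
        area_total=left + right,
        fs_video_hz=params.fs_video_hz,
        area_left=left,
        area_right=right,
    )


def _add_noise(
    harmonic: np.ndarray,
    noise_db: float,
    floor: float,
    rng: np.random.Generator,
    fs: float,
    band_hz: Tuple[float, float],
) -> np.ndarray:
    """Add measurement noise: a band-limited turbulence component with
    total RMS ``noise_db`` below the harmonic RMS, plus a white sensor
    floor across the full instrumental band."""
    out = harmonic
    h_rms = float(np.sqrt(np.mean(harmonic**2)))
    rel = 0.0 if not np.isfinite(noise_db) else h_rms * 10 ** (noise_db / 20.0)
    if rel > 0:
        from scipy import signal as sps

        white = rng.normal(0.0, 1.0, size=harmonic.size)
        lo, hi = band_hz
        hi = min(hi, 0.45 * fs)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        shaped = sps.sosfiltfilt(sos, white)
        shaped *= rel / float(np.sqrt(np.mean(shaped**2)))
        out = out + shaped
    if floor > 0:
        out = out + rng.normal(0.0, floor, size=harmonic.size)
    return out


def synth_acoustic(
    params: PhonationParameters, cycles: Optional[CycleSequence] = None
) -> SignalRecording:
    """Supraglottal acoustic channel: scaled time derivative of the
    glottal area (flow-derivative source) plus broadband noise."""
    if cycles is None:
        cycles = draw_cycle_sequence(params)
    _, left, right = _area_series(params, cycles, params.fs_signal_hz, params.duration_s)
    area = left + right
    harmonic = params.acoustic_scale * np.gradient(area) * params.fs_signal_hz
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    samples = _add_noise(harmonic, params.noise_db_audio, params.noise_floor_audio_pa,
                         rng, params.fs_signal_hz, params.noise_band_hz)
    return SignalRecording(samples=samples, fs_hz=params.fs_signal_hz, channel="acoustic")


def synth_psub(
    params: PhonationParameters, cycles: Optional[CycleSequence] = None
) -> SignalRecording:
    """Subglottal pressure channel: DC plus a modulated component
    anti-correlated with the glottal opening, plus broadband noise."""
    if cycles is None:
        cycles = draw_cycle_sequence(params)
    _, left, right = _area_series(params, cycles, params.fs_signal_hz, params.duration_s)
    area = left + right
    harmonic = params.psub_mod_pa_per_mm2 * (float(np.mean(area)) - area)
    if params.psub_deriv_pa_s_per_mm2:
        harmonic = harmonic - params.psub_deriv_pa_s_per_mm2 * np.gradient(area) * params.fs_signal_hz
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    noisy = _add_noise(harmonic, params.noise_db_psub, params.noise_floor_psub_pa,
                       rng, params.fs_signal_hz, params.noise_band_hz)
    return SignalRecording(
        samples=params.psub_dc_pa + noisy, fs_hz=params.fs_signal_hz, channel="subglottal"
    )


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _lens_masks(
    area_left_px: float,
    area_right_px: float,
    resolution: int,
    axis_len_frac: float = 0.7,
) -> np.ndarray:
    """Rasterize a lens-shaped glottis: two half-ellipses sharing a
    vertical midline of fixed semi-length ``b``.

    The midline runs between the two center columns, so no pixel lies on
    the axis.  Each side is rasterized by greedy coverage: every pixel's
    analytic coverage by the half-lens is computed, and exactly
    ``round(area)`` pixels are taken in decreasing coverage order (ties
    broken toward the lens center).  This keeps the pixel count exact
    and the shape compact and connected even for sub-pixel-wide slivers
    near closure, which plain pixel-center rasterization would drop.
    """
    b = axis_len_frac * resolution / 2.0
    cy = (resolution - 1) / 2.0
    col_left = resolution // 2 - 1   # first column left of the midline
    col_right = resolution // 2      # first column right of the midline
    rows = np.arange(resolution)
    y2 = np.clip(1.0 - ((rows - cy) / b) ** 2, 0.0, None)
    mask = np.zeros((resolution, resolution), dtype=bool)
    for area_px, start, step in ((area_left_px, col_left, -1), (area_right_px, col_right, +1)):
        n_px = int(round(area_px))
        if n_px <= 0:
            continue
        # half-ellipse area = (pi/2) * w * b  =>  max half-width w
        w = 2.0 * area_px / (math.pi * b)
        if w > resolution / 2.0 or n_px > resolution**2 // 2:
            raise ValueError("requested glottis area larger than the frame")
        widths = w * np.sqrt(y2)
        kmax = max(1, int(math.ceil(widths.max())))
        # coverage of the k-th pixel out from the axis in each row
        cover = np.clip(widths[:, None] - np.arange(kmax)[None, :], 0.0, 1.0)
        r_idx, k_idx = np.nonzero(cover > 0)
        if r_idx.size < n_px:  # numerical corner: widen by one pixel layer
            cover = np.clip(widths[:, None] + 0.5 - np.arange(kmax + 1)[None, :], 0.0, 1.0)
            r_idx, k_idx = np.nonzero(cover > 0)
        order = np.lexsort((k_idx, np.abs(rows[r_idx] - cy), -cover[r_idx, k_idx]))
        take = order[: min(n_px, order.size)]
        cols = start + step * k_idx[take]
        mask[r_idx[take], cols] = True
    return mask


def render_frames(
    params: PhonationParameters,
    cycles: Optional[CycleSequence] = None,
    resolution: int = 256,
    pixel_scale_mm: float = 0.05,
    n_frames: Optional[int] = None,
) -> Tuple[FrameStack, np.ndarray]:
    """Render a synthetic high-speed stack (dark glottis on a brighter
    textured background) plus its ground-truth masks.

    The per-frame mask pixel count times ``pixel_scale_mm**2`` tracks the
    hemi-areas of the generator's waveform (rasterization keeps it within
    a couple of percent for realistically sized glottises).
    """
    if resolution < 64:
        raise ValueError("resolution must be >= 64")
    if cycles is None:
        cycles = draw_cycle_sequence(params)
    dur = params.video_duration_s or params.duration_s
    t, left, right = _area_series(params, cycles, params.fs_video_hz, dur)
    if n_frames is not None:
        t, left, right = t[:n_frames], left[:n_frames], right[:n_frames]
    px_area = pixel_scale_mm**2
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    background = 0.65 + 0.1 * rng.random((resolution, resolution))
    frames = np.empty((t.size, resolution, resolution), dtype=np.float32)
    masks = np.zeros((t.size, resolution, resolution), dtype=bool)
    for i in range(t.size):
        m = _lens_masks(left[i] / px_area, right[i] / px_area, resolution)
        frame = background.copy()
        frame[m] = 0.05 + 0.03 * rng.random(int(m.sum()))
        frames[i] = frame
        masks[i] = m
    stack = FrameStack(frames=frames, fs_video_hz=params.fs_video_hz, pixel_scale_mm=pixel_scale_mm)
    return stack, masks


def simulate_recording(
    params: PhonationParameters,
    with_frames: bool = False,
    resolution: int = 256,
    pixel_scale_mm: float = 0.05,
) -> MultimodalRecording:
    """Generate all channels of one synthetic measurement from a single
    realized cycle sequence, so the channels share ground truth."""
    cycles = draw_cycle_sequence(params)
    gaw = synth_gaw(params, cycles)
    audio = synth_acoustic(params, cycles)
    psub = synth_psub(params, cycles)
    frames = masks = None
    if with_frames:
        frames, masks = render_frames(
            params, cycles, resolution=resolution, pixel_scale_mm=pixel_scale_mm
        )
    return MultimodalRecording(
        audio=audio, psub=psub, gaw=gaw, truth=params, cycles=cycles,
        frames=frames, masks=masks,
    )
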