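"""End-to-end study cohort: simulate -> segment -> analyze.

Maps a measurement-protocol grid onto generator settings, renders and
analyzes every record, and returns the flat measurement table the
statistics battery consumes.  The mapping encodes the physical
hypotheses the study design manipulates:

* the posterior gap sets the baseline open area (closure, GGI) *and*
  the turbulent-noise level of both pressure channels — incomplete
  closure produces broadband flow noise;
* the configuration's periodicity (jitter/shimmer) drives signal
  regularity and hence CPP, independently of closure;
* left-right asymmetry (amplitude ratio, phase lag) is varied
  independently of the noise level, so symmetry by construction has no
  direct effect on signal quality.

Fundamental frequency rises with total adduction torque (tissue
tension), and subglottal pressure rises with airflow.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GlottalAreaWaveform
from .gaw_metrics import F0UndetectableError, analyze_gaw
from .io import LaryngealConfiguration, MeasurementRecord, enumerate_protocol
from .segmentation import GlottisSegmenter
from .signal_metrics import analyze_signal, rb
from .simulate import PhonationParameters, simulate_recording

logger = logging.getLogger(__name__)

__all__ = ["params_for_config", "analyze_recording", "run_cohort"]

STUDY_GAPS_MM = (0.0, 1.0, 2.0)
STUDY_ADDUCTION_MNM = ((5.0, 15.0), (5.0, 25.0), (15.0, 25.0))
STUDY_FLOW_STEPS = 7


def params_for_config(
    config: LaryngealConfiguration,
    seed: int,
    duration_s: float = 2.0,
    video_duration_s: float = 0.6,
    fs_signal_hz: float = 96000.0,
    fs_video_hz: float = 4000.0,
) -> PhonationParameters:
    """Generator settings for one protocol cell.

    Per-larynx traits (base F0, asymmetry, perturbation levels) are
    drawn reproducibly from the larynx identifier so that specimens
    differ from each other but not between runs.
    """
    lid_num = int("".join(ch for ch in config.larynx_id if ch.isdigit()) or 0)
    # per-larynx traits: one stream per specimen ...
    trait_rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + lid_num]))
    base_f0 = float(trait_rng.uniform(100.0, 160.0))
    larynx_noise_db = float(trait_rng.normal(0.0, 1.0))
    # ... and one stream per protocol cell, so periodicity, symmetry and
    # turbulence vary *within* a larynx across its configurations
    cell_rng = np.random.default_rng(
        np.random.SeedSequence(
            [seed, lid_num, int(round(config.gap_mm * 10)),
             int(round(config.torque_left_mNm)), int(round(config.torque_right_mNm)),
             config.flow_step]
        )
    )
    asym_ratio = float(cell_rng.uniform(0.55, 1.0))   # left/right amplitude ratio
    phase_off = float(cell_rng.uniform(0.0, 0.12))
    # log-uniform: cycle-to-cycle period variability spans healthy to
    # mildly erratic, and CPP responds roughly linearly in log(cv)
    jitter_cfg = float(10.0 ** cell_rng.uniform(-3.7, -2.0))
    shimmer_cfg = float(cell_rng.uniform(0.005, 0.06))

    # F0 rises with total adduction torque (elongation/tension effect)
    f0 = base_f0 * (1.0 + 0.006 * (config.total_torque_mNm - 20.0))
    # airflow raises subglottal pressure and oscillation amplitude
    flow = config.flow_slm
    psub_dc = 400.0 + 14.0 * flow
    amp = 4.0 * (0.8 + 0.004 * flow)
    # posterior gap sets the DC open area and the turbulence level
    gap_area = 2.2 * config.gap_mm
    noise_db = -38.0 + 12.0 * config.gap_mm + larynx_noise_db + float(cell_rng.normal(0.0, 1.0))
    # closed-phase duration varies across configurations independently of
    # the gap, so the closing quotient is not a mere closure duplicate
    open_quotient = float(cell_rng.uniform(0.7, 0.95))

    cell_seed = int(cell_rng.integers(0, 2**31 - 1))
    return PhonationParameters(
        f0_hz=float(np.clip(f0, 50.0, 280.0)),
        duration_s=duration_s,
        video_duration_s=video_duration_s,
        gap_area_mm2=gap_area,
        amp_left_mm2=amp * asym_ratio,
        amp_right_mm2=amp,
        phase_offset_cycles=phase_off,
        jitter_cv=min(jitter_cfg, 0.3),
        shimmer_cv=shimmer_cfg,
        open_quotient=open_quotient,
        noise_db_audio=noise_db,
        noise_db_psub=noise_db - 3.0,
        noise_band_hz=(50.0, 12000.0),
        psub_dc_pa=psub_dc,
        flow_slm=flow,
        fs_signal_hz=fs_signal_hz,
        fs_video_hz=fs_video_hz,
        seed=cell_seed,
    )


def analyze_recording(
    config: LaryngealConfiguration,
    audio,
    psub,
    gaw: GlottalAreaWaveform,
    f0_band_hz: Tuple[float, float] = (40.0, 400.0),
) -> MeasurementRecord:
    """Compute the full parameter vector of one multimodal recording.

    Channels with an undetectable fundamental frequency leave their
    metrics as NaN; the exclusion rules downstream act on those flags.
    """
    rec = MeasurementRecord(config=config)
    kwargs = {}
    try:
        g = analyze_gaw(gaw, f0_band_hz)
        kwargs.update(
            f0_hsi_hz=g.f0_hsi_hz, ggi=g.ggi, cq=g.cq, ap=g.ap, tp=g.tp,
            pai=g.pai, asi=g.asi,
        )
    except F0UndetectableError:
        logger.info("high-speed channel: F0 undetectable (%s)", config)
    try:
        a = analyze_signal(audio, f0_band_hz)
        kwargs.update(
            f0_audio_hz=a.f0_hz, spl_db=a.spl_db,
            hnr_audio_db=a.hnr_db, nne_audio_db=a.nne_db, cpp_audio_db=a.cpp_db,
            jitt_audio_pct=a.jitt_pct, shim_audio_pct=a.shim_pct,
        )
    except F0UndetectableError:
        logger.info("acoustic channel: F0 undetectable (%s)", config)
    psub_mean = float(np.mean(psub.samples))
    kwargs["psub_mean_pa"] = psub_mean
    if config.flow_slm > 0:
        kwargs["rb_pa_per_slm"] = rb(psub_mean, config.flow_slm)
    try:
        p = analyze_signal(psub, f0_band_hz)
        kwargs.update(
            f0_psub_hz=p.f0_hz,
            hnr_psub_db=p.hnr_db, nne_psub_db=p.nne_db, cpp_psub_db=p.cpp_db,
            jitt_psub_pct=p.jitt_pct, shim_psub_pct=p.shim_pct,
        )
    except F0UndetectableError:
        logger.info("subglottal channel: F0 undetectable (%s)", config)
    return replace(rec, **kwargs)


def run_cohort(
    seed: int,
    n_larynges: int = 9,
    gaps_mm: Sequence[float] = STUDY_GAPS_MM,
    adduction_levels: Sequence[Tuple[float, float]] = STUDY_ADDUCTION_MNM,
    n_flow_steps: int = STUDY_FLOW_STEPS,
    duration_s: float = 2.0,
    video_duration_s: float = 0.6,
    through_frames: bool = False,
    frame_resolution: int = 128,
    max_video_frames: Optional[int] = 200,
    fs_signal_hz: float = 96000.0,
    fs_video_hz: float = 4000.0,
) -> pd.DataFrame:
    """Simulate and analyze a full synthetic cohort.

    With ``through_frames`` the glottal area waveform is recovered by
    rendering and re-segmenting the high-speed stack (the full imaging
    pipeline); otherwise the generator's waveform is analyzed directly.
    Returns the flat measurement table (one row per protocol cell).
    """
    from .io import records_to_frame

    grid = enumerate_protocol(n_larynges, list(gaps_mm), list(adduction_levels), n_flow_steps)
    records: List[MeasurementRecord] = []
    for config in grid:
        params = params_for_config(
            config, seed, duration_s=duration_s, video_duration_s=video_duration_s,
            fs_signal_hz=fs_signal_hz, fs_video_hz=fs_video_hz,
        )
        mm = simulate_recording(
            params, with_frames=through_frames, resolution=frame_resolution,
            pixel_scale_mm=0.1,
        )
        gaw = mm.gaw
        if through_frames:
            frames = mm.frames
            if max_video_frames is not None and frames.n_frames > max_video_frames:
                from .datatypes import FrameStack

                frames = FrameStack(
                    frames=frames.frames[:max_video_frames],
                    fs_video_hz=frames.fs_video_hz,
                    pixel_scale_mm=frames.pixel_scale_mm,
                )
            seg = GlottisSegmenter().fit(frames)
            gaw = seg.area_waveform(frames)
        records.append(analyze_recording(config, mm.audio, mm.psub, gaw))
    return records_to_frame(records)
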