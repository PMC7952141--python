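"""Protocol enumeration, measurement records, exclusion rules, and file I/O.

The measurement protocol is a full factorial grid: larynges x
pre-phonatory gaps x asymmetric adduction levels x airflow steps.  Each
grid cell yields one multimodal recording, summarised downstream as a
:class:`MeasurementRecord`.  Records whose fundamental frequency cannot
be detected in at least one channel, or that belong to a configuration
series with aberrant glottal flow resistance (setup leakage), are
excluded before statistics.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .datatypes import FrameStack, GlottalAreaWaveform, SignalRecording

__all__ = [
    "LaryngealConfiguration",
    "MeasurementRecord",
    "ExclusionRule",
    "enumerate_protocol",
    "apply_exclusion_rules",
    "read_signal",
    "write_signal",
    "read_gaw",
    "write_gaw",
    "read_frames",
    "write_frames",
    "read_records",
    "write_records",
]


@dataclass(frozen=True)
class LaryngealConfiguration:
    """One cell of the measurement protocol.

    ``gap_mm`` is the posterior pre-phonatory gap, ``torque_left_mNm`` /
    ``torque_right_mNm`` the arytenoid adduction torques, ``flow_step``
    the index of the airflow increment above phonation onset and
    ``flow_slm`` the resulting mean airflow in standard liters/min.
    ``sensor_distance_mm`` (130 in the reference setup) is metadata only.
    """

    larynx_id: str
    gap_mm: float
    torque_left_mNm: float
    torque_right_mNm: float
    flow_step: int
    flow_slm: float = float("nan")
    sensor_distance_mm: float = 130.0

    def __post_init__(self) -> None:
        if self.gap_mm < 0:
            raise ValueError("gap_mm must be >= 0")
        if self.torque_left_mNm < 0 or self.torque_right_mNm < 0:
            raise ValueError("torques must be >= 0")
        if self.flow_step < 0:
            raise ValueError("flow_step must be >= 0")

    @property
    def total_torque_mNm(self) -> float:
        return self.torque_left_mNm + self.torque_right_mNm

    @property
    def asym_fraction(self) -> float:
        """Adduction asymmetry (T_L - T_R) / (T_L + T_R); NaN when undefined."""
        tot = self.total_torque_mNm
        if tot <= 0:
            return float("nan")
        return (self.torque_left_mNm - self.torque_right_mNm) / tot

    @property
    def series_key(self) -> Tuple[str, float, float, float]:
        """Identifies the configuration series this record belongs to
        (all airflow steps of one larynx/gap/adduction setting)."""
        return (self.larynx_id, self.gap_mm, self.torque_left_mNm, self.torque_right_mNm)


# Columns of the flat record table, in output order.
_RECORD_FIELDS = [
    "f0_hsi_hz", "f0_audio_hz", "f0_psub_hz",
    "psub_mean_pa", "rb_pa_per_slm", "spl_db",
    "ggi", "cq", "ap", "tp", "pai", "asi",
    "hnr_audio_db", "hnr_psub_db", "nne_audio_db", "nne_psub_db",
    "cpp_audio_db", "cpp_psub_db",
    "shim_audio_pct", "shim_psub_pct", "jitt_audio_pct", "jitt_psub_pct",
]

_INDEX_FIELDS = ["ggi", "cq", "ap", "tp", "pai", "asi"]
_PCT_FIELDS = ["shim_audio_pct", "shim_psub_pct", "jitt_audio_pct", "jitt_psub_pct"]
EXCLUSION_REASONS = ("none", "f0_undetectable", "leakage")


@dataclass
class MeasurementRecord:
    """Full parameter vector of one protocol cell.

    Metric fields may be NaN when not computable (e.g. after an
    undetectable fundamental frequency).  ``excluded_reason`` is one of
    ``none`` / ``f0_undetectable`` / ``leakage``.
    """

    config: LaryngealConfiguration
    f0_hsi_hz: float = math.nan
    f0_audio_hz: float = math.nan
    f0_psub_hz: float = math.nan
    psub_mean_pa: float = math.nan
    rb_pa_per_slm: float = math.nan
    spl_db: float = math.nan
    ggi: float = math.nan
    cq: float = math.nan
    ap: float = math.nan
    tp: float = math.nan
    pai: float = math.nan
    asi: float = math.nan
    hnr_audio_db: float = math.nan
    hnr_psub_db: float = math.nan
    nne_audio_db: float = math.nan
    nne_psub_db: float = math.nan
    cpp_audio_db: float = math.nan
    cpp_psub_db: float = math.nan
    shim_audio_pct: float = math.nan
    shim_psub_pct: float = math.nan
    jitt_audio_pct: float = math.nan
    jitt_psub_pct: float = math.nan
    excluded_reason: str = "none"

    def __post_init__(self) -> None:
        if self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")
        for name in _INDEX_FIELDS:
            v = getattr(self, name)
            if not math.isnan(v) and not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def excluded(self) -> bool:
        return self.excluded_reason != "none"

    @property
    def f0_detectable_all(self) -> bool:
        return not (
            math.isnan(self.f0_hsi_hz)
            or math.isnan(self.f0_audio_hz)
            or math.isnan(self.f0_psub_hz)
        )


def enumerate_protocol(
    n_larynges: int,
    gaps_mm: Sequence[float],
    adduction_levels: Sequence[Tuple[float, float]],
    n_flow_steps: int,
    flow_onset_slm: float = 20.0,
    flow_step_slm: float = 5.0,
) -> List[LaryngealConfiguration]:
    """Enumerate the full factorial measurement grid.

    Deterministic ordering: larynx, gap, adduction level, flow step.
    ``flow_slm`` is filled as onset + step * increment; the study raised
    airflow in 5 SLM steps from phonation onset.
    """
    if n_larynges <= 0 or n_flow_steps <= 0:
        raise ValueError("counts must be positive")
    if not gaps_mm or not adduction_levels:
        raise ValueError("gaps_mm and adduction_levels must be non-empty")
    grid: List[LaryngealConfiguration] = []
    for i in range(n_larynges):
        lid = f"L{i + 1}"
        for gap in gaps_mm:
            for (tl, tr) in adduction_levels:
                for step in range(n_flow_steps):
                    grid.append(
                        LaryngealConfiguration(
                            larynx_id=lid,
                            gap_mm=float(gap),
                            torque_left_mNm=float(tl),
                            torque_right_mNm=float(tr),
                            flow_step=step,
                            flow_slm=flow_onset_slm + flow_step_slm * step,
                        )
                    )
    return grid


@dataclass(frozen=True)
class ExclusionRule:
    """Leakage rule: flag a whole configuration series whose median R_B
    sits more than ``k_mad`` robust deviations above the within-larynx
    median.  The rule operates on series, not single records, because a
    leak in the mounting affects every airflow step of that setting."""

    k_mad: float = 5.0

    def leaking_series(self, records: Sequence[MeasurementRecord]) -> set:
        by_larynx: dict = {}
        for r in records:
            if not math.isnan(r.rb_pa_per_slm):
                by_larynx.setdefault(r.config.larynx_id, []).append(r)
        flagged = set()
        for lid, recs in by_larynx.items():
            rb_all = np.array([r.rb_pa_per_slm for r in recs])
            med = np.median(rb_all)
            mad = np.median(np.abs(rb_all - med))
            if mad == 0:
                mad = 1e-12
            series: dict = {}
            for r in recs:
                series.setdefault(r.config.series_key, []).append(r.rb_pa_per_slm)
            for key, vals in series.items():
                if np.median(vals) > med + self.k_mad * mad:
                    flagged.add(key)
        return flagged


def apply_exclusion_rules(
    records: Sequence[MeasurementRecord],
    rb_rule: Optional[ExclusionRule] = None,
) -> Tuple[List[MeasurementRecord], List[MeasurementRecord]]:
    """Partition records into (kept, excluded-with-reasons).

    A record is excluded iff the fundamental frequency is undetectable in
    at least one of the three channels (high-speed, acoustic, subglottal)
    or its configuration series is flagged by the leakage rule.
    Exclusion reasons are written onto the returned records; the
    operation is idempotent.
    """
    rule = rb_rule if rb_rule is not None else ExclusionRule()
    leaking = rule.leaking_series(records)
    kept: List[MeasurementRecord] = []
    excluded: List[MeasurementRecord] = []
    for r in records:
        if not r.f0_detectable_all:
            excluded.append(dataclasses.replace(r, excluded_reason="f0_undetectable"))
        elif r.config.series_key in leaking:
            excluded.append(dataclasses.replace(r, excluded_reason="leakage"))
        else:
            kept.append(dataclasses.replace(r, excluded_reason="none"))
    return kept, excluded


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_signal(
    path,
    fmt: Optional[str] = None,
    calibration_pa_per_unit: float = 1.0,
    channel: str = "acoustic",
    fs_hz: Optional[float] = None,
) -> SignalRecording:
    """Read a signal from WAV (PCM or float) or two-column time/value CSV.

    WAV sample values are multiplied by ``calibration_pa_per_unit`` to map
    raw units to Pa (pressure sensors are not natively WAV-calibrated).
    Tabular files carry their own time axis; the sampling rate is inferred
    from it unless ``fs_hz`` is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "wav" if path.suffix.lower() == ".wav" else "tabular"
    if fmt == "wav":
        fs, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        samples = data.astype(float) * calibration_pa_per_unit
        return SignalRecording(samples=samples, fs_hz=float(fs), channel=channel)
    if fmt == "tabular":
        df = pd.read_csv(path)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise ValueError(f"tabular signal file {path} is missing column '{col}'")
        t = df["time_s"].to_numpy(float)
        if fs_hz is None:
            if t.size < 2:
                raise ValueError("cannot infer sampling rate 'fs_hz' from fewer than 2 samples")
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("non-uniform time axis; pass 'fs_hz' explicitly")
            fs_hz = 1.0 / dt[0]
        samples = df["value"].to_numpy(float) * calibration_pa_per_unit
        return SignalRecording(samples=samples, fs_hz=float(fs_hz), channel=channel)
    raise ValueError(f"unknown signal format {fmt!r}")


def write_signal(rec: SignalRecording, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "wav" if path.suffix.lower() == ".wav" else "tabular"
    if fmt == "wav":
        wavfile.write(path, int(round(rec.fs_hz)), rec.samples.astype(np.float32))
    elif fmt == "tabular":
        pd.DataFrame({"time_s": rec.t, "value": rec.samples}).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")


def read_gaw(path, fs_video_hz: Optional[float] = None) -> GlottalAreaWaveform:
    """Read a glottal area waveform CSV (time_s, area_total[, area_left, area_right])."""
    df = pd.read_csv(path)
    for col in ("time_s", "area_total"):
        if col not in df.columns:
            raise ValueError(f"GAW file {path} is missing column '{col}'")
    t = df["time_s"].to_numpy(float)
    if fs_video_hz is None:
        if t.size < 2:
            raise ValueError("cannot infer sampling rate 'fs_video_hz' from fewer than 2 samples")
        fs_video_hz = 1.0 / float(t[1] - t[0])
    left = df["area_left"].to_numpy(float) if "area_left" in df.columns else None
    right = df["area_right"].to_numpy(float) if "area_right" in df.columns else None
    return GlottalAreaWaveform(
        area_total=df["area_total"].to_numpy(float),
        fs_video_hz=float(fs_video_hz),
        area_left=left,
        area_right=right,
    )


def write_gaw(gaw: GlottalAreaWaveform, path) -> None:
    data = {"time_s": gaw.t, "area_total": gaw.area_total}
    if gaw.has_hemi:
        data["area_left"] = gaw.area_left
        data["area_right"] = gaw.area_right
    pd.DataFrame(data).to_csv(path, index=False)


def read_frames(path, fs_video_hz: float, pixel_scale_mm: Optional[float] = None) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or a directory of PNGs."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        import tifffile

        frames = tifffile.imread(path)
    return FrameStack(frames=frames, fs_video_hz=fs_video_hz, pixel_scale_mm=pixel_scale_mm)


def write_frames(stack: FrameStack, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), stack.frames)


def _config_dict(cfg: LaryngealConfiguration) -> dict:
    return {
        "larynx_id": cfg.larynx_id,
        "gap_mm": cfg.gap_mm,
        "torque_left_mNm": cfg.torque_left_mNm,
        "torque_right_mNm": cfg.torque_right_mNm,
        "flow_step": cfg.flow_step,
        "flow_slm": cfg.flow_slm,
        "sensor_distance_mm": cfg.sensor_distance_mm,
    }


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Flatten records into a tidy table, one row per protocol cell."""
    rows = []
    for r in records:
        row = _config_dict(r.config)
        row["total_torque_mNm"] = r.config.total_torque_mNm
        row["asym_fraction"] = r.config.asym_fraction
        for f in _RECORD_FIELDS:
            row[f] = getattr(r, f)
        row["excluded_reason"] = r.excluded_reason
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> List[MeasurementRecord]:
    records = []
    for _, row in df.iterrows():
        cfg = LaryngealConfiguration(
            larynx_id=str(row["larynx_id"]),
            gap_mm=float(row["gap_mm"]),
            torque_left_mNm=float(row["torque_left_mNm"]),
            torque_right_mNm=float(row["torque_right_mNm"]),
            flow_step=int(row["flow_step"]),
            flow_slm=float(row["flow_slm"]),
            sensor_distance_mm=float(row.get("sensor_distance_mm", 130.0)),
        )
        kwargs = {f: float(row[f]) for f in _RECORD_FIELDS if f in row}
        records.append(
            MeasurementRecord(
                config=cfg,
                excluded_reason=str(row.get("excluded_reason", "none")),
                **kwargs,
            )
        )
    return records


def write_records(records: Sequence[MeasurementRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path) -> List[MeasurementRecord]:
    df = pd.read_csv(path)
    required = {"larynx_id", "gap_mm", "torque_left_mNm", "torque_right_mNm", "flow_step", "flow_slm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record table {path} is missing column(s) {sorted(missing)}")
    return frame_to_records(df)
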