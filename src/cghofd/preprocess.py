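"""Cleaning, Kaiser-window band-limiting, segmentation and gating.

The processing order mirrors the acquisition pipeline: NaN removal across
aligned channels, Kaiser FIR low-pass (35 Hz) and high-pass (0.0665 Hz)
denoising, min-max normalization of the PPG only, then tiling into
fixed-length windows which are gated on amplitude and on ABP-derived
SBP/DBP bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSegmentError,
    RecordExcludedError,
    RecordUnusableError,
    SegmentTooShortError,
)
from .types import Segment, WaveformRecord

__all__ = [
    "PreprocessConfig",
    "drop_nans",
    "normalize_minmax",
    "bandlimit",
    "segment_and_gate",
    "preprocess_record",
]


@dataclass
class PreprocessConfig:
    skip_head_s: float = 60.0
    window_s: float = 20.0
    hp_cutoff_Hz: float = 0.0665
    lp_cutoff_Hz: float = 35.0
    kaiser_ripple_dB: float = 60.0
    lp_transition_Hz: float = 5.0
    hp_transition_Hz: float = 0.05
    # Robust amplitude gate: drop windows whose per-channel extrema leave
    # median +/- amplitude_gate_iqr * IQR of the whole record.  None disables.
    amplitude_gate_iqr: float | None = 4.0
    # BP gate: (sbp_low, sbp_high, dbp_low, dbp_high); windows with
    # SBP >= high or <= low (resp. DBP) are dropped.
    bp_gate: tuple[float, float, float, float] = (80.0, 180.0, 50.0, 130.0)

    def validate(self, fs: float) -> None:
        if not (0 < self.hp_cutoff_Hz < self.lp_cutoff_Hz < fs / 2):
            raise ValueError("require 0 < hp_cutoff < lp_cutoff < fs/2")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


def drop_nans(record: WaveformRecord) -> WaveformRecord:
    """Remove every sample index at which any channel is NaN."""
    bad = np.isnan(record.ecg) | np.isnan(record.ppg) | np.isnan(record.abp)
    if bad.all():
        raise RecordUnusableError(f"record {record.subject_id}: all samples NaN")
    if not bad.any():
        return record
    keep = ~bad
    return WaveformRecord(subject_id=record.subject_id, fs=record.fs,
                          ecg=record.ecg[keep], ppg=record.ppg[keep],
                          abp=record.abp[keep], t0_offset_s=record.t0_offset_s)


def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Map a series onto [0, 1] via (x - min) / (max - min)."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi - lo <= 0:
        raise DegenerateSegmentError("constant series cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def _kaiser_fir(cutoff_Hz: float, transition_Hz: float, ripple_dB: float,
                fs: float, pass_zero: bool) -> np.ndarray:
    numtaps, beta = sps.kaiserord(ripple_dB, transition_Hz / (fs / 2.0))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, cutoff_Hz, window=("kaiser", beta),
                      pass_zero=pass_zero, fs=fs)


def _zero_phase_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    # A symmetric (linear-phase) FIR applied by centered convolution is
    # zero-phase; reflect-pad by half the filter length to keep edges sane.
    half = len(h) // 2
    xp = np.concatenate([x[half:0:-1], x, x[-2:-half - 2:-1]])
    y = sps.fftconvolve(xp, h, mode="same")
    return y[half:half + len(x)]


def bandlimit(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Kaiser FIR low-pass then high-pass; preserves length."""
    if cfg is None:
        cfg = PreprocessConfig()
    cfg.validate(fs)
    x = np.asarray(x, dtype=float)
    lp = _kaiser_fir(cfg.lp_cutoff_Hz, cfg.lp_transition_Hz, cfg.kaiser_ripple_dB,
                     fs, pass_zero=True)
    hp = _kaiser_fir(cfg.hp_cutoff_Hz, cfg.hp_transition_Hz, cfg.kaiser_ripple_dB,
                     fs, pass_zero=False)
    need = max(len(lp), len(hp))
    if len(x) < need:
        raise SegmentTooShortError(
            f"series of {len(x)} samples shorter than filter length {need}")
    y = _zero_phase_fir(x, lp)
    y = _zero_phase_fir(y, hp)
    return y


def _robust_bounds(x: np.ndarray, k: float) -> tuple[float, float]:
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = float(q3 - q1)
    return med - k * iqr, med + k * iqr


@dataclass
class GateCounts:
    candidates: int = 0
    dropped_amplitude: int = 0
    dropped_bp: int = 0
    retained: int = 0
    notes: list[str] = field(default_factory=list)


def segment_and_gate(record: WaveformRecord, cfg: PreprocessConfig | None = None,
                     counts: GateCounts | None = None) -> list[Segment]:
    """Skip the head, tile non-overlapping windows, apply amplitude/BP gates."""
    if cfg is None:
        cfg = PreprocessConfig()
    cfg.validate(record.fs)
    fs = record.fs
    skip = int(round(cfg.skip_head_s * fs))
    wlen = int(round(cfg.window_s * fs))
    if record.n_samples <= skip + wlen - 1:
        raise RecordExcludedError(
            f"record {record.subject_id} shorter than skip_head + window")

    gates = None
    if cfg.amplitude_gate_iqr is not None:
        k = cfg.amplitude_gate_iqr
        gates = {ch: _robust_bounds(getattr(record, ch)[skip:], k)
                 for ch in ("ecg", "ppg", "abp")}

    sbp_lo, sbp_hi, dbp_lo, dbp_hi = cfg.bp_gate
    out: list[Segment] = []
    c = counts if counts is not None else GateCounts()
    for start in range(skip, record.n_samples - wlen + 1, wlen):
        c.candidates += 1
        sl = slice(start, start + wlen)
        seg = Segment(parent=record.subject_id, start_index=start,
                      ecg=record.ecg[sl], ppg=record.ppg[sl],
                      abp=record.abp[sl], fs=fs)
        if gates is not None:
            bad = False
            for ch in ("ecg", "ppg", "abp"):
                lo, hi = gates[ch]
                arr = getattr(seg, ch)
                if arr.min() < lo or arr.max() > hi:
                    bad = True
                    break
            if bad:
                c.dropped_amplitude += 1
                continue
        sbp, dbp = float(seg.abp.max()), float(seg.abp.min())
        if sbp >= sbp_hi or sbp <= sbp_lo or dbp >= dbp_hi or dbp <= dbp_lo:
            c.dropped_bp += 1
            continue
        c.retained += 1
        out.append(seg)
    if not out:
        raise RecordExcludedError(
            f"record {record.subject_id}: no segment survived gating")
    return out


def preprocess_record(record: WaveformRecord, cfg: PreprocessConfig | None = None,
                      counts: GateCounts | None = None) -> list[Segment]:
    """Full chain: drop NaNs, band-limit ECG/PPG, normalize PPG, segment+gate.

    ABP is neither filtered nor normalized so that mmHg units survive for
    the reference SBP/DBP computation.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    record = drop_nans(record)
    ecg = bandlimit(record.ecg, record.fs, cfg)
    ppg = bandlimit(record.ppg, record.fs, cfg)
    filtered = WaveformRecord(subject_id=record.subject_id, fs=record.fs,
                              ecg=ecg, ppg=ppg, abp=record.abp,
                              t0_offset_s=record.t0_offset_s)
    segments = segment_and_gate(filtered, cfg, counts)
    for seg in segments:
        seg.ppg = normalize_minmax(seg.ppg)
    return segments
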