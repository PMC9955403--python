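"""Seeded generators for BP-coupled waveform triplets and sparse feature tables.

Two fixtures back the whole pipeline without any external download:

* :func:`generate_waveforms` emits a 125 Hz ECG/PPG/ABP triplet whose PPG
  foot lags the ECG R-peak by a delay linear in SBP, together with
  ground-truth fiducials for every complete cycle.
* :func:`generate_feature_table` emits a standard-normal feature matrix
  with a known sparse linear target, optional redundant (noisy-copy)
  columns, and the true support, for testing the selection algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoCyclesError
from .types import FEATURE_NAMES, FeatureTable, GroundTruth, PulseFiducials, WaveformRecord

__all__ = [
    "SynthWaveformConfig",
    "SynthFeatureConfig",
    "generate_waveforms",
    "generate_feature_table",
]

# Pulse-shape constants (fractions of the cycle period).  The PPG pulse is a
# sum of a systolic and a smaller reflected Gaussian bump, which guarantees a
# genuine falling-edge inflection (dicrotic notch) between them.  Pulses are
# evaluated per cycle on phase in [0, 1), so feet are sharp V-shaped troughs.
_SYS_CENTER = 0.28
_SYS_WIDTH = 0.09
_DIA_CENTER = 0.58
_DIA_WIDTH = 0.12
_DIA_AMP = 0.45
_PPG_BASELINE = 0.25
_WANDER_AMP = 0.03
_WANDER_HZ = 0.09
_REF_SBP = 120.0   # mmHg at which the foot delay equals _BASE_DELAY_MS
_BASE_DELAY_MS = 250.0


@dataclass
class SynthWaveformConfig:
    duration_s: float = 20.0
    fs: float = 125.0
    heart_rate_bpm: float = 72.0
    sbp_mmHg: float = 120.0
    dbp_mmHg: float = 70.0
    ptt_slope: float = -2.0   # ms of PPG-foot delay per mmHg of SBP
    noise_sd: float = 0.0
    hr_jitter_sd: float = 0.0  # Gaussian jitter on cycle length, seconds
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not self.dbp_mmHg < self.sbp_mmHg:
            raise ValueError("dbp must be below sbp")


@dataclass
class SynthFeatureConfig:
    n_segments: int = 200
    n_features: int = 25
    support: tuple[int, ...] = (0, 1, 2)       # 0-based feature indices
    effect_sizes: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_redundant: int = 0
    copy_noise_sd: float = 0.05
    noise_sd: float = 1.0                       # target noise, mmHg
    target_offset: float = 120.0                # SBP-like scale shift
    dbp_offset: float = 70.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.support) == 0:
            raise ValueError("support must be non-empty")
        if len(self.effect_sizes) != len(self.support):
            raise ValueError("effect_sizes must match support length")
        if not set(self.support) <= set(range(self.n_features)):
            raise ValueError("support indices out of range")
        if self.n_redundant > self.n_features - len(self.support):
            raise ValueError("too many redundant features")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    """Two-Gaussian pulse plus a slow decay, evaluated at phase in [0, 1).

    The linear decay keeps the late-diastolic tail strictly decreasing, so
    the foot (the wrap from phase 1 back to 0) is a sharp, well-defined
    trough even under additive noise.
    """
    sys = np.exp(-0.5 * ((phase - _SYS_CENTER) / _SYS_WIDTH) ** 2)
    dia = _DIA_AMP * np.exp(-0.5 * ((phase - _DIA_CENTER) / _DIA_WIDTH) ** 2)
    return sys + dia + 0.08 * (1.0 - phase)


def _clean_channels(cfg: SynthWaveformConfig, rng: np.random.Generator):
    """Build noise-free channels plus the per-cycle timing bookkeeping."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    period = 60.0 / cfg.heart_rate_bpm

    # R-peak times; optional jitter on successive cycle lengths.
    r_times = []
    tr = 0.25 * period
    while tr < cfg.duration_s + period:
        r_times.append(tr)
        dt = period + (rng.normal(0.0, cfg.hr_jitter_sd) if cfg.hr_jitter_sd > 0 else 0.0)
        tr += max(dt, 0.3 * period)
    r_times = np.asarray(r_times)

    delay_s = (_BASE_DELAY_MS + cfg.ptt_slope * (cfg.sbp_mmHg - _REF_SBP)) / 1000.0
    delay_s = float(np.clip(delay_s, 0.02, 0.45 * period))
    foot_times = r_times + delay_s

    ecg = np.zeros(n)
    qrs_w = 0.012  # narrow QRS-like bump, seconds
    for tr_k in r_times:
        ecg += np.exp(-0.5 * ((t - tr_k) / qrs_w) ** 2)

    # Phase within the current cycle: piecewise per [foot_k, foot_{k+1}),
    # extrapolated with the nominal period outside the first/last foot.
    phase = np.empty(n)
    idx = np.searchsorted(foot_times, t, side="right") - 1
    for i in range(n):
        k = idx[i]
        if k < 0:
            phase[i] = (t[i] - foot_times[0]) / period + 1.0
        elif k + 1 < len(foot_times):
            phase[i] = (t[i] - foot_times[k]) / (foot_times[k + 1] - foot_times[k])
        else:
            phase[i] = (t[i] - foot_times[k]) / period
    phase = np.mod(phase, 1.0)
    pulse = _pulse_shape(phase)

    ppg = _PPG_BASELINE + _WANDER_AMP * np.sin(2 * np.pi * _WANDER_HZ * t) + pulse

    # ABP: per-cycle affine map of the pulse shape onto [dbp, sbp], so each
    # cycle's extrema hit dbp and sbp exactly.
    abp = np.empty(n)
    foot_idx = np.clip(np.round(foot_times * cfg.fs).astype(int), 0, n)
    edges = sorted(set([0, *foot_idx.tolist(), n]))
    span = cfg.sbp_mmHg - cfg.dbp_mmHg
    for a, b in zip(edges[:-1], edges[1:]):
        seg = pulse[a:b]
        lo, hi = seg.min(), seg.max()
        if hi - lo < 1e-12:
            abp[a:b] = cfg.dbp_mmHg
        else:
            abp[a:b] = cfg.dbp_mmHg + span * (seg - lo) / (hi - lo)

    return t, ecg, ppg, abp, r_times, foot_times, period


def generate_waveforms(cfg: SynthWaveformConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Generate a BP-coupled ECG/PPG/ABP triplet with ground-truth fiducials.

    Ground-truth landmarks are read off the *noise-free* PPG with the
    package's landmark definitions, anchored on the exact R-peak times used
    in construction; detectors running on the noisy channels are then
    validated against them.
    """
    from .features import detect_ppg_fiducials

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t, ecg, ppg, abp, r_times, foot_times, period = _clean_channels(cfg, rng)
    n = len(t)

    r_idx = np.round(r_times * cfg.fs).astype(int)
    r_idx = r_idx[r_idx < n]
    fiducials = (detect_ppg_fiducials(ppg, cfg.fs, r_idx)
                 if len(r_idx) >= 2 else [])
    if not fiducials:
        raise NoCyclesError("record too short to contain one complete cycle")

    # Per-cycle reference BP from the noise-free ABP channel.
    sbp = np.array([abp[f.ppg_foot:f.next_foot].max() for f in fiducials])
    dbp = np.array([abp[f.ppg_foot:f.next_foot].min() for f in fiducials])

    if cfg.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, cfg.noise_sd, n)
        ppg = ppg + rng.normal(0.0, cfg.noise_sd, n)
        abp = abp + rng.normal(0.0, cfg.noise_sd, n)

    record = WaveformRecord(subject_id=f"synth-{cfg.seed}", fs=cfg.fs,
                            ecg=ecg, ppg=ppg, abp=abp)
    truth = GroundTruth(fiducials=fiducials, reference_sbp=sbp, reference_dbp=dbp)
    return record, truth


def generate_feature_table(cfg: SynthFeatureConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table with known sparse linear target structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_segments, cfg.n_features
    X = rng.standard_normal((n, p))

    support = tuple(cfg.support)
    effects = np.asarray(cfg.effect_sizes, dtype=float)
    signal = X[:, list(support)] @ effects

    redundant_of: dict[int, int] = {}
    free = [j for j in range(p) if j not in support]
    for i in range(cfg.n_redundant):
        j = free[i]
        src = support[i % len(support)]
        X[:, j] = X[:, src] + rng.normal(0.0, cfg.copy_noise_sd, n)
        redundant_of[j] = src

    noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
    y = cfg.target_offset + signal + noise
    y_dbp = cfg.dbp_offset + 0.5 * signal + (rng.normal(0.0, cfg.noise_sd, n)
                                             if cfg.noise_sd > 0 else 0.0)

    if p == len(FEATURE_NAMES):
        names = list(FEATURE_NAMES)
    else:
        names = [f"f{j + 1}" for j in range(p)]
    frame = pd.DataFrame(X, columns=names)
    frame["SBP"] = y
    frame["DBP"] = y_dbp
    table = FeatureTable(frame, names)
    truth = GroundTruth(reference_sbp=np.asarray(y, dtype=float),
                        reference_dbp=np.asarray(y_dbp, dtype=float),
                        true_support=support, effect_sizes=effects,
                        redundant_of=redundant_of)
    return table, truth
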