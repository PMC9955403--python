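"""Shared domain types: waveform records, fiducials, feature tables, weights."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical short names of the 25 morphology/timing features, in table order.
FEATURE_NAMES: tuple[str, ...] = (
    "ST", "DT", "PIR", "HR", "PAT1", "PAT3", "PAT2", "LASI", "AI",
    "S1", "S2", "S3", "S4", "IPAR", "PPGk",
    "dppgH", "dppgW", "ddppgPH", "ddppgTH", "ddppgW", "ddppgH",
    "MXAP", "MIAP", "MEU", "FHR",
)


@dataclass
class WaveformRecord:
    """Synchronized ECG/PPG/ABP sample arrays for one subject.

    ABP is in mmHg; ECG and PPG are in arbitrary units.  All three series
    must have the same length and share the sampling rate ``fs``.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    t0_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError("ecg/ppg/abp must have equal lengths")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        t = self.t0_offset_s + np.arange(self.n_samples) / self.fs
        return pd.DataFrame({"t": t, "ecg": self.ecg, "ppg": self.ppg, "abp": self.abp})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "record", fs: float | None = None) -> "WaveformRecord":
        df = pd.read_csv(path)
        if fs is None:
            t = df["t"].to_numpy()
            fs = round(1.0 / float(np.median(np.diff(t))), 6)
        return cls(subject_id=subject_id, fs=fs,
                   ecg=df["ecg"].to_numpy(), ppg=df["ppg"].to_numpy(),
                   abp=df["abp"].to_numpy())


@dataclass
class Segment:
    """One fixed-length window of a record; indices are 0-based half-open."""

    parent: str
    start_index: int
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError("segment channels must have equal lengths")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)


@dataclass(frozen=True)
class PulseFiducials:
    """Per-cardiac-cycle landmark sample indices.

    Ordering invariant: ppg_foot < max_slope < systolic_peak < inflection
    < next_foot, and r_peak < systolic_peak.
    """

    r_peak: int
    ppg_foot: int
    max_slope: int
    systolic_peak: int
    inflection: int
    next_foot: int

    def __post_init__(self) -> None:
        seq = (self.ppg_foot, self.max_slope, self.systolic_peak,
               self.inflection, self.next_foot)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"fiducials out of order: {seq}")
        if not self.r_peak < self.systolic_peak:
            raise ValueError("r_peak must precede the systolic peak")


@dataclass
class GroundTruth:
    """Generator-emitted truth used as an oracle by the test-suite."""

    fiducials: list[PulseFiducials] = field(default_factory=list)
    reference_sbp: np.ndarray | None = None
    reference_dbp: np.ndarray | None = None
    true_support: tuple[int, ...] | None = None
    effect_sizes: np.ndarray | None = None
    redundant_of: dict[int, int] | None = None


class FeatureTable:
    """Segments x features matrix plus reference SBP/DBP columns.

    Backed by a DataFrame whose columns are the feature names followed by
    ``SBP`` and ``DBP`` (and optional ``subject_id`` / ``segment_index``).
    """

    def __init__(self, frame: pd.DataFrame, feature_names: Sequence[str] | None = None):
        if feature_names is None:
            feature_names = [c for c in frame.columns
                             if c not in ("SBP", "DBP", "subject_id", "segment_index")]
        names = list(feature_names)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for col in names + ["SBP", "DBP"]:
            if col not in frame.columns:
                raise ValueError(f"missing column {col!r}")
        self.frame = frame.reset_index(drop=True)
        self.feature_names = names

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def y(self, target: str = "SBP") -> np.ndarray:
        if target not in ("SBP", "DBP"):
            raise ValueError("target must be 'SBP' or 'DBP'")
        return self.frame[target].to_numpy(dtype=float)

    def dropna(self) -> "FeatureTable":
        cols = self.feature_names + ["SBP", "DBP"]
        keep = self.frame[cols].notna().all(axis=1)
        return FeatureTable(self.frame[keep].reset_index(drop=True), self.feature_names)

    def to_csv(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, index=False, sep=sep)

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "FeatureTable":
        return cls(pd.read_csv(path, sep=sep))


@dataclass
class WeightVector:
    """Per-feature nonnegative scores with the ranking that produced them."""

    method: str  # FTEST | RNCA | MRMR
    weights: np.ndarray
    ranking: np.ndarray  # feature indices, descending weight
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        p = len(self.weights)
        if sorted(self.ranking.tolist()) != list(range(p)):
            raise ValueError("ranking must be a permutation of all feature indices")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_dict(self) -> dict:
        return {"method": self.method,
                "weights": self.weights.tolist(),
                "ranking": self.ranking.tolist(),
                "meta": _jsonable(self.meta)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
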