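"""Fiducial-point detection and the 25 pulse morphology/timing features.

Landmarks per cardiac cycle: ECG R-peak, PPG foot (diastolic trough that
begins the pulse), maximum-slope point of the systolic rise, systolic
peak, falling-edge inflection closest to the diastolic wave, and the next
foot.  Features are computed per cycle and aggregated per segment by the
median (robust to a single bad beat).

The MEU (blood viscosity) feature has no published formula; the default
surrogate is ps/pm (pulse max over mean pulse height) and is configurable
via ``meu_surrogate``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import NoCyclesError
from .types import FEATURE_NAMES, FeatureTable, PulseFiducials, Segment

__all__ = [
    "detect_r_peaks",
    "detect_ppg_fiducials",
    "compute_features",
    "reference_bp",
    "extract_segment_features",
    "build_feature_table",
]


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.3) -> np.ndarray:
    """Locate ECG R-peaks; strictly increasing, refractory period enforced."""
    from scipy.signal import find_peaks

    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 3 or np.ptp(ecg) <= 0:
        raise NoCyclesError("flat or empty ECG: no cycles")
    height = ecg.min() + 0.5 * np.ptp(ecg)
    peaks, _ = find_peaks(ecg, height=height, distance=max(int(refractory_s * fs), 1))
    if len(peaks) == 0:
        raise NoCyclesError("no R-peaks found")
    return peaks.astype(int)


def _inflection_on_falling_edge(d1: np.ndarray, peak: int,
                                next_foot: int) -> int | None:
    """Falling-edge inflection adjacent to the diastolic wave.

    Realized as the argmax of the 1st derivative on (peak, next_foot): the
    point where the decay is slowest (or the secondary rise fastest).  At
    an interior maximum of d1 the 2nd derivative crosses zero, so this is
    the stable member of the zero-crossing family nearest the diastolic
    peak.
    """
    # The diastolic wave sits mid-edge; the flat tail just before the next
    # foot (where d1 also approaches zero) is excluded from the search.
    lo = peak + 1
    hi = peak + max(int(0.6 * (next_foot - peak)), 2)
    if hi <= lo + 1:
        return None
    cand = lo + int(np.argmax(d1[lo:hi]))
    if peak < cand < next_foot:
        return cand
    return None


def detect_ppg_fiducials(ppg: np.ndarray, fs: float,
                         r_peaks: Sequence[int]) -> list[PulseFiducials]:
    """Per-cycle PPG landmarks anchored on the ECG R-peaks.

    Cycles whose landmarks cannot be resolved (or violate the ordering
    invariant) are dropped, never fabricated.
    """
    ppg = np.asarray(ppg, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise NoCyclesError("need at least two R-peaks to bound one cycle")
    # Derivatives from a lightly smoothed copy; the 2nd derivative is far
    # too noise-sensitive for zero-crossing detection otherwise.
    win = min(max(int(0.06 * fs) | 1, 5), max(len(ppg) - 1, 5))
    if len(ppg) > win >= 5:
        from scipy.signal import savgol_filter
        smooth = savgol_filter(ppg, win, polyorder=3)
    else:
        smooth = ppg
    d1 = np.gradient(smooth) * fs
    d2 = np.gradient(d1) * fs
    n = len(ppg)

    out: list[PulseFiducials] = []
    for k in range(len(r_peaks) - 1):
        r0, r1 = int(r_peaks[k]), int(r_peaks[k + 1])
        if r1 >= n:
            break
        win = ppg[r0:r1]
        if len(win) < 8 or np.ptp(win) <= 0:
            continue
        peak = r0 + int(np.argmax(win))
        if peak <= r0 + 1:
            continue
        foot = r0 + int(np.argmin(ppg[r0:peak]))
        if peak - foot < 3:
            continue
        slope = foot + int(np.argmax(d1[foot:peak]))
        # Next foot: minimum between this systolic peak and the following
        # cycle's systolic region.
        r2 = int(r_peaks[k + 2]) if k + 2 < len(r_peaks) else min(n - 1, 2 * r1 - r0)
        nxt_hi = min(r2, n - 1)
        search = ppg[r1:nxt_hi] if nxt_hi > r1 else ppg[peak + 1:nxt_hi]
        if nxt_hi > r1 + 2:
            nxt_peak = r1 + int(np.argmax(ppg[r1:nxt_hi]))
        else:
            nxt_peak = n - 1
        if nxt_peak <= peak + 2:
            continue
        next_foot = peak + 1 + int(np.argmin(ppg[peak + 1:nxt_peak]))
        if next_foot - peak < 3:
            continue
        infl = _inflection_on_falling_edge(d1, peak, next_foot)
        if infl is None:
            continue
        try:
            out.append(PulseFiducials(r_peak=r0, ppg_foot=foot, max_slope=slope,
                                      systolic_peak=peak, inflection=infl,
                                      next_foot=next_foot))
        except ValueError:
            continue
    return out


def _main_peak_width(x: np.ndarray, lo: int, hi: int, fs: float) -> float:
    """Half-prominence width (s) of the tallest interior local peak of x[lo:hi)."""
    from scipy.signal import find_peaks, peak_widths

    seg = np.asarray(x[lo:hi], dtype=float)
    if len(seg) < 3:
        return np.nan
    peaks, _ = find_peaks(seg)
    if len(peaks) == 0:
        return np.nan
    best = peaks[int(np.argmax(seg[peaks]))]
    width = peak_widths(seg, [best], rel_height=0.5)[0][0]
    return float(width) / fs


def _safe_div(a: float, b: float) -> float:
    if b == 0 or not np.isfinite(b) or not np.isfinite(a):
        return np.nan
    return a / b


def compute_features(fid: PulseFiducials, ppg: np.ndarray, fs: float,
                     rr_s: float,
                     meu_surrogate: Callable[[float, float, float], float] | None = None,
                     ) -> dict[str, float]:
    """All 25 features for one cycle.

    ``rr_s`` is the R-R interval of the cycle in seconds; ``meu_surrogate``
    maps (ps, pd, pm) to the MEU value (default ps/pm).
    """
    ppg = np.asarray(ppg, dtype=float)
    f, ms, pk, ip, nf, r = (fid.ppg_foot, fid.max_slope, fid.systolic_peak,
                            fid.inflection, fid.next_foot, fid.r_peak)
    d1 = np.gradient(ppg) * fs
    d2 = np.gradient(d1) * fs

    st = (pk - f) / fs
    dt = (nf - pk) / fs
    feats: dict[str, float] = {}
    feats["ST"] = st
    feats["DT"] = dt
    feats["PIR"] = _safe_div(ppg[pk], ppg[f])
    feats["HR"] = _safe_div(1.0, rr_s)
    feats["PAT1"] = (pk - r) / fs
    feats["PAT2"] = (ms - r) / fs
    feats["PAT3"] = (nf - r) / fs
    feats["LASI"] = _safe_div(1.0, (ip - pk) / fs)
    feats["AI"] = _safe_div(ppg[pk], ppg[ip])

    t = np.arange(len(ppg)) / fs
    s1 = np.trapezoid(ppg[f:ms + 1], t[f:ms + 1])
    s2 = np.trapezoid(ppg[ms:pk + 1], t[ms:pk + 1])
    s3 = np.trapezoid(ppg[pk:ip + 1], t[pk:ip + 1])
    s4 = np.trapezoid(ppg[ip:nf + 1], t[ip:nf + 1])
    feats["S1"], feats["S2"], feats["S3"], feats["S4"] = s1, s2, s3, s4
    feats["IPAR"] = _safe_div(s4, s1 + s2 + s3)

    pulse = ppg[f:nf + 1]
    ps, pd_ = float(pulse.max()), float(pulse.min())
    dur = (nf - f) / fs
    pm = _safe_div(float(np.trapezoid(pulse, t[f:nf + 1])), dur)
    feats["PPGk"] = _safe_div(pm - pd_, ps - pd_)

    # 1st/2nd derivative characteristics within the pulse.
    feats["dppgH"] = float(d1[f:nf].max())
    feats["dppgW"] = _main_peak_width(d1, f, nf, fs)
    feats["ddppgPH"] = float(d2[f:nf].max())
    feats["ddppgTH"] = float(d2[f:nf].min())
    feats["ddppgH"] = feats["ddppgPH"] - feats["ddppgTH"]
    feats["ddppgW"] = _main_peak_width(d2, f, nf, fs)

    feats["MXAP"] = ps
    feats["MIAP"] = pd_
    if meu_surrogate is None:
        feats["MEU"] = _safe_div(ps, pm)
    else:
        feats["MEU"] = float(meu_surrogate(ps, pd_, pm))
    feats["FHR"] = feats["HR"]  # heart rate expressed as a frequency in Hz
    return feats


def reference_bp(abp: np.ndarray, fiducials: Sequence[PulseFiducials]
                 ) -> tuple[float, float]:
    """Segment SBP/DBP: means of per-cycle ABP maxima and minima."""
    abp = np.asarray(abp, dtype=float)
    if len(fiducials) == 0:
        raise NoCyclesError("no cycles for reference BP")
    maxima = [float(abp[f.ppg_foot:f.next_foot].max()) for f in fiducials]
    minima = [float(abp[f.ppg_foot:f.next_foot].min()) for f in fiducials]
    return float(np.mean(maxima)), float(np.mean(minima))


def extract_segment_features(segment: Segment,
                             meu_surrogate=None) -> dict[str, float] | None:
    """Feature row (25 features + SBP/DBP) for one segment; None if unusable."""
    try:
        r_peaks = detect_r_peaks(segment.ecg, segment.fs)
        fids = detect_ppg_fiducials(segment.ppg, segment.fs, r_peaks)
    except NoCyclesError:
        return None
    if not fids:
        return None
    rr = np.diff(r_peaks) / segment.fs
    rr_by_r = {int(r): float(d) for r, d in zip(r_peaks[:-1], rr)}
    rows = []
    for fid in fids:
        rr_s = rr_by_r.get(fid.r_peak, float(np.median(rr)) if len(rr) else np.nan)
        rows.append(compute_features(fid, segment.ppg, segment.fs, rr_s,
                                     meu_surrogate=meu_surrogate))
    agg = {name: float(np.nanmedian([r[name] for r in rows])) for name in FEATURE_NAMES}
    try:
        sbp, dbp = reference_bp(segment.abp, fids)
    except NoCyclesError:
        return None
    agg["SBP"] = sbp
    agg["DBP"] = dbp
    return agg


def build_feature_table(segments: Sequence[Segment],
                        meu_surrogate=None,
                        include_meu: bool = True) -> FeatureTable:
    """Assemble the per-segment feature table; NaN rows are dropped."""
    records = []
    for i, seg in enumerate(segments):
        row = extract_segment_features(seg, meu_surrogate=meu_surrogate)
        if row is None:
            continue
        row["subject_id"] = seg.parent
        row["segment_index"] = i
        records.append(row)
    if not records:
        raise NoCyclesError("no segment yielded a feature row")
    frame = pd.DataFrame.from_records(records)
    names = [n for n in FEATURE_NAMES if include_meu or n != "MEU"]
    if not include_meu:
        frame = frame.drop(columns=["MEU"])
    cols = names + ["SBP", "DBP", "subject_id", "segment_index"]
    return FeatureTable(frame[cols], names).dropna()
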