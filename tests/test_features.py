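import numpy as np
import pytest

from cghofd import (
    FEATURE_NAMES,
    PulseFiducials,
    Segment,
    SynthWaveformConfig,
    compute_features,
    detect_ppg_fiducials,
    detect_r_peaks,
    generate_waveforms,
    reference_bp,
)
from cghofd.errors import NoCyclesError
from cghofd.features import build_feature_table, extract_segment_features


def _match_truth(fids, truth):
    tf = {f.r_peak: f for f in truth.fiducials}
    for f in fids:
        key = min(tf, key=lambda k: abs(k - f.r_peak))
        yield f, tf[key]


class TestDetectRPeaks:
    def test_within_two_samples_of_truth(self, noisy_waveforms):
        rec, truth = noisy_waveforms
        detected = detect_r_peaks(rec.ecg, rec.fs)
        true_r = np.array([f.r_peak for f in truth.fiducials])
        for r in true_r:
            assert np.abs(detected - r).min() <= 2

    def test_flatline_raises(self):
        with pytest.raises(NoCyclesError):
            detect_r_peaks(np.zeros(1000), 125.0)

    def test_peak_count_matches_heart_rate(self):
        rec, _ = generate_waveforms(SynthWaveformConfig(
            duration_s=20, heart_rate_bpm=60, noise_sd=0.0, seed=0))
        n = len(detect_r_peaks(rec.ecg, rec.fs))
        assert 19 <= n <= 21

    def test_strictly_increasing(self, noisy_waveforms):
        rec, _ = noisy_waveforms
        peaks = detect_r_peaks(rec.ecg, rec.fs)
        assert np.all(np.diff(peaks) > 0)


class TestDetectPpgFiducials:
    def test_landmarks_within_three_samples_of_truth(self, noisy_waveforms):
        rec, truth = noisy_waveforms
        r = detect_r_peaks(rec.ecg, rec.fs)
        fids = detect_ppg_fiducials(rec.ppg, rec.fs, r)
        assert len(fids) >= len(truth.fiducials) - 2
        for f, t in _match_truth(fids, truth):
            assert abs(f.ppg_foot - t.ppg_foot) <= 3
            assert abs(f.max_slope - t.max_slope) <= 3
            assert abs(f.systolic_peak - t.systolic_peak) <= 3
            assert abs(f.inflection - t.inflection) <= 3
            assert abs(f.next_foot - t.next_foot) <= 3

    def test_monotone_ppg_yields_no_cycles(self):
        ppg = np.linspace(0, 1, 500)
        fids = detect_ppg_fiducials(ppg, 125.0, [50, 200, 350])
        assert fids == []

    def test_ordering_invariant_on_every_cycle(self, noisy_waveforms):
        rec, _ = noisy_waveforms
        r = detect_r_peaks(rec.ecg, rec.fs)
        for f in detect_ppg_fiducials(rec.ppg, rec.fs, r):
            assert f.ppg_foot < f.max_slope < f.systolic_peak < f.inflection \
                < f.next_foot

    def test_requires_two_rpeaks(self):
        with pytest.raises(NoCyclesError):
            detect_ppg_fiducials(np.random.default_rng(0).random(100), 125.0, [10])


class TestComputeFeatures:
    def _pulse(self):
        """Simple synthetic pulse with hand-placed fiducials."""
        fs = 125.0
        n = 150
        ppg = np.full(n, 0.2)
        ppg[20:101] = 0.2 + np.sin(np.linspace(0, np.pi, 81))
        fid = PulseFiducials(r_peak=10, ppg_foot=20, max_slope=40,
                             systolic_peak=60, inflection=80, next_foot=100)
        return fid, ppg, fs

    def test_timing_features_exact(self):
        fid, ppg, fs = self._pulse()
        f = compute_features(fid, ppg, fs, rr_s=0.8)
        assert f["ST"] == pytest.approx((60 - 20) / fs)
        assert f["DT"] == pytest.approx((100 - 60) / fs)
        assert f["PAT1"] == pytest.approx((60 - 10) / fs)
        assert f["PAT2"] == pytest.approx((40 - 10) / fs)
        assert f["PAT3"] == pytest.approx((100 - 10) / fs)
        assert f["HR"] == pytest.approx(1 / 0.8)
        assert f["FHR"] == pytest.approx(f["HR"])

    def test_ipar_is_area_ratio(self):
        fid, ppg, fs = self._pulse()
        f = compute_features(fid, ppg, fs, rr_s=0.8)
        assert f["IPAR"] == pytest.approx(f["S4"] / (f["S1"] + f["S2"] + f["S3"]))

    def test_ppgk_limits(self):
        # pm == pd -> 0; pm == ps -> 1 (exercised via the formula directly).
        fid, ppg, fs = self._pulse()
        f = compute_features(fid, ppg, fs, rr_s=0.8)
        assert 0.0 <= f["PPGk"] <= 1.0

    def test_pat1_matches_truth_on_synthetic(self, clean_waveforms):
        rec, truth = clean_waveforms
        for fid in truth.fiducials[:5]:
            f = compute_features(fid, rec.ppg, rec.fs, rr_s=0.8)
            assert f["PAT1"] == pytest.approx(
                (fid.systolic_peak - fid.r_peak) / rec.fs)

    def test_pir_and_ai_at_least_one(self, clean_waveforms):
        rec, truth = clean_waveforms
        for fid in truth.fiducials:
            f = compute_features(fid, rec.ppg, rec.fs, rr_s=0.8)
            assert f["PIR"] >= 1.0
            assert f["AI"] >= 1.0

    def test_division_by_zero_flagged_nan(self):
        fid, ppg, fs = self._pulse()
        ppg = ppg - ppg[fid.ppg_foot]  # foot amplitude exactly zero
        f = compute_features(fid, ppg, fs, rr_s=0.8)
        assert np.isnan(f["PIR"])

    def test_meu_surrogate_pluggable(self):
        fid, ppg, fs = self._pulse()
        f = compute_features(fid, ppg, fs, rr_s=0.8,
                             meu_surrogate=lambda ps, pd, pm: 42.0)
        assert f["MEU"] == 42.0


class TestReferenceBp:
    def test_noise_free_extrema(self, clean_waveforms):
        rec, truth = clean_waveforms
        sbp, dbp = reference_bp(rec.abp, truth.fiducials)
        assert sbp == pytest.approx(120.0, abs=0.01)
        assert dbp == pytest.approx(70.0, abs=0.01)

    def test_single_cycle_equals_extremum(self, clean_waveforms):
        rec, truth = clean_waveforms
        f = truth.fiducials[2]
        sbp, dbp = reference_bp(rec.abp, [f])
        assert sbp == rec.abp[f.ppg_foot:f.next_foot].max()
        assert dbp == rec.abp[f.ppg_foot:f.next_foot].min()

    def test_mean_of_cycle_maxima(self):
        # Oracle: mean of {118,120,122,119,121} = 120.
        fs = 10.0
        abp = np.zeros(110)
        fids = []
        for i, peak in enumerate([118, 120, 122, 119, 121]):
            base = i * 20
            abp[base:base + 20] = 70.0
            abp[base + 10] = peak
            fids.append(PulseFiducials(r_peak=base + 1, ppg_foot=base + 2,
                                       max_slope=base + 5, systolic_peak=base + 10,
                                       inflection=base + 14, next_foot=base + 20))
        sbp, _ = reference_bp(abp, fids)
        assert sbp == pytest.approx(120.0)

    def test_no_cycles_raises(self):
        with pytest.raises(NoCyclesError):
            reference_bp(np.ones(100), [])


class TestTableAssembly:
    def test_segment_row_complete(self, noisy_waveforms):
        rec, _ = noisy_waveforms
        seg = Segment("s", 0, rec.ecg, rec.ppg, rec.abp, rec.fs)
        row = extract_segment_features(seg)
        assert row is not None
        for name in FEATURE_NAMES:
            assert np.isfinite(row[name]), name

    def test_feature_values_stable_against_truth_fiducials(self, clean_waveforms):
        # Features from detected fiducials match features from ground-truth
        # fiducials on the noise-free record.
        rec, truth = clean_waveforms
        r = detect_r_peaks(rec.ecg, rec.fs)
        fids = detect_ppg_fiducials(rec.ppg, rec.fs, r)
        for f, t in _match_truth(fids, truth):
            a = compute_features(f, rec.ppg, rec.fs, rr_s=0.8)
            b = compute_features(t, rec.ppg, rec.fs, rr_s=0.8)
            for name in ("ST", "DT", "PAT1", "LASI", "AI", "IPAR", "PPGk"):
                assert a[name] == pytest.approx(b[name], rel=0.05), name

    def test_increasing_sbp_decreases_pat1(self):
        pats = []
        for sbp in (100.0, 130.0, 160.0):
            rec, _ = generate_waveforms(SynthWaveformConfig(
                duration_s=20, sbp_mmHg=sbp, dbp_mmHg=70.0, noise_sd=0.0, seed=4))
            seg = Segment("s", 0, rec.ecg, rec.ppg, rec.abp, rec.fs)
            pats.append(extract_segment_features(seg)["PAT1"])
        assert pats[0] > pats[1] > pats[2]

    def test_build_feature_table(self, noisy_waveforms):
        rec, _ = noisy_waveforms
        half = rec.n_samples // 2
        segs = [Segment("s", 0, rec.ecg[:half], rec.ppg[:half], rec.abp[:half], rec.fs),
                Segment("s", half, rec.ecg[half:], rec.ppg[half:], rec.abp[half:], rec.fs)]
        table = build_feature_table(segs)
        assert len(table) == 2
        assert table.feature_names == list(FEATURE_NAMES)
        assert not table.frame[list(FEATURE_NAMES)].isna().any().any()

    def test_exclude_meu(self, noisy_waveforms):
        rec, _ = noisy_waveforms
        segs = [Segment("s", 0, rec.ecg, rec.ppg, rec.abp, rec.fs)]
        table = build_feature_table(segs, include_meu=False)
        assert "MEU" not in table.feature_names
        assert len(table.feature_names) == 24
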