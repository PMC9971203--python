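"""MCC, peak annotation, DNP, DPA and the correlation matrix."""

from __future__ import annotations

import numpy as np
import pytest

import pulsescreen as ps
from pulsescreen.features import last_strong_negative_peak

from conftest import mcc_reference


def make_cycle(samples: np.ndarray, fs: float = 1000.0) -> ps.AveragedCycle:
    """Wrap a raw waveform as a normalized AveragedCycle."""
    s = samples - samples.mean()
    s = s / s.max()
    pos = int(np.argmax(s))
    neg = last_strong_negative_peak(s, pos)
    return ps.AveragedCycle(samples=s, fs=fs, pos_peak_index=pos,
                            last_neg_peak_index=neg)


def lobe_cycle(n=700, ripple_pairs=0, ripple_amp=0.05, tail_amp=0.25, fs=1000.0):
    """One positive lobe, a flat gap, then one negative lobe.

    ``ripple_pairs`` injects that many (maximum, minimum) extremum pairs into
    the flat gap as alternating narrow Gaussian bumps; on the flat background
    each bump contributes exactly one extremum of prominence ~ripple_amp, so
    the small-peak count between A and B is 2 * ripple_pairs by construction.
    ``tail_amp`` adds a positive bump after the negative lobe (the post-notch
    peak).
    """
    t = np.arange(n) / fs
    s = np.exp(-((t - 0.10) ** 2) / (2 * 0.02**2))
    s -= 0.8 * np.exp(-((t - 0.38) ** 2) / (2 * 0.03**2))
    if tail_amp:
        s += tail_amp * np.exp(-((t - 0.52) ** 2) / (2 * 0.02**2))
    centers = [0.18, 0.22, 0.26, 0.30]
    for k in range(2 * ripple_pairs):
        sign = 1.0 if k % 2 == 0 else -1.0
        s += sign * ripple_amp * np.exp(-((t - centers[k]) ** 2) / (2 * 0.008**2))
    return s


class TestMCC:
    def test_self_correlation_is_one(self):
        w = make_cycle(lobe_cycle())
        assert ps.mcc(w, w) == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance_of_maximum(self):
        base = lobe_cycle()
        shifted = np.roll(base, 30)
        # circular roll of a compactly-supported cycle = pure delay
        assert ps.mcc(make_cycle(base), make_cycle(shifted)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_oracle_on_fixed_pair(self):
        rng = np.random.default_rng(2024)
        a, b = rng.normal(size=64), rng.normal(size=64)
        fast = ps.mcc(a, b)
        slow = mcc_reference(a, b)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_matches_pure_python_double_loop(self):
        """Tiny case against a literal double loop (no numpy vectorization)."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=32), rng.normal(size=32)
        n, T = 32, 16
        best = -np.inf
        for tau in range(-T, T + 1):
            num = ea = eb = 0.0
            for m in range(n):
                k = m + tau
                if 0 <= k < n:
                    num += a[m] * b[k]
                    ea += a[m] ** 2
                    eb += b[k] ** 2
            if ea > 0 and eb > 0:
                best = max(best, num / np.sqrt(ea * eb))
        assert ps.mcc(a, b) == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("n", [64, 100, 256])
    def test_oracle_equivalence_random_lengths(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert ps.mcc(a, b) == pytest.approx(mcc_reference(a, b), abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.normal(size=100), rng.normal(size=100)
            v = ps.mcc(a, b)
            assert -1.0 <= v <= 1.0
            assert v == pytest.approx(ps.mcc(b, a), abs=1e-9)

    def test_unnormalized_form_matches_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=80), rng.normal(size=80)
        fast = ps.mcc(a, b, normalized=False)
        slow = mcc_reference(a, b, normalized=False)
        assert fast == pytest.approx(slow, abs=1e-9)
        # the raw lagged inner product scales with signal energy
        assert ps.mcc(2 * a, 2 * b, normalized=False) == pytest.approx(4 * fast, rel=1e-9)

    def test_constant_input_rejected(self):
        w = make_cycle(lobe_cycle())
        with pytest.raises(ps.UndefinedCorrelationError):
            ps.mcc(w.samples, np.ones(w.samples.size))

    def test_unequal_lengths_truncated(self):
        a = lobe_cycle(n=600)
        b = lobe_cycle(n=650)
        assert ps.mcc(a, b) == pytest.approx(mcc_reference(a, b), abs=1e-9)


class TestAnnotatePeaks:
    def test_clean_two_lobe_cycle(self):
        w = make_cycle(lobe_cycle(tail_amp=0.0))
        ann = ps.annotate_peaks(w)
        assert ann.n_small_peaks == 0
        assert ann.A_index == np.argmax(w.samples)
        assert ann.B_index == np.argmin(w.samples)

    def test_injected_ripples_counted_as_extrema_pairs(self):
        # 2 extremum pairs inject 2 maxima + 2 minima between A and B
        w = make_cycle(lobe_cycle(ripple_pairs=2, ripple_amp=0.05, tail_amp=0.0))
        ann = ps.annotate_peaks(w)
        assert ann.n_small_peaks == 4
        assert all(ann.A_index < i < ann.B_index for i in ann.small_peaks)

    def test_prominence_floor_suppresses_tiny_ripples(self):
        w = make_cycle(lobe_cycle(ripple_pairs=2, ripple_amp=0.002, tail_amp=0.0))
        ann = ps.annotate_peaks(w)
        assert ann.n_small_peaks == 0

    def test_post_notch_peak_amplitude(self):
        w = make_cycle(lobe_cycle(tail_amp=0.3))
        ann = ps.annotate_peaks(w)
        assert ann.post_notch_peak_index > ann.B_index
        # tail bump dominates the post-notch region
        assert ann.post_notch_amplitude == pytest.approx(
            w.samples[ann.post_notch_peak_index])
        assert ann.post_notch_amplitude > 0.1

    def test_monotone_tail_falls_back_to_last_sample(self):
        n = 700
        t = np.arange(n) / 1000.0
        s = np.exp(-((t - 0.10) ** 2) / (2 * 0.02**2))
        s -= 0.8 * np.exp(-((t - 0.38) ** 2) / (2 * 0.03**2))
        s += np.where(t > 0.45, 0.5 * (t - 0.45), 0.0)  # monotone rising tail
        w = make_cycle(s)
        ann = ps.annotate_peaks(w)
        assert ann.post_notch_peak_index == n - 1
        assert ann.post_notch_amplitude == pytest.approx(w.samples[-1])

    def test_no_strong_negative_peak_rejected(self):
        n = 400
        t = np.arange(n) / 1000.0
        s = np.exp(-((t - 0.2) ** 2) / (2 * 0.05**2))  # positive lobe only
        s0 = s - s.mean()
        s0 = s0 / s0.max()
        with pytest.raises(ps.AnnotationError):
            last_strong_negative_peak(s0, int(np.argmax(s0)))


class TestDnpDpa:
    def test_identical_sides_are_zero(self):
        w = make_cycle(lobe_cycle(ripple_pairs=1))
        ann = ps.annotate_peaks(w)
        assert ps.dnp(ann, ann) == 0
        assert ps.dpa(ann, ann) == 0.0

    def test_count_difference(self):
        a = ps.annotate_peaks(make_cycle(lobe_cycle(ripple_pairs=2, tail_amp=0.0)))
        b = ps.annotate_peaks(make_cycle(lobe_cycle(tail_amp=0.0)))
        assert a.n_small_peaks == 4
        assert ps.dnp(a, b) == 4
        assert ps.dnp(a, b) == ps.dnp(b, a)

    def test_amplitude_difference_from_constructed_fixture(self):
        a = ps.annotate_peaks(make_cycle(lobe_cycle(tail_amp=0.30)))
        b = ps.annotate_peaks(make_cycle(lobe_cycle(tail_amp=0.18)))
        expected = abs(a.post_notch_amplitude - b.post_notch_amplitude)
        assert ps.dpa(a, b) == pytest.approx(expected, abs=1e-12)
        assert ps.dpa(a, b) == ps.dpa(b, a)
        assert ps.dpa(a, b) > 0


class TestExtractFeatures:
    def test_identical_sides(self):
        w = make_cycle(lobe_cycle())
        fv = ps.extract_features(w, w)
        assert fv.x1 == pytest.approx(1.0, abs=1e-12)
        assert fv.x2 == 0
        assert fv.x3 == pytest.approx(0.0, abs=1e-12)

    def test_left_right_exchange_invariance(self, occluded_recording):
        left, right = ps.preprocess_recording(occluded_recording)
        f1 = ps.extract_features(left, right)
        f2 = ps.extract_features(right, left)
        assert f1.x1 == pytest.approx(f2.x1, abs=1e-9)
        assert f1.x2 == f2.x2
        assert f1.x3 == pytest.approx(f2.x3, abs=1e-12)

    def test_occluded_pair_shows_asymmetry(self, occluded_recording):
        fv = ps.extract_features_from_recording(occluded_recording)
        assert fv.x1 < 1.0
        assert fv.x2 >= 1
        assert fv.x3 > 0

    def test_group_means_ordering_on_large_cohorts(self):
        """Patients have lower MCC and higher DNP on average by construction."""
        rng = np.random.default_rng(77)
        cfg = ps.CohortSimConfig(n_cycles=8)
        healthy, patient = [], []
        for i in range(25):
            p = ps.SubjectSimParams(
                noise_sd=cfg.noise_sd, rr_jitter_sd=cfg.rr_jitter_sd,
                lr_asym_sd=cfg.lr_asym_sd, dicrotic_asym_sd=cfg.dicrotic_asym_sd,
                n_cycles=8, seed=int(rng.integers(2**31)))
            healthy.append(ps.extract_features_from_recording(ps.simulate_recording(p)))
            q = ps.SubjectSimParams(
                occluded_side="L", reflection_coeff=0.3, reflection_delay=0.06,
                ripple_count=int(rng.integers(0, 4)), post_notch_boost=0.1,
                noise_sd=cfg.noise_sd, rr_jitter_sd=cfg.rr_jitter_sd,
                lr_asym_sd=cfg.lr_asym_sd, dicrotic_asym_sd=cfg.dicrotic_asym_sd,
                n_cycles=8, seed=int(rng.integers(2**31)))
            patient.append(ps.extract_features_from_recording(ps.simulate_recording(q)))
        mcc_h = np.mean([f.x1 for f in healthy])
        mcc_p = np.mean([f.x1 for f in patient])
        dnp_h = np.mean([f.x2 for f in healthy])
        dnp_p = np.mean([f.x2 for f in patient])
        assert mcc_p < mcc_h
        assert dnp_p > dnp_h


class TestFeatureLabelCorrelations:
    def _features(self, X):
        return [ps.FeatureVector(x1=r[0], x2=int(r[1]), x3=r[2]) for r in X]

    def test_hand_computed_six_subject_table(self):
        X = np.array([
            [0.95, 0, 0.02],
            [0.90, 1, 0.05],
            [0.85, 2, 0.10],
            [0.80, 3, 0.04],
            [0.99, 0, 0.01],
            [0.70, 4, 0.12],
        ])
        labels = ["Negative", "Negative", "Positive", "Positive", "Negative", "Positive"]
        corr = ps.feature_label_correlations(self._features(X), labels)
        y = np.array([0, 0, 1, 1, 0, 1], float)

        def pearson(u, v):
            u, v = u - u.mean(), v - v.mean()
            return float(np.sum(u * v) / np.sqrt(np.sum(u**2) * np.sum(v**2)))

        cols = {"MCC": X[:, 0], "DNP": X[:, 1], "DPA": X[:, 2], "C": y}
        for a in cols:
            for b in cols:
                assert corr.loc[a, b] == pytest.approx(pearson(cols[a], cols[b]), abs=1e-9)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_duplicated_feature_correlates_perfectly(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=8), rng.integers(0, 5, 8), rng.normal(size=8)])
        X[:, 0] = np.clip(X[:, 0], -1, 1)
        X[:, 2] = np.abs(X[:, 2])
        feats = self._features(X)
        labels = ["Positive" if x > 2 else "Negative" for x in X[:, 1]]
        corr = ps.feature_label_correlations(feats, labels)
        assert corr.loc["DNP", "DNP"] == pytest.approx(1.0)

    def test_identical_labels_rejected(self):
        X = np.array([[0.9, 1, 0.1], [0.8, 2, 0.2], [0.7, 3, 0.3]])
        with pytest.raises(ValueError, match="identical"):
            ps.feature_label_correlations(self._features(X), ["Positive"] * 3)

    def test_zero_variance_feature_reported_as_nan(self):
        X = np.array([[0.9, 1, 0.0], [0.8, 2, 0.0], [0.7, 3, 0.0], [0.6, 0, 0.0]])
        labels = ["Negative", "Positive", "Positive", "Negative"]
        corr = ps.feature_label_correlations(self._features(X), labels)
        assert np.isnan(corr.loc["DPA", "C"])
        assert corr.loc["MCC", "DNP"] == pytest.approx(
            np.corrcoef(X[:, 0], X[:, 1])[0, 1])
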