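"""Shared fixtures: synthetic recordings and cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pulsescreen as ps


def mcc_reference(a, b, max_shift_frac=0.5, normalized=True):
    """Exhaustive per-lag cross-correlation oracle (no FFT).

    Evaluates every lag independently with direct sums over the overlapping
    support — the definition itself, used to cross-check the FFT-based
    implementation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    T = int(np.floor(max_shift_frac * n))
    best = -np.inf
    for tau in range(-T, T + 1):
        if tau >= 0:
            aa, bb = a[: n - tau], b[tau:]
        else:
            aa, bb = a[-tau:], b[: n + tau]
        num = float(np.dot(aa, bb))
        if normalized:
            ea, eb = float(np.dot(aa, aa)), float(np.dot(bb, bb))
            if ea == 0 or eb == 0:
                continue
            val = num / np.sqrt(ea * eb)
        else:
            val = num / n
        best = max(best, val)
    return best


@pytest.fixture(scope="session")
def healthy_recording() -> ps.RawRecording:
    return ps.simulate_recording(ps.SubjectSimParams(seed=11))


@pytest.fixture(scope="session")
def occluded_recording() -> ps.RawRecording:
    params = ps.SubjectSimParams(
        seed=12,
        occluded_side="R",
        reflection_coeff=0.35,
        reflection_delay=0.05,
        ripple_count=2,
        post_notch_boost=0.12,
    )
    return ps.simulate_recording(params)


@pytest.fixture(scope="session")
def default_cohort() -> ps.CohortTable:
    """Default 30+23 synthetic cohort with features from the full pipeline."""
    recordings, cohort = ps.generate_cohort(base_seed=42)
    for rec in recordings:
        cohort.features[rec.meta.subject_id] = ps.extract_features_from_recording(rec)
    return cohort
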