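"""The three dynamic features of bilateral pulse-wave asymmetry.

All three features quantify left/right differences of the averaged
differential pulse cycle, on the physical premise that a unilateral occlusion
adds reflected-wave energy to one side only:

* **MCC** (x1) — maximum of the left/right cross-correlation function over a
  symmetric lag range; a whole-waveform similarity in [-1, 1].
* **DNP** (x2) — absolute left/right difference in the number of small
  positive and negative peaks between the main positive peak (A) and the
  last strong negative peak (B); counts reflection-induced ripples.
* **DPA** (x3) — absolute left/right difference of the amplitude of the
  positive peak following B (the peak after the dicrotic notch); reflects
  end-diastolic flow asymmetry.

Healthy subjects have nearly symmetric sides, so x ≈ [1, 0, 0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import correlate, find_peaks

from .core_types import AnnotationError, AveragedCycle, FeatureVector, PulseScreenError

__all__ = [
    "FeatureConfig",
    "UndefinedCorrelationError",
    "PeakAnnotation",
    "mcc",
    "last_strong_negative_peak",
    "annotate_peaks",
    "dnp",
    "dpa",
    "extract_features",
    "feature_label_correlations",
]


class UndefinedCorrelationError(PulseScreenError):
    """Cross-correlation is undefined for a constant signal."""


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    max_shift_frac — half-width of the MCC lag search as a fraction of the
    cycle length (default ±N/2); small_peak_prominence — minimum prominence
    (in units of the normalized amplitude) for an extremum between A and B to
    count as a small peak; neg_peak_floor — |amplitude| a local minimum must
    reach to qualify as the strong negative peak B; normalized — use the
    correlation *coefficient* for MCC (default) rather than the raw lagged
    inner product.
    """

    max_shift_frac: float = 0.5
    small_peak_prominence: float = 0.01
    neg_peak_floor: float = 0.2
    normalized: bool = True


@dataclass
class PeakAnnotation:
    """Landmarks of one averaged cycle used by DNP and DPA.

    A_index: main positive peak; B_index: last strong negative peak (the
    deflection preceding the dicrotic notch); small_peaks: qualifying local
    maxima and minima strictly between A and B; post_notch_peak_index /
    post_notch_amplitude: the selected positive peak at or after B.
    """

    A_index: int
    B_index: int
    small_peaks: np.ndarray
    post_notch_peak_index: int
    post_notch_amplitude: float

    @property
    def n_small_peaks(self) -> int:
        return int(len(self.small_peaks))


def _as_samples(w: AveragedCycle | np.ndarray) -> np.ndarray:
    if isinstance(w, AveragedCycle):
        return w.samples
    return np.asarray(w, dtype=float)


# --------------------------------------------------------------------------
# MCC — maximum of the cross-correlation function (x1)
# --------------------------------------------------------------------------


def mcc(
    l: AveragedCycle | np.ndarray,
    r: AveragedCycle | np.ndarray,
    max_shift_frac: float = 0.5,
    normalized: bool = True,
) -> float:
    """Maximum cross-correlation between the two sides over lags ±max_shift.

    Both signals are truncated to the shorter length N; the lag range is
    ``|tau| <= floor(max_shift_frac * N)``.  With ``normalized=True`` (the
    default) each lag's inner product is divided by the product of the two
    vector norms over the overlapping support, giving a value in [-1, 1]
    with MCC(w, w) = 1.  ``normalized=False`` returns the raw lagged inner
    product scaled by 1/N, which depends on signal energy and is kept only
    for fidelity checks.

    The lag sums are computed with an FFT-based correlation; the per-lag
    norms come from prefix sums of the squared signals.
    """
    a = _as_samples(l)
    b = _as_samples(r)
    n = min(a.size, b.size)
    if n < 2:
        raise UndefinedCorrelationError("signals too short for correlation")
    a, b = a[:n], b[:n]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant signal: correlation undefined")

    max_shift = int(np.floor(max_shift_frac * n))
    # full correlation: num[tau + n - 1] = sum_m b[m + tau] * a[m]
    num = correlate(b, a, mode="full", method="fft")
    taus = np.arange(-max_shift, max_shift + 1)
    vals = num[taus + n - 1]

    if not normalized:
        return float(np.max(vals) / n)

    # per-lag overlap norms from prefix sums of squares
    ca = np.concatenate([[0.0], np.cumsum(a * a)])  # ca[i] = sum a[:i]^2
    cb = np.concatenate([[0.0], np.cumsum(b * b)])
    out = np.empty(taus.size)
    for i, tau in enumerate(taus):
        if tau >= 0:
            # overlap m in [0, n-1-tau]: a[m], b[m+tau]
            ea = ca[n - tau] - ca[0]
            eb = cb[n] - cb[tau]
        else:
            # overlap m in [-tau, n-1]: a[m], b[m+tau]
            ea = ca[n] - ca[-tau]
            eb = cb[n + tau] - cb[0]
        denom = np.sqrt(ea * eb)
        out[i] = vals[i] / denom if denom > 0 else np.nan
    result = float(np.nanmax(out))
    # clip float round-off just past +/-1
    return float(np.clip(result, -1.0, 1.0))


# --------------------------------------------------------------------------
# Peak annotation — landmarks A, B, small peaks, post-notch peak
# --------------------------------------------------------------------------


def last_strong_negative_peak(
    samples: np.ndarray, pos_peak_index: int, neg_peak_floor: float = 0.2
) -> int:
    """Index of B: the last local minimum at or below ``-neg_peak_floor``.

    A plain "last local minimum" would latch onto low-amplitude ripples near
    the cycle end; the amplitude floor restricts B to the strong negative
    deflection that precedes the dicrotic notch.
    """
    minima, _ = find_peaks(-samples)
    minima = minima[(minima > pos_peak_index) & (samples[minima] <= -neg_peak_floor)]
    if minima.size == 0:
        raise AnnotationError(
            f"no negative peak at or below {-neg_peak_floor} after the positive peak"
        )
    return int(minima[-1])


def annotate_peaks(
    w: AveragedCycle, config: FeatureConfig | None = None
) -> PeakAnnotation:
    """Locate the landmarks of one normalized averaged cycle.

    A is the global maximum (amplitude 1 by the normalization contract).
    B is the last local minimum with amplitude <= -neg_peak_floor.  Small
    peaks are sign changes of the first difference strictly between A and B
    — both maxima and minima — whose prominence reaches
    ``small_peak_prominence``; this realizes the zero-derivative peak
    condition robustly on sampled data.  The post-notch peak is the local
    maximum of largest amplitude at index >= B (earliest index on ties);
    when the tail after B has no interior local maximum the tail's global
    maximum is used instead.
    """
    cfg = config or FeatureConfig()
    s = w.samples
    a_idx = int(np.argmax(s))
    b_idx = last_strong_negative_peak(s, a_idx, cfg.neg_peak_floor)

    maxima, _ = find_peaks(s, prominence=cfg.small_peak_prominence)
    minima, _ = find_peaks(-s, prominence=cfg.small_peak_prominence)
    between = lambda idx: idx[(idx > a_idx) & (idx < b_idx)]  # noqa: E731
    small = np.sort(np.concatenate([between(maxima), between(minima)]))

    tail_maxima = maxima[maxima >= b_idx]
    if tail_maxima.size > 0:
        amps = s[tail_maxima]
        best = int(tail_maxima[int(np.argmax(amps))])  # argmax -> earliest on tie
    else:
        tail = s[b_idx:]
        best = b_idx + int(np.argmax(tail))
    return PeakAnnotation(
        A_index=a_idx,
        B_index=b_idx,
        small_peaks=small,
        post_notch_peak_index=best,
        post_notch_amplitude=float(s[best]),
    )


# --------------------------------------------------------------------------
# DNP (x2) and DPA (x3)
# --------------------------------------------------------------------------


def dnp(l_ann: PeakAnnotation, r_ann: PeakAnnotation) -> int:
    """Absolute left/right difference in the small-peak count."""
    return abs(l_ann.n_small_peaks - r_ann.n_small_peaks)


def dpa(l_ann: PeakAnnotation, r_ann: PeakAnnotation) -> float:
    """Absolute left/right difference of the post-notch peak amplitude."""
    return abs(l_ann.post_notch_amplitude - r_ann.post_notch_amplitude)


def extract_features(
    left: AveragedCycle, right: AveragedCycle, config: FeatureConfig | None = None
) -> FeatureVector:
    """Compute x = [MCC, DNP, DPA] for one subject's bilateral cycle pair."""
    cfg = config or FeatureConfig()
    try:
        x1 = mcc(left, right, cfg.max_shift_frac, cfg.normalized)
    except UndefinedCorrelationError as exc:
        raise UndefinedCorrelationError(f"MCC undefined: {exc}") from exc
    anns = {}
    for side, cycle in (("left", left), ("right", right)):
        try:
            anns[side] = annotate_peaks(cycle, cfg)
        except AnnotationError as exc:
            raise AnnotationError(f"[{side}] {exc}") from exc
    return FeatureVector(
        x1=x1, x2=dnp(anns["left"], anns["right"]), x3=dpa(anns["left"], anns["right"])
    )


def extract_features_from_recording(
    rec,
    pre_config=None,
    feat_config: FeatureConfig | None = None,
) -> FeatureVector:
    """Full per-subject pipeline: raw recording -> feature vector."""
    from .preprocess import preprocess_recording  # deferred: avoids import cycle

    left, right = preprocess_recording(rec, pre_config)
    return extract_features(left, right, feat_config)


# --------------------------------------------------------------------------
# Feature/label correlation matrix
# --------------------------------------------------------------------------


def feature_label_correlations(
    features: list[FeatureVector], labels: list[str] | np.ndarray
) -> pd.DataFrame:
    """Pearson correlations among x1, x2, x3 and the occlusion label C.

    The label is encoded 1 for Positive and 0 for Negative, so feature/label
    entries are point-biserial correlations.  A zero-variance feature yields
    NaN in its row/column; identical labels make every label correlation
    undefined and raise a ``ValueError``.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    y = np.array([1.0 if str(lab) == "Positive" else 0.0 for lab in labels])
    if len(features) != y.size:
        raise ValueError("features and labels length mismatch")
    if np.ptp(y) == 0:
        raise ValueError("labels are all identical: label correlations undefined")
    X = np.array([[f.x1, float(f.x2), f.x3] for f in features])
    data = np.column_stack([X, y])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    names = ["MCC", "DNP", "DPA", "C"]
    return pd.DataFrame(corr, index=names, columns=names)
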