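"""Preprocessing: raw bilateral recording -> one averaged cycle per side.

The chain per side is: detect the main positive peak of every cardiac cycle,
segment the raw series into peak-anchored cycles (each starting 0.1 s before
its positive peak), pick the most stable run of ``n_avg`` consecutive cycles,
average them pointwise, remove the DC component of the average, and normalize
so the positive-peak amplitude is 1.  Everything is deterministic and
amplitude-invariant (beat detection uses a relative prominence scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core_types import AveragedCycle, InsufficientCyclesError, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "BeatSet",
    "detect_beats",
    "segment_cycles",
    "average_and_normalize",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    min_rr_s / max_rr_s bound the plausible heart-rate band (24–150 bpm);
    prominence_frac scales the beat-detection threshold relative to the
    signal's robust amplitude (90th percentile of |x - median|); pre_peak_s
    is the segment lead-in before each positive peak; lowpass_hz, when set,
    applies a zero-phase Butterworth smoothing used only to stabilize
    small-peak counting on noisy input (off by default).
    """

    n_avg: int = 5
    min_rr_s: float = 0.4
    max_rr_s: float = 2.5
    prominence_frac: float = 0.5
    pre_peak_s: float = 0.1
    min_cycle_s: float = 0.3
    lowpass_hz: float | None = None


@dataclass
class BeatSet:
    """Detected main positive peaks of successive cardiac cycles."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive peak-to-peak intervals in seconds."""
        return np.diff(self.peak_indices) / self.fs


def _robust_amplitude(signal: np.ndarray) -> float:
    """Unit-free amplitude scale: 90th percentile of |x - median(x)|."""
    return float(np.percentile(np.abs(signal - np.median(signal)), 90))


def detect_beats(signal: np.ndarray, fs: float, config: PreprocessConfig | None = None) -> BeatSet:
    """Find the main positive peak of each cardiac cycle.

    Peaks must be separated by at least ``min_rr_s`` and exceed a prominence
    of ``prominence_frac`` times the signal's robust amplitude, which makes
    detection invariant to rescaling of the raw samples.  Raises
    :class:`InsufficientCyclesError` when fewer than 6 peaks are found (five
    averageable cycles require six anchoring peaks).
    """
    cfg = config or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2 * fs:
        raise InsufficientCyclesError(
            f"signal too short: {signal.size / fs:.2f} s < 2 s"
        )
    scale = _robust_amplitude(signal)
    if scale <= 0:
        raise InsufficientCyclesError("flat signal: no beats detectable")
    peaks, _ = find_peaks(
        signal,
        distance=max(1, int(round(cfg.min_rr_s * fs))),
        prominence=cfg.prominence_frac * scale,
    )
    # Discard peaks implying an implausible RR interval with both neighbours.
    if peaks.size >= 2:
        rr = np.diff(peaks) / fs
        keep = np.ones(peaks.size, dtype=bool)
        for i in range(peaks.size):
            adjacent = []
            if i > 0:
                adjacent.append(rr[i - 1])
            if i < peaks.size - 1:
                adjacent.append(rr[i])
            if adjacent and all(r > cfg.max_rr_s for r in adjacent):
                keep[i] = False
        peaks = peaks[keep]
    if peaks.size < 6:
        raise InsufficientCyclesError(
            f"only {peaks.size} beats found; need >= 6 for 5-cycle averaging"
        )
    return BeatSet(peak_indices=peaks, fs=fs)


def segment_cycles(
    signal: np.ndarray, beats: BeatSet, fs: float, config: PreprocessConfig | None = None
) -> list[np.ndarray]:
    """Cut the raw series into peak-anchored cycles.

    Cycle *i* spans ``[peak_i - pre_peak_s, peak_{i+1} - pre_peak_s)`` so each
    cycle starts 0.1 s (default) before its positive peak.  Peaks too close
    to the record edges to anchor a full cycle are dropped; cycles shorter
    than ``min_cycle_s`` are rejected with a warning.  Cycles keep their
    natural (unequal) lengths.
    """
    cfg = config or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    lead = int(round(cfg.pre_peak_s * fs))
    min_len = int(round(cfg.min_cycle_s * fs))
    cycles: list[np.ndarray] = []
    peaks = beats.peak_indices
    for i in range(peaks.size - 1):
        start = peaks[i] - lead
        stop = peaks[i + 1] - lead
        if start < 0 or stop > signal.size:
            continue
        if stop - start < min_len:
            warnings.warn(
                f"cycle at peak {peaks[i]} shorter than {cfg.min_cycle_s} s; rejected",
                stacklevel=2,
            )
            continue
        cycles.append(signal[start:stop].copy())
    return cycles


def _align_and_truncate(cycles: list[np.ndarray]) -> np.ndarray:
    """Stack cycles aligned on their positive peaks, truncated to the shortest.

    By construction every cycle's positive peak sits ``pre_peak_s`` into the
    segment, so alignment is truncation from the end.
    """
    n = min(c.size for c in cycles)
    return np.vstack([c[:n] for c in cycles])


def _mean_pairwise_correlation(stack: np.ndarray) -> float:
    c = np.corrcoef(stack)
    iu = np.triu_indices_from(c, k=1)
    return float(np.mean(c[iu]))


def average_and_normalize(
    cycles: list[np.ndarray],
    fs: float,
    n_avg: int = 5,
    config: PreprocessConfig | None = None,
) -> AveragedCycle:
    """Average the most stable ``n_avg`` consecutive cycles and normalize.

    The "stable portion" is operationalized as the consecutive window of
    ``n_avg`` cycles maximizing the mean pairwise correlation after peak
    alignment (first window wins ties).  The selected cycles are truncated to
    the shortest member, averaged pointwise, the mean of the average is
    subtracted (DC removal), and the result divided by its maximum so the
    positive peak is exactly 1.
    """
    cfg = config or PreprocessConfig()
    if len(cycles) < n_avg:
        raise InsufficientCyclesError(
            f"need {n_avg} cycles for averaging, have {len(cycles)}"
        )

    if len(cycles) == n_avg:
        best = _align_and_truncate(cycles)
    else:
        best, best_score = None, -np.inf
        for start in range(len(cycles) - n_avg + 1):
            stack = _align_and_truncate(cycles[start : start + n_avg])
            score = _mean_pairwise_correlation(stack)
            if score > best_score:
                best, best_score = stack, score
        assert best is not None

    avg = best.mean(axis=0)
    if cfg.lowpass_hz is not None:
        from scipy.signal import butter, filtfilt

        b, a = butter(4, cfg.lowpass_hz, fs=fs)
        avg = filtfilt(b, a, avg)
    avg = avg - avg.mean()
    peak = avg.max()
    if peak <= 0:
        raise InsufficientCyclesError("averaged cycle has no positive peak")
    avg = avg / peak

    pos_peak = int(np.argmax(avg))
    from .features import last_strong_negative_peak  # shared B-peak rule

    neg_peak = last_strong_negative_peak(avg, pos_peak)
    return AveragedCycle(
        samples=avg, fs=fs, pos_peak_index=pos_peak, last_neg_peak_index=neg_peak
    )


def preprocess_recording(
    rec: RawRecording, config: PreprocessConfig | None = None
) -> tuple[AveragedCycle, AveragedCycle]:
    """Run the full per-side chain and return (left, right) averaged cycles.

    Per-side failures are re-raised with the side name attached.
    """
    cfg = config or PreprocessConfig()
    out = []
    for side, signal in (("left", rec.left), ("right", rec.right)):
        try:
            beats = detect_beats(signal, rec.fs, cfg)
            cycles = segment_cycles(signal, beats, rec.fs, cfg)
            out.append(average_and_normalize(cycles, rec.fs, cfg.n_avg, cfg))
        except InsufficientCyclesError as exc:
            raise InsufficientCyclesError(
                f"{rec.meta.subject_id} [{side}]: {exc}"
            ) from exc
    logger.debug("preprocessed %s: L=%d R=%d samples", rec.meta.subject_id,
                 out[0].samples.size, out[1].samples.size)
    return out[0], out[1]
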