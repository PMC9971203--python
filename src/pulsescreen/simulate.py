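"""Synthetic bilateral differential pulse-wave generator.

Clinical carotid recordings for this method are not publicly deposited, so
this module emulates their phenomenology well enough to exercise the whole
pipeline: quasi-periodic cycles (RR ~0.7-1.2 s), a dominant positive
derivative peak followed by a strong negative one, a dicrotic component, and
near left/right symmetry for healthy subjects.  A unilateral occlusion acts
as an extra reflector of the pressure wave, so the occluded side adds

* a delayed, scaled copy of the systolic component (``reflection_coeff`` /
  ``reflection_delay`` — the delay is a proxy for occlusion distance),
* small damped oscillations between the main positive and negative peaks
  (``ripple_count`` — repetitive reflections between occlusion and heart),
* a boost of the post-dicrotic-notch peak (``post_notch_boost`` — slowed
  end-diastolic flow on the affected side).

The waveform primitive is a pair of smooth asymmetric Gaussian bumps in the
pressure domain (systolic + dicrotic), differentiated analytically, because
the sensor chain measures the differential (velocity) waveform.  The model
targets waveform phenomenology, not arterial-tree physiology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core_types import (
    CohortTable,
    RawRecording,
    StructuralValidityError,
    SubjectMeta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectSimParams",
    "CohortSimConfig",
    "simulate_cycle",
    "simulate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class SubjectSimParams:
    """Per-subject simulation parameters.

    Occlusion effect sizes (reflection_coeff, ripple_count, ripple_amp,
    post_notch_boost) apply only to ``occluded_side``; amplitudes are
    fractions of the main positive derivative peak.
    """

    heart_rate: float = 70.0        # beats/min -> nominal RR 0.857 s
    n_cycles: int = 10
    fs: float = 1000.0
    occluded_side: str = "none"     # {L, R, none}
    reflection_coeff: float = 0.0   # [0, 1] amplitude ratio of reflected copy
    reflection_delay: float = 0.08  # s; occlusion-distance proxy
    ripple_count: int = 0           # oscillations injected between A and B
    ripple_amp: float = 0.18        # ripple amplitude, fraction of main peak
    post_notch_boost: float = 0.0   # additive amplitude on the post-notch peak
    noise_sd: float = 0.0           # noise SD, fraction of main peak
    noise_bandwidth_hz: float = 50.0  # measurement-noise bandwidth (acquisition chain)
    rr_jitter_sd: float = 0.0       # s
    lr_asym_sd: float = 0.0         # natural left/right timing/width asymmetry
    dicrotic_asym_sd: float = 0.0   # natural left/right dicrotic-amplitude asymmetry
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflection_coeff <= 1.0:
            raise ValueError("reflection_coeff must be in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.n_cycles < 6:
            raise ValueError("n_cycles must be >= 6 (5-cycle averaging)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Waveform geometry as fractions of the nominal cycle period.  The systolic
# pressure bump rises fast and decays slowly (asymmetric widths), so its
# derivative has a sharp positive peak (the normalization reference) and a
# broader negative one at -rise/fall = -0.45, well past the B-peak floor of
# 0.2.  The dicrotic bump sits late enough that the systolic tail has decayed,
# making its derivative's positive peak a true local maximum (the post-notch
# peak, relative amplitude = dic_amp); its falling lobe is twice as wide as
# its rising lobe so the dicrotic trough (~ dic_amp/2) stays above the B-peak
# floor even under large left/right dicrotic asymmetry.
_SYS_CENTER = 0.22
_SYS_RISE = 0.045
_SYS_FALL = 0.10
_DICROTIC_CENTER = 0.55
_DICROTIC_RISE = 0.045
_DICROTIC_FALL = 0.09
_DICROTIC_AMP = 0.14


def _bump_derivative(t: np.ndarray, amp: float, center: float, s_rise: float,
                     s_fall: float) -> np.ndarray:
    """Analytic derivative of an asymmetric Gaussian pressure bump."""
    s = np.where(t < center, s_rise, s_fall)
    return -amp * (t - center) / s**2 * np.exp(-((t - center) ** 2) / (2 * s**2))


@dataclass(frozen=True)
class _Morphology:
    """Per-side waveform geometry (fractions of the nominal period).

    Healthy left and right sides are similar but not identical; per-side
    draws of these parameters model that natural asymmetry.
    """

    sys_center: float = _SYS_CENTER
    sys_rise: float = _SYS_RISE
    sys_fall: float = _SYS_FALL
    dic_center: float = _DICROTIC_CENTER
    dic_rise: float = _DICROTIC_RISE
    dic_fall: float = _DICROTIC_FALL
    dic_amp: float = _DICROTIC_AMP


def _draw_morphology(rng: np.random.Generator, lr_asym_sd: float,
                     dicrotic_asym_sd: float) -> _Morphology:
    base = _Morphology()
    if lr_asym_sd == 0 and dicrotic_asym_sd == 0:
        return base

    def jig(v: float, sd: float) -> float:
        return v * float(1.0 + np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd)) if sd > 0 else v

    return _Morphology(
        sys_center=jig(base.sys_center, lr_asym_sd),
        sys_rise=jig(base.sys_rise, lr_asym_sd),
        sys_fall=jig(base.sys_fall, lr_asym_sd),
        dic_center=jig(base.dic_center, lr_asym_sd),
        dic_rise=jig(base.dic_rise, lr_asym_sd),
        dic_fall=jig(base.dic_fall, lr_asym_sd),
        dic_amp=jig(base.dic_amp, dicrotic_asym_sd),
    )


def _main_peak_amp(T: float) -> float:
    """Amplitude of the systolic positive derivative peak (at center - s_rise)."""
    s = _SYS_RISE * T
    return 1.0 / (s * np.sqrt(np.e))


def simulate_cycle(
    params: SubjectSimParams,
    occluded: bool = False,
    rr_s: float | None = None,
    morph: _Morphology | None = None,
) -> np.ndarray:
    """One noiseless differential pulse cycle of duration ``rr_s``.

    With ``occluded=False`` (or all effect sizes zero) this is the shared
    base morphology; ``occluded=True`` superposes the three occlusion
    effects.  Raises :class:`StructuralValidityError` when the parameters
    destroy the dominant positive-then-negative main peak pair (e.g. a
    near-total reflection with near-zero delay, indistinguishable from the
    incident wave).
    """
    m = morph or _Morphology()
    T = 60.0 / params.heart_rate
    dur = rr_s if rr_s is not None else T
    t = np.arange(int(round(dur * params.fs))) / params.fs

    w = _bump_derivative(t, 1.0, m.sys_center * T, m.sys_rise * T, m.sys_fall * T)
    w += _bump_derivative(t, m.dic_amp, m.dic_center * T,
                          m.dic_rise * T, m.dic_fall * T)

    if occluded:
        if params.reflection_coeff >= 0.95 and params.reflection_delay <= 0.01:
            raise StructuralValidityError(
                "near-total reflection with near-zero delay superposes on the "
                "incident wave and destroys the dominant-peak structure"
            )
        if params.reflection_coeff > 0:
            w += _bump_derivative(
                t, params.reflection_coeff,
                m.sys_center * T + params.reflection_delay,
                m.sys_rise * T, m.sys_fall * T,
            )
        if params.ripple_count > 0:
            # damped oscillations on the systolic downstroke, between the main
            # positive peak (center - rise) and negative peak (center + fall)
            t0 = (m.sys_center - m.sys_rise) * T
            t1 = (m.sys_center + m.sys_fall) * T
            u = (t - t0) / (t1 - t0)
            window = np.where((u > 0) & (u < 1), np.sin(np.pi * np.clip(u, 0, 1)) ** 2, 0.0)
            ripple = np.sin(2 * np.pi * params.ripple_count * u) * window
            w += params.ripple_amp * _main_peak_amp(T) * ripple
        if params.post_notch_boost > 0:
            # raise the dicrotic derivative's positive peak (post-notch peak)
            peak_t = (m.dic_center - m.dic_rise) * T
            s = 0.4 * m.dic_rise * T
            w += (params.post_notch_boost * _main_peak_amp(T)
                  * np.exp(-((t - peak_t) ** 2) / (2 * s**2)))

        _check_structure(w)
    return w


def _check_structure(w: np.ndarray) -> None:
    """The cycle must keep one dominant positive peak followed by the min."""
    peak = w.max()
    if peak <= 0 or w.min() >= -0.2 * peak:
        raise StructuralValidityError("no dominant positive/negative peak pair")
    i_max, i_min = int(np.argmax(w)), int(np.argmin(w))
    if i_max >= i_min:
        raise StructuralValidityError("positive peak does not precede negative peak")
    # competing positive peaks at >= 90% of the main one, away from it
    near_top = np.flatnonzero(w >= 0.9 * peak)
    if np.any(np.abs(near_top - i_max) > 0.05 * w.size):
        raise StructuralValidityError("secondary positive peak rivals the main peak")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                       cutoff_hz: float) -> np.ndarray:
    """Measurement noise: Gaussian, low-pass limited like the acquisition chain.

    White noise at the full 1 kHz bandwidth would litter the averaged cycle
    with sample-to-sample extrema no analog front end produces; the sensor
    and preamplifier pass only the low-frequency band.
    """
    from scipy.signal import butter, filtfilt

    white = rng.normal(0.0, 1.0, n)
    if cutoff_hz < fs / 2:
        b, a = butter(4, cutoff_hz, fs=fs)
        white = filtfilt(b, a, white)
    scale = white.std()
    return white * (sd / scale) if scale > 0 else white


def simulate_recording(
    params: SubjectSimParams, meta: SubjectMeta | None = None
) -> RawRecording:
    """Concatenate jittered cycles into a bilateral raw recording.

    Both sides share the beat timing; the occluded side (if any) carries the
    occlusion effects; white measurement noise is drawn independently per
    side.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    T = 60.0 / params.heart_rate
    morphs = {
        side: _draw_morphology(rng, params.lr_asym_sd, params.dicrotic_asym_sd)
        for side in ("L", "R")
    }
    if params.rr_jitter_sd > 0:
        jitter = np.clip(rng.normal(0.0, params.rr_jitter_sd, params.n_cycles),
                         -3 * params.rr_jitter_sd, 3 * params.rr_jitter_sd)
    else:
        jitter = np.zeros(params.n_cycles)
    rr = np.maximum(T + jitter, 0.8 * T)

    sides: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        occluded = params.occluded_side == side
        segments = [
            simulate_cycle(params, occluded=occluded, rr_s=float(r), morph=morphs[side])
            for r in rr
        ]
        sides[side] = np.concatenate(segments)
    n = min(sides["L"].size, sides["R"].size)
    left, right = sides["L"][:n], sides["R"][:n]

    if params.noise_sd > 0:
        sd = params.noise_sd * _main_peak_amp(T)
        left = left + _bandlimited_noise(rng, n, params.fs, sd, params.noise_bandwidth_hz)
        right = right + _bandlimited_noise(rng, n, params.fs, sd, params.noise_bandwidth_hz)

    if meta is None:
        meta = SubjectMeta(
            subject_id=f"sim-{params.seed}",
            age=60,
            sex="male",
            occlusion_side=params.occluded_side,  # type: ignore[arg-type]
            occlusion_type="none" if params.occluded_side == "none" else "ICO_neck",
        )
    return RawRecording(meta=meta, fs=params.fs, left=left, right=right)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level simulation settings.

    Patient effect sizes are drawn per subject from the ranges below; the
    occlusion type is drawn first (frequencies mirroring the 16/5/2
    neck/intra/MCO composition of the reference cohort) and sets the
    reflection-delay band — an extracranial neck occlusion is closest to the
    measurement site, hence the shortest delay and strongest reflection.
    Defaults produce overlapping feature distributions (some patients with
    zero ripples, measurement noise on every subject), so classification is
    informative but deliberately imperfect.
    """

    n_healthy: int = 30
    n_patients: int = 23
    n_cycles: int = 10
    fs: float = 1000.0
    heart_rate_range: tuple[float, float] = (55.0, 85.0)
    noise_sd: float = 0.02
    rr_jitter_sd: float = 0.02
    lr_asym_sd: float = 0.04
    dicrotic_asym_sd: float = 0.25
    ripple_amp_range: tuple[float, float] = (0.10, 0.20)
    ripple_count_range: tuple[int, int] = (0, 3)
    post_notch_boost_range: tuple[float, float] = (0.0, 0.20)
    type_probs: tuple[float, float, float] = (16 / 23, 5 / 23, 2 / 23)
    # (reflection_coeff range, reflection_delay range) per occlusion type
    reflection_by_type: dict = field(default_factory=lambda: {
        "ICO_neck": ((0.25, 0.50), (0.03, 0.08)),
        "ICO_intra": ((0.10, 0.30), (0.08, 0.14)),
        "MCO": ((0.05, 0.20), (0.14, 0.20)),
    })


def generate_cohort(
    n_healthy: int = 30,
    n_patients: int = 23,
    base_seed: int = 0,
    config: CohortSimConfig | None = None,
) -> tuple[list[RawRecording], CohortTable]:
    """Simulate a full cohort of bilateral recordings with metadata.

    Returns the recordings and a cohort table whose composition mirrors the
    reference study (default 30 healthy + 23 patients).  Deterministic for a
    fixed ``base_seed``.
    """
    if n_healthy < 1 or n_patients < 1:
        raise ValueError("n_healthy and n_patients must be >= 1")
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(base_seed)
    type_names = ("ICO_neck", "ICO_intra", "MCO")

    recordings: list[RawRecording] = []
    subjects: list[SubjectMeta] = []

    for i in range(n_healthy):
        meta = SubjectMeta(
            subject_id=f"SH{i + 1:02d}",
            age=int(rng.integers(21, 91)),
            sex="male" if rng.random() < 0.5 else "female",
        )
        params = SubjectSimParams(
            heart_rate=float(rng.uniform(*cfg.heart_rate_range)),
            n_cycles=cfg.n_cycles,
            fs=cfg.fs,
            noise_sd=cfg.noise_sd,
            rr_jitter_sd=cfg.rr_jitter_sd,
            lr_asym_sd=cfg.lr_asym_sd,
            dicrotic_asym_sd=cfg.dicrotic_asym_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recordings.append(simulate_recording(params, meta))
        subjects.append(meta)

    for i in range(n_patients):
        occ_type = type_names[int(rng.choice(3, p=cfg.type_probs))]
        (rc_lo, rc_hi), (rd_lo, rd_hi) = cfg.reflection_by_type[occ_type]
        meta = SubjectMeta(
            subject_id=f"SP{i + 1:02d}",
            age=int(rng.integers(51, 97)),
            sex="male" if rng.random() < 16 / 23 else "female",
            occlusion_side="L" if rng.random() < 0.5 else "R",
            occlusion_type=occ_type,  # type: ignore[arg-type]
        )
        params = SubjectSimParams(
            heart_rate=float(rng.uniform(*cfg.heart_rate_range)),
            n_cycles=cfg.n_cycles,
            fs=cfg.fs,
            occluded_side=meta.occlusion_side,
            reflection_coeff=float(rng.uniform(rc_lo, rc_hi)),
            reflection_delay=float(rng.uniform(rd_lo, rd_hi)),
            ripple_count=int(rng.integers(cfg.ripple_count_range[0],
                                          cfg.ripple_count_range[1] + 1)),
            ripple_amp=float(rng.uniform(*cfg.ripple_amp_range)),
            post_notch_boost=float(rng.uniform(*cfg.post_notch_boost_range)),
            noise_sd=cfg.noise_sd,
            rr_jitter_sd=cfg.rr_jitter_sd,
            lr_asym_sd=cfg.lr_asym_sd,
            dicrotic_asym_sd=cfg.dicrotic_asym_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recordings.append(simulate_recording(params, meta))
        subjects.append(meta)

    logger.info("generated cohort: %d healthy + %d patients", n_healthy, n_patients)
    return recordings, CohortTable(subjects=subjects)
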