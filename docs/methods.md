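# Methods

## Signal model and preprocessing

The working signal is the *differential* pulse wave: the acquisition chain
(piezoelectric transducer + preamplifier) senses skin-surface velocity, so
every recording is the time derivative of the displacement pulse wave,
sampled at `fs` (1 kHz by default) on the left and right common carotid
arteries simultaneously.  Amplitudes are in arbitrary units; every
downstream quantity is invariant to a common rescaling of the raw samples.

Preprocessing converts each side into one averaged, normalized cycle:

1. **Beat detection** — the main positive peak of each cardiac cycle, via
   `scipy.signal.find_peaks` with a minimum separation `min_rr_s` (0.4 s)
   and a prominence threshold of `prominence_frac` (0.5) times a robust
   amplitude scale, the 90th percentile of |x − median(x)|.  The relative
   threshold is what makes detection unit-free and outlier-resistant.
   Peaks whose every neighbouring interval exceeds `max_rr_s` (2.5 s) are
   discarded as artefacts.  Fewer than 6 surviving peaks is an error:
   5 averageable cycles need 6 anchoring peaks.
2. **Segmentation** — cycle *i* spans `[peak_i − 0.1 s, peak_{i+1} − 0.1 s)`,
   so each cycle carries its positive peak 0.1 s in.  Peaks too close to the
   record edges are dropped; cycles shorter than 0.3 s are rejected with a
   warning.  Cycles keep their natural unequal lengths.
3. **Stable-portion selection and averaging** — "the stable portion" is
   operationalized as the consecutive window of `n_avg` (5) cycles with the
   highest mean pairwise correlation after peak alignment (first window wins
   ties; alignment is truncation to the shortest member, since all cycles
   share the 0.1 s pre-peak anchor).  The selected cycles are averaged
   pointwise, the mean of the *average* is then subtracted (DC removal
   happens after averaging, not per cycle), and the result is divided by its
   maximum, fixing the positive-peak amplitude at exactly 1.  The averaged
   cycle is therefore not zero-mean.
4. An optional zero-phase Butterworth low-pass (`lowpass_hz`, off by
   default) exists solely to stabilize small-peak counting on unusually
   noisy input; it is part of the configuration and recorded in output
   provenance.

Preprocessing is fully deterministic: identical input gives identical
output.

## The three dynamic features

**MCC (x1).**  The maximum over lags τ ∈ [−N/2, +N/2] of the left/right
cross-correlation.  The raw lagged inner product `(1/N) Σ l(n) r(n+τ)` is
unbounded and depends on signal energy, whereas the feature is used as a
similarity on unit-normalized waves with values near 1 for healthy
subjects; the default is therefore the normalized cross-correlation
coefficient — each lag's inner product divided by the product of the two
vector norms over the overlapping support — which lies in [−1, 1] and
equals 1 for identical sides.  The raw form remains available
(`normalized=False`) for fidelity checks.  Lag sums are computed by FFT
correlation with per-lag norms from prefix sums; the implementation is
tested to 1e-9 against an exhaustive per-lag oracle and a literal
double-loop. The lag range (±half the cycle, configurable) covers
physiologic left/right timing offsets while avoiding degenerate short
overlaps.

**Peak annotation.**  A is the global maximum (amplitude 1).  B, the last
strong negative peak preceding the dicrotic notch, is the last local
minimum at or below −0.2 (`neg_peak_floor`); without the floor, B would
latch onto low-amplitude ripples near the cycle end.  The analytic peak
condition dl/dt = 0 is realized on sampled data as a sign change of the
first difference with a prominence floor (`small_peak_prominence`, 0.01 of
the normalized amplitude) — the literal zero-derivative condition is
noise-fragile, and the floor is the configurable, logged compromise.
Whether the original counting used such a floor is not documented; the
default is a convention of this implementation.

**DNP (x2)** counts local maxima *and* minima strictly between A and B on
each side and takes the absolute left/right difference.  One injected
oscillation contributes an extremum pair, so counts move in steps of ~2.

**DPA (x3)** is the absolute left/right difference of the post-notch peak
amplitude: the local maximum of largest amplitude at or after B (earliest
index on ties, for determinism); if the tail after B has no interior local
maximum, the tail's global maximum is used (for a monotone tail, the last
sample).

All three features are symmetric under left/right exchange and invariant
to rescaling of the raw amplitudes.

## Classifier and evaluation protocol

Logistic regression on `x = [x1, x2, x3]`, fit by maximum likelihood.  Two
choices deserve note:

* **Standardization.**  Features are z-scored on the training fold (the
  constants are stored in the model).  The three features live on very
  different scales (x1 ≈ 1, x2 integer counts, x3 ≈ 0.1), and comparing
  weight magnitudes across features — the point of the weight table — only
  makes sense on a common scale.  Reported weights are standardized-scale
  coefficients.
* **Regularization.**  None in substance; a tiny ridge (C = 1e8 in the
  scikit-learn parametrization, i.e. penalty ~1e-8) keeps the optimizer
  finite on separable folds.  On separable training folds the weights are
  consequently large — their size is then set by the ridge, not the data —
  which inflates the weight SDs across trials.

Classification threshold: Positive iff P > 0.50 strictly; an exact 0.50 is
Negative ("greater than the preset threshold").

The evaluation shuffles the cohort with seed `base_seed + trial`, splits
into the first 40 (train) / remaining 13 (test), fits, and scores; 20
trials by default.  A trial whose training split is single-class is
re-drawn with the next seed (logged; more than 10 consecutive re-draws
abort).  Metrics with undefined denominators (e.g. precision when nothing
is called positive) are recorded as undefined and excluded from the
aggregate, with an exclusion count.  The chance level is the accuracy of
the all-positive classifier — the positive-class ratio (0.43 for the
30/23 reference composition) — because a screening baseline must not miss
positives.  The t-test on the per-trial accuracies against that level is
one-sample and one-sided (the claim is directional: *higher* than chance),
α = 0.01.  With zero variance across trials (a separable cohort) the test
degenerates and is reported as t = ±∞, p ∈ {0, 1}.

## Synthetic cohort generator

The generator targets waveform *phenomenology*, not arterial physiology
(no transmission-line or PDE modeling).  The pressure-domain primitive is a
pair of smooth asymmetric Gaussian bumps — systolic (fast rise, slow decay)
and dicrotic — differentiated analytically, because the sensor measures the
differential waveform; this yields the observed morphology: a sharp
dominant positive peak, a broad strong negative peak at −rise/fall ≈ −0.45
of the main peak, and a late dicrotic derivative peak (relative amplitude
0.14) that is the post-notch peak.  The dicrotic trough (≈ half its peak)
stays above the B-floor across the asymmetry range so that B remains the
systolic trough.

A unilateral occlusion adds, on the occluded side only:

* a **delayed scaled copy** of the systolic component
  (`reflection_coeff` ∈ [0, 1], `reflection_delay` in seconds — a proxy for
  occlusion distance; shorter delay and stronger reflection for occlusions
  nearer the measurement site);
* **ripples** between the main peaks (`ripple_count` damped oscillations of
  amplitude `ripple_amp`, default 0.18 of the main peak — large enough to
  produce extrema against the downstroke slope; smaller values can be
  fully masked, which is why cohort draws from [0.10, 0.20] leave some
  patients with zero measured DNP);
* a **post-notch boost** (`post_notch_boost`, additive amplitude on the
  dicrotic derivative peak; the pipeline-measured DPA equals the boost to
  within a few percent).

Parameter combinations that destroy the dominant positive-then-negative
peak pair — e.g. a near-total reflection with near-zero delay,
indistinguishable from the incident wave — raise a structural-validity
error.

Realism features shared by both sides: per-beat RR jitter (`rr_jitter_sd`,
0.02 s in cohorts) around a per-subject heart rate (55–85 bpm), and
Gaussian measurement noise band-limited to 50 Hz (`noise_bandwidth_hz`) —
the analog front end passes only low frequencies, and full-bandwidth white
noise would litter the averaged cycle with sample-scale extrema no real
chain produces.  Natural left/right asymmetry of healthy subjects is
modeled by independent per-side draws of the morphology parameters
(`lr_asym_sd` = 0.04 relative on timings/widths, `dicrotic_asym_sd` = 0.25
on the dicrotic amplitude in cohorts; both default to 0 at the
single-subject level so that the null-occlusion identity holds exactly).
The dicrotic asymmetry is deliberately large: healthy left/right post-notch
amplitudes differ by ~0.05 on average, so DPA overlaps substantially
between groups, as it does clinically.

Cohort defaults (frozen in `CohortSimConfig`): 30 healthy + 23 patients;
occlusion type drawn at the reference frequencies 16:5:2
(neck ICA : intracranial ICA : MCA), mapping to reflection bands — neck
(closest to the probe): coeff 0.25–0.50, delay 0.03–0.08 s; intracranial:
0.10–0.30, 0.08–0.14 s; MCA: 0.05–0.20, 0.14–0.20 s; ripple counts 0–3;
boosts 0–0.20; noise SD 0.02 of the main peak (chosen so that averaged
noise sits just below the small-peak prominence floor: healthy DNP is then
usually 0–2, from noise and asymmetry, rather than noise-dominated).
Ages and sexes are drawn to mirror the reference cohort (healthy 21–90,
patients 51–96; patient sex ratio 16:7).  Everything is deterministic
under `base_seed`.

**What passing tests show — and don't.**  The defaults produce overlapping
feature distributions and imperfect classification (mean accuracy roughly
0.75–0.93 across cohort seeds, against a 0.43 chance level), so the
evaluation machinery is exercised in a regime of partial separability.
They do not reproduce clinical effect sizes: real occlusion effects are
weaker and more heterogeneous (clinical accuracy for this method is far
lower), real waveforms contain baseline drift, probe-pressure variation
and arrhythmia that the generator omits, and the simulator's occluded-side
effects are by construction aligned with what the features measure.
Synthetic results validate the pipeline's correctness and qualitative
orderings (patients: lower MCC, higher DNP, higher DPA), not clinical
performance.

## Numerical choices and degenerate inputs

* MCC is clipped to [−1, 1] against float round-off; constant inputs raise
  an undefined-correlation error.
* Ties in the stable-window score: first window; ties in the post-notch
  maximum: earliest index.
* Standardization scales of zero-variance training features are replaced
  by 1 (the feature then contributes a zero weight).
* Correlation matrices report NaN for zero-variance features; all-equal
  labels are an error.
* Recording CSVs serialize samples via `repr`, so read ∘ write is exact on
  IEEE doubles (`float_precision="round_trip"` on read).
* Problem sizes throughout (10-cycle recordings, 53-subject cohorts,
  n = 5000 for parameter recovery, 100 pairs for the oracle check) keep
  the full suite and the acceptance script in the seconds range; they are
  the scales at which the checked properties are already stable.

## Known limitations

* The generator's occlusion effects are phenomenological dials, not
  hemodynamics; effect magnitudes were chosen once for plausible overlap
  and are not calibrated to patient data.
* DNP's prominence floor and the B-peak amplitude floor are conventions of
  this implementation; the original counting rules are underdocumented.
* No integration of the differential waveform back to displacement is
  attempted, and age/sex are carried in metadata but never used as model
  inputs.
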