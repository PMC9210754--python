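# Methods

This note documents the models, estimators and numerical choices behind
`fogsense`, and what the synthetic cohort does and does not establish.

## Synthetic cohort

The generator replaces non-public patient recordings. It is a
phenomenological signal model, not a biomechanical one: each channel is
a sum of deterministic oscillations, a stochastic trembling component,
and white Gaussian sensor noise, switched by a walk/freeze schedule.

**Schedule.** Subjects walk; "freezer" subjects (10 of 12 by default)
additionally freeze. Walking gaps between episodes are exponential
(memoryless) with a 2 s minimum, at `episode_rate` = 1.2 episodes/min.
Episode durations are lognormal with mu = 1.6715, sigma = 0.9170 —
mean 8.1 s, sd 9.3 s, median 5.3 s (so more than half of episodes are
shorter than 6 s) — truncated by resampling to [0.9 s, 76.9 s]. A
freezer whose draw produces no episode receives one mid-recording, so
the freezer count is exact by construction. Default recording length is
720 s per subject at 100 Hz, consistent with a cohort totalling about
two and a half hours over 12 subjects.

**Walking.** IMU channels carry A · [sin(2π f₀ t + φ) +
0.4 sin(4π f₀ t + φ')] with a per-subject step fundamental
f₀ ~ U(1.5, 2.5) Hz and independent per-channel phases. Site
amplitudes (accelerometer, in g): shank 1.0, thigh 0.9, foot 0.7,
waist 0.5; axis weights x/y/z = 1.0/0.7/0.5; gyroscopes use the same
table scaled by 20 (deg/s). Shank and thigh carry the largest
locomotor signal, so leg sensors are the most informative — the
qualitative premise of the sensor-configuration experiments. Plantar
cells produce a half-rectified loading pattern
base + 0.8·max(0, sin(2π f₀ t + φ)).

**Freezing.** During an episode the locomotor amplitude is attenuated
by `fog_amplitude_ratio` = 0.3 and a trembling component is added:
Gaussian noise spectrally confined to `tremble_freq_range` = 4–7 Hz,
scaled so its RMS equals that of a sinusoid at the site's trembling
amplitude (shank 0.7, thigh 0.6, foot 0.45, waist 0.3, in g). The
trembling is deliberately *broadband*: trembling-type freezing is
shaking distributed across the 3–8 Hz band rather than a pure tone,
and this is exactly what the freeze index integrates over. (A pure
per-subject tremble tone would additionally make each held-out
subject's freeze signature a frequency never seen during training — an
artefact of the simulation, not a property of the method.) Plantar
load is near-constant mid-range during freezes. Sensor noise is white
with sd 0.05 (scaled per channel like the signal). None of the
per-site amplitudes are reported quantities; they are free parameters
fixed once, chosen so that band powers separate clearly while window
boundaries remain genuinely ambiguous.

**Dropouts.** Per channel, Poisson-many gaps (`gap_rate` = 0.05/s) of
5–50 samples are masked (≈1.4% of samples, always interior so
interpolation never extrapolates). Missing values are NaN plus a mask.

**Reproducibility.** All randomness flows from
`SeedSequence(seed, spawn_key=(subject, stream))`; identical
configuration and seed give bit-identical cohorts regardless of call
order.

**What the synthetic data does not emulate.** Kinematic gait structure
(stance/swing asymmetries, turning, festination), gravity orientation
on accelerometer axes, episode-onset dynamics (freezes start and stop
instantaneously here), inter-episode correlation, medication state, and
sensor quantisation. Passing results therefore demonstrate that the
pipeline recovers planted class structure under the stated spectral
model — not clinical performance.

## Preprocessing

Missing samples are filled by linear interpolation between the nearest
valid neighbours (nearest-value extension at the edges; an all-missing
channel is an error). Interpolation is idempotent.

The band-pass filter is a 27-tap (order 26) equiripple FIR, nominal
band 0.5–10 Hz, applied in a single causal pass (`lfilter`), so all
channels share a constant 13-sample group delay and window labels stay
aligned across channels. Design details matter here: at 100 Hz a
27-tap filter cannot realise sharp cut-offs at both 0.5 and 10 Hz. We
verified by linear programming over the complete linear-phase cosine
basis that *no* 27-tap symmetric FIR can combine ≥ −3 dB response
across 1–8 Hz with ≤ −10 dB at DC and above 15 Hz (the best minimax
ripple is ±0.41). The filter is therefore designed antisymmetric
(type III linear phase), which contributes an exact spectral null at
DC for free; the Parks–McClellan exchange then only has to trade the
passband against the upper stopband. Design bands: pass 1–8 Hz, stop
14–50 Hz, stopband weight 2; gain normalised to unity at mid-band.
Achieved response: exact DC null, −2.4…+2.7 dB over 1–8 Hz, ≤ −16 dB
above 15 Hz. The magnitude contract (not the tap values) is the tested
interface. FSR channels are filtered identically to IMU channels,
which removes the static load baseline and keeps every channel's
feature definitions uniform.

## Windowing and labelling

Windows of m = 2 s step by t = 0.5 s; count = ⌊(l/f − m)/t⌋ + 1 (a
small epsilon guards the float division before flooring). The label is
taken at the window's *start* point — observers annotating from video
mark freeze onsets late, so the start-point rule counteracts that lag —
with episodes half-open `[start, end)`: a window starting exactly at an
episode's end is non-FoG. Windows spanning an onset or offset are
genuinely mixed; their labels are noisy by construction, which bounds
attainable window-level sensitivity.

## Features

Per (window, channel), in fixed order: FI, energy, sum power, mean,
absolute mean, zero-crossing rate, standard deviation (population),
range, RMS, max, min, principal-direction eigenvalue, entropy.
Spectral quantities use the plain DFT of the raw 200-sample window —
no taper, no detrending. Band power sums squared two-sided DFT
magnitudes over bins whose |frequency| falls in the band, divided by N;
the DC bin belongs to neither zone. The motion zone is [0.5, 3) Hz and
the freezing zone [3, 8] Hz — the 3 Hz bin is assigned exclusively to
the freezing zone so the two zones partition and sum power counts each
bin once. FI = freeze/(motion + 1e−12); the epsilon keeps FI finite
for windows with no locomotor power (the ratio is then enormous, which
is the correct signal). Energy is the un-normalised two-sided sum
Σ|X_k|².

Zero crossings count strict sign changes; an exact zero inherits the
previous nonzero sign so a touch-and-go is not double-counted. Entropy
uses 16 equal-width bins spanning the window's own min–max, natural
log, 0·log 0 := 0; a constant window has entropy 0 (single occupied
bin), not an error. The principal-direction feature diagonalises the
3×3 within-window covariance of each sensor triad and assigns the
eigenvalues, sorted descending, to the x/y/z columns in that order —
each channel still owns exactly 13 scalars; a partial triad uses the
covariance of whatever axes are present, and a pressure cell its
variance.

Min–max normalisation maps the training minimum/maximum of each
feature to 0/1; a constant training feature maps everything to 0; test
values may leave [0, 1] and are not clipped. The model is always fit
inside the training fold — fitting on pooled data would leak test-range
information into training.

## Feature selection

ANOVA F uses the classical decomposition
SS_b = Σ_i N_i (x̄ⁱ − x̄)², SS_w = Σ_i Σ_j (x_jⁱ − x̄ⁱ)². A feature
with distinct class means but zero within-class scatter receives +inf
and ranks above all finite scores; SS_b = 0 scores 0. Mutual
information is the plug-in estimate on the empirical joint after
discretising the feature into 10 quantile bins — quantile (not
equal-width) binning makes the score invariant to monotone rescaling
and robust to outliers; tiny negative estimates are clamped to 0. Ties
in ranking break by column order, so rankings are deterministic.
Restricting to the top-k keeps the surviving columns in their original
order, making k = p exactly the identity.

## Balancing

SMOTE runs on training rows only, after normalisation (Euclidean
neighbourhoods presume commensurate scales). For each minority row the
k = 5 nearest minority neighbours are found; synthetic rows are drawn
uniformly along the connecting segments until the minority count
reaches the majority count. When the required count is not a multiple
of the minority size, the remainder's base points are drawn without
replacement. Synthetic rows inherit their base row's subject id, so
leave-one-subject-out audits can verify that no training row — original
or synthetic — descends from the held-out subject. If the minority
class has ≤ 5 rows the neighbourhood shrinks with a warning.

## Classification and evaluation

Random forest: 10 trees, fully grown (no depth limit), bootstrap
resampling, √p features per split, fixed seed (scikit-learn). Folds
are leave-one-subject-out; within each fold the order is: fit min–max
→ rank features → keep top-k → SMOTE → train → predict the untouched,
unbalanced test rows. Per-fold seeds for SMOTE and the forest derive
deterministically from the master seed.

Aggregate metrics come from pooled confusion counts, which remain
well-defined when a fold has no positive windows (the two non-freezer
subjects); fold-wise means ± sd are reported alongside, skipping folds
where a metric is undefined (sensitivity without positives). Precision
is TP/(TP+FP) and F-score the harmonic mean of sensitivity and
precision.

**Null behaviour.** With shuffled labels (or pure-noise features) and
no balancing, the forest's predictions become independent of the truth;
its accuracy then equals q·p₀ + (1−q)(1−p₀), where p₀ is the
majority-class rate and q the rate at which the forest emits the
majority class. Because unpruned trees memorise single rows, q is
slightly below 1 and null accuracy sits slightly *below* p₀ — chance
level, never above it. The null tests therefore assert (a) accuracy
does not exceed the majority rate and (b) accuracy matches the
independence expression, both within 3 binomial standard deviations.
With SMOTE enabled a null forest predicts each class about half the
time, so balanced null accuracy is ≈ 0.5 by design; the leakage audit
for the balanced pipeline uses subject-id provenance instead.

## Problem sizes in the test suite

Unit and property tests run on reduced cohorts (typically 4–6 subjects
at 120 s) — the contracts they check are size-independent. The
parameter-recovery check runs the full default conditions (12 subjects
× 720 s, five master seeds) on the left-shank channels; the episode
duration law is checked on 10 000 pooled Monte-Carlo draws. The ANOVA
oracle comparison covers 1 000 random instances at 1e−9 relative
tolerance.

## Known limitations

Single-pass causal filtering leaves a 13-sample transient at each
recording start and shifts all features by a constant 130 ms relative
to annotations — immaterial for 2 s windows but a real choice (zero-
phase filtering would halve the usable order and preclude online use).
The MI estimator's bin count (10) is a bias/variance compromise for
~10³–10⁴ windows; rankings, not absolute MI values, are the interface.
Window-level metrics say nothing about episode-level detection latency.
And all quantitative results concern the synthetic model above;
clinical recordings differ in every inconvenient way.
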