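# Methods

This note documents the models, estimators and design choices behind
`dyadsync`: what the synthetic-study generator assumes, how synchrony is
estimated and nulled, how outcomes are modeled, and where the genuinely open
choices were made.

## Study design model

A study consists of one session per condition (e.g. a mutual-gaze
meditation, a "Just-Like-Me" contemplation, a solitary eyes-closed control),
each with its own pool of `n_participants`. Within a session, partners are
assigned by the circle method, the standard round-robin construction:
everyone meets a new partner each round as long as
`n_rounds ≤ n_participants − 1` (even pools; one more for odd pools, where
one participant sits out per round). Requesting more rounds without
`allow_repeats=True` is an error rather than a silent repeat. Familiarity
(0 = not at all, 1 = moderately, 2 = extremely) is drawn per member at a low
rate; the robustness filter `exclude_familiar=True` removes every pairing —
real or pseudo — involving a participant who reported any familiarity with a
real partner, mirroring how such sensitivity analyses drop *individuals*.

### Latent coupling

Each dyad receives one latent factor `z ~ N(0, 1)`. The smile mimicry
probability is `clip01(mimicry_prob + coupling_sd · z)` and the HR
shared-innovation weight `clip01(hr_coupling + coupling_sd · z)`; the
outcome-driving coupling is the mean of the modality couplings in play. One
latent per dyad (rather than independent draws per modality) encodes the
assumption that behavioral and physiological coordination share a common
affiliative cause — the mechanism the outcome models are meant to detect.
`coupling_sd` defaults to 0.25 so that coupling varies enough across dyads
for slope recovery to be identifiable while means stay at the configured
levels.

### Smile signals

Smile intensity (0–100, 25 Hz, 120 s) is a sum of half-cosine bursts:
amplitude `amp · cos(π(t − t₀)/w)` for `|t − t₀| < w/2`. Spontaneous burst
centers are Poisson with rate `smile_burst_rate` (default 8/min); amplitudes
jitter uniformly in [0.7, 1] × `smile_burst_amp` (default 70); width
defaults to 2 s. With the dyad's mimicry probability, each spontaneous burst
seeds a partner response burst after a lag drawn uniformly from
[0.2, 1.0] s — inside the ±1-s lag window the WCLC profile searches, which
is what makes peak synchrony sensitive to mimicry. Responses do not trigger
counter-responses (no infinite echo). A participant may be a *non-smiler*
(all-zero series); in whole-study simulation this is a stable trait drawn
once per participant (default probability 0.19, so that roughly 65% of
dyads have both members smiling). Values are clipped to [0, 100].

The half-cosine shape is a deliberate stand-in: it is smooth, bounded and
analytically simple, and no generative model of smiling is established.
What the generator must (and does) reproduce is the qualitative structure
the analysis assumes — sparse bounded bursts, probabilistic short-lag
mimicry, non-smilers — not the texture of real facial-expression tracker
output (no tracker noise, no drift, no partial-intensity plateaus). Passing
tests therefore validate the estimators' logic and calibration, not their
behavior on tracker artifacts.

### Heart-rate signals

HR (bpm, 0.5 Hz, 120 s) is `baseline + amp·exp(−t/τ) + x(t)`: everyone
starts the exercise aroused and settles (defaults baseline 77 bpm, amp
12 bpm, τ 30 s, matching starts near 89 bpm that decline to the high 70s).
`x` is AR(1) with coefficient φ (default 0.5; |φ| ≥ 1 is rejected) and
innovations `e_i = √(1−c)·u_i + √c·s` with member-specific `u_i` and shared
`s`, all white with SD `hr_noise_sd` (default 1 bpm). `x₀` is the first
innovation scaled by the stationary factor `1/√(1−φ²)`, so at `c = 1` the
two members' fluctuation components coincide exactly — a useful analytic
limit (prewhitened residuals correlate 1). Values are floored at 1 bpm.
Beat-to-beat variability and waveform shape are out of scope; only bpm-level
dynamics are modeled.

### Outcomes

Ratings are generated per rater × round × measure. Measures with pre values
(closeness on the 7-point pictorial scale; warmth, competence,
attractiveness, friendship sliders 0–100) draw `pre` from a measure-specific
normal; `post = pre + (condition_effect + γ·(coupling − mean coupling) +
noise) · pre_sd`, clipped to the measure's range and rounded for integer
scales. Post-only measures (dictator-game allocation, emotion sliders) are
generated the same way around their own baseline. Expressing
`condition_effects` (defaults: JLM 0.97, Gazing 0.57, Eyes Closed 0.0) and
the coupling slope γ (default 0.5) in pre-SD units makes them read as
standardized effect sizes. Clipping rather than resampling preserves the
monotone effect structure; its attenuation of the recovered slope is below
0.02 at the default noise level (measured by the recovery experiment).

## Preprocessing

* **Rounding**: half-away-from-zero to whole intensities (matches common
  spreadsheet/statistical rounding; banker's rounding would surprise).
* **Smoothing**: centered moving average, default 4 samples (160 ms at
  25 Hz). Edges *shrink* by default so output length equals input length —
  required for pairwise correlation without trimming; `edges="trim"`
  reproduces tooling that leaves incomplete windows undefined. For even
  windows the label sits right of center (window `[i−w/2, i+w/2−1]`).
  Rounding precedes smoothing.
* **Prewhitening**: Yule–Walker AR fit on the demeaned series with
  denominator-n autocovariances, order selected by AIC
  (`n·log σ̂² + 2p`) over `0..⌊10·log₁₀ n⌋` — the classic time-series
  default. Residuals are one-step-ahead prediction errors for `t ≥ p`, so
  the residual series is `p` samples shorter; pairs are aligned on their
  tails (and, for WCLC time courses, all recordings are cut to the common
  minimum so window grids agree). Order 0 degenerates to the demeaned
  series; constant series raise (`zero variance`).

## Synchrony estimation

`lagged_correlation(a, b, ℓ)` correlates `a[t]` with `b[t+ℓ]` over the
overlap and is undefined (NaN) when a slice has zero variance or fewer than
two points; Spearman is Pearson on average ranks. Global synchrony is lag-0
correlation of the full preprocessed series, carrying the *raw* signal means
(average smiling / average HR) as covariates for later models. Smile
eligibility — both members must smile at least once, judged on raw series —
is recorded per pair, and ineligible pairs keep a row with the exclusion
reason rather than disappearing.

WCLC computes, for each window start on the step grid (windows fully inside
the recording), correlations over the symmetric lag grid and records the
maximum over defined lags plus its argmax lag. Conventions the literature
leaves open, fixed here and tested:

* **Lag sign**: positive lag means member B's signal follows member A's.
* **Ties**: smallest |lag| wins; negative before positive.
* **All-negative windows**: the signed maximum is recorded and flagged
  (`all_negative`) instead of being dropped — silently discarding windows
  would bias time courses upward.
* **Undefined lags** (zero-variance slices) are skipped; a window is NaN
  only if every lag is undefined.
* Lags are taken *within* the window (overlap `W − |ℓ|`), matching the
  exhaustive double-loop oracle the estimator is tested against (equality to
  1e-12 on random pairs).

`peak_timecourse` averages defined peaks per window start within
condition × pair-type groups, with a ±1.96·SE band; single-pair groups get
an undefined CI and `n_pairs = 1` rather than a fake zero-width band.

Note that peak-picking over a lag grid is positively biased under the null
(max of several near-independent correlations), the more so the shorter the
window; real-vs-pseudo comparisons are unaffected because both arms share
the bias.

## Pseudo-pair null

`scope="any"` pairs every two same-condition participants who were never
real partners, crossing all their per-round recordings (full enumeration by
default — the very large t-test degrees of freedom such analyses report
imply exactly that — with a seeded subsampling cap for tractability).
`scope="round_matched"` pairs, within each round, the participants not
paired with each other *in that round*; two people who met in a different
round still count, following the "not paired at that moment" logic.
Defaults: `any` for smile studies, `round_matched` for HR studies. Pseudo
pairs never duplicate a real dyad-round, and cross-session pairings can be
disabled (`within_session_only`) where session timing matters.

## Inference

Standardization scales pre *and* post by the pre-exercise mean and SD,
pooled across conditions (per-condition scaling available by flag);
post-only variables are z-scored. Dyad change scores average (post − pre)
over the two members; dyads with a missing member are excluded and logged.

OLS fits are closed-form with classical SEs and t-based two-sided p-values
on n − k df; rank-deficient designs raise with the offending columns named.
Perfect fits are flagged rather than reporting misleading zero SEs. The
dyadic mixed models use variance components over a single grouping to
express crossed random intercepts (participant, dyad, partner, round) via
REML; when a fit fails to converge or a component's variance collapses, the
worst-performing intercept is dropped and the model refitted, with the
pruning path recorded in the fit's metadata — the model reports what it
pruned instead of guessing the "right" random-effect set. Inference on
mixed-model fixed effects is Wald-z. On small simulated studies the full
type × condition × mean-level interaction model can have empty cells; the
pipeline then falls back to the additive model and labels it as such.

Real-vs-pseudo tests are pooled-variance (Student) two-sample t-tests —
matching the df convention `n₁ + n₂ − 2` such analyses report — with Welch
available by flag; the per-test threshold is α/m over the six canonical
contrasts (real vs pseudo within each of three conditions; real-pair
differences between condition pairs), giving 0.05/6 ≈ 0.008. HR change
(last − first sample, bpm) gets a per-condition intercept-only model with a
participant random intercept when anyone participated repeatedly; with
single participation it reduces exactly to the one-sample t-test. For the
default decay (amp A, time constant τ, last sample at T′) the expected
change is `A·(e^(−T′/τ) − 1)` ≈ −9.8 bpm for A = 10, τ = 30 s, T′ ≈ 120 s.

## Numerical and test-design choices

* Determinism: one study seed expands into counter-based substreams keyed by
  stage and dyad id, so per-dyad signals are reproducible independently of
  iteration order and whole runs are bit-identical (manifest carries a
  config hash). CSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write→read is lossless.
* Problem sizes: module tests use studies of 6–10 participants; the
  statistical acceptance checks use 200 dyads per coupling level, 500–30,000
  uncoupled pairs for null calibration, and 400 replicates of 200 dyads for
  slope recovery. 400 replicates (rather than the minimal 200) keep the
  Monte-Carlo SE of the CI-coverage estimate (~0.011) small against the
  acceptance band [0.90, 0.98]; with 200 replicates a perfectly calibrated
  estimator leaves that band about one run in ten.
* The shared-trend prewhitening check runs at 1 Hz over the 2-min record
  (120 samples). This is deliberate: for *independent* length-n residual
  pairs, mean |r| concentrates near √(2/(π(n−1))) — about 0.105 at the HR
  study's native 60 samples, i.e. above the 0.1 bound the check enforces
  even for perfect whitening, but ≈ 0.073 at 120 samples, where the bound
  genuinely separates removed from unremoved trend.
* Scenario parameters for that check (AR coef 0.5, innovation SD 1 bpm,
  decay amp 10 bpm, τ 30 s) make the shared trend carry ~80% of raw
  variance, satisfying the check's premise that raw |r| exceed 0.8.

## Limitations

* The generator reproduces the structure the estimators assume, not real
  sensor output: no tracker noise or dropout, no motion artifacts, no
  respiratory sinus arrhythmia, no circadian or session-order drift.
* Mimicry is one-step (responses do not cascade), and coupling is constant
  within a recording; time-varying coupling would be needed to study WCLC's
  temporal resolution itself.
* Mixed-model p-values are Wald-z, not Satterthwaite/Kenward–Roger; at the
  cluster counts simulated here the difference is small but real for tiny
  studies.
* The pseudo-pair null shares the task but not the *moment* under
  `scope="any"`; genuinely time-locked task structure (e.g. synchronized
  instructions) is only controlled by `round_matched`.
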