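# Methods

This note documents the models, algorithms and numerical choices behind
beatsync, and what the synthetic-data tests do and do not establish
about real recordings.

## Data model

A trial is a 3-axis acceleration trace, nominally 100 samples/s and
115 s long for paced trials (120 s for self-paced production), recorded
from the trunk (bouncing) or the forearm of the dominant hand
(clapping). Acceleration is represented about a zero baseline
(gravity-removed): every statistic in the pipeline depends only on
relative dynamics, so the constant component carries no information.
The stimulus set is six musical excerpts plus a metronome, the merengue
and metronome each at two tempi (8 paced trials per movement type);
tempi span 116–132 BPM, i.e. inter-beat intervals (IBIs) of 455–517 ms.
Each stimulus carries a beat-saliency z-score, and the musical stimuli a
familiarity z-score, from independent rating panels; these are consumed
as data.

## Event extraction

The first 10 s of every trial are discarded (orientation transient),
leaving 105 s. Events are detected on the full trace and trimmed to the
analysis window afterwards, so the filters see no artificial boundary at
10 s.

*Bouncing.* The vertical axis — auto-detected as the axis with maximal
variance in the 0.3–5 Hz movement band, overridable — is band-passed
(4th-order Butterworth, zero-phase) and local minima are taken as
maximal knee flexion, with minimum separation 0.4× the expected movement
period and prominence ≥ 0.5× the filtered signal's SD.

*Clapping.* Each mean-removed axis is high-passed above 10 Hz and
correlated with a unit-norm template of the high-passed impact transient
(biexponential, 1 ms rise / 30 ms decay); the per-axis matched scores
are combined into a resultant detection score. Peaks must exceed the
score median by 4 robust (MAD-based) noise SDs, clear a relative floor
of 0.2× the maximal score, and be separated by a 150 ms refractory
window. The matched filter integrates the transient's energy across
samples and axes; simple amplitude thresholding of the rectified
high-passed signal loses most of the transient's energy below the
filter corner and cannot separate impacts from sensor noise at
realistic noise levels. The relative floor handles noiseless traces,
where the robust noise estimate collapses and sub-transient wiggles
would otherwise be detected; it assumes impacts of broadly similar
magnitude within a trial, which holds for steady clapping.

All constants live in `AnalysisConfig`. Trials with fewer than 8 events
are unusable.

## Metrical level

The produced movement frequency is the maximal peak of the raw
periodogram of the mean-removed movement axis within 0.2–4 Hz. No
window or padding is applied: at 105 s the native resolution
(~0.0095 Hz) resolves the ±10 % level tolerance at every relevant
frequency, including the four-beat level near 0.5 Hz. A spectrum whose
peak is less than 20× the in-band median power is indeterminate. The
threshold is set against the statistics of raw periodogram bins, which
are exponentially distributed: for pure noise the in-band maximum falls
near ln(n_bins)/ln(2) ≈ 9–14 times the median, while genuine periodic
movement exceeds the floor by three or more orders of magnitude.

Levels are assigned by relative deviation |f − f_b/L|/(f_b/L) ≤ 0.10 for
L ∈ {1, 2, 4}, the smallest qualifying L winning (ties are only possible
at absurd tolerances). The level is checked on each half of the analysis
window; disagreement marks the trial unstable. This two-half rule is one
defensible operationalization of "the chosen level was not constant";
a time-resolved tempogram is out of scope.

Four-beat trials are not scored for synchronization. They receive a
whole-trial Rayleigh test on a 4·IBI circle, and a participant whose
determinable trials are majority four-beat with a majority of those
period-matched is excluded as a four-beat mover — consistent tempo
matching at a level not comparable to the rest of the cohort.

## Circular statistics

Angles: θ_i = 2π·(tᵢ mod L·IBI)/(L·IBI), with the unrounded IBI.
R is the mean resultant length; V = 1 − R (clamped into [0, 1] against
roundoff); the Rayleigh statistic is z = nR² with the small-sample
p-value approximation p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)),
capped into (0, 1]. The test requires n ≥ 4; empirical type-I error at
n = 30 is within [0.04, 0.06] at α = 0.05 (checked over 5000 uniform
samples). α = 0.05 throughout; the choice is conventional.

Beat-level trials are split into 4 consecutive equal-count segments,
two-beat trials into 2; a remainder r puts one extra response into each
of the first r segments. Segmentation catches trials that lose the beat
partway or find it late.

Bimodality (responses alternating between two phases) is flagged by
axial doubling: with R₂ the resultant of 2θ, a trial is bimodal when the
Rayleigh test on 2θ is significant and R₂ − R ≥ 0.2. The margin demands
that two antipodal lobes dominate a single lobe; both constants are in
config. This is an operationalization of a judgment the source data's
analysts made by inspection, and its constants were not calibrated to
any reported bimodal-trial count.

## Classification rules

Trial: bimodal → excluded; else normal iff every segment's Rayleigh test
is significant, else poor. Participant: poor synchronizer iff ≥ 3 of the
6 music trials of either movement type failed, where off-tempo and
unstable trials count as failures (a participant who matches no tempo at
all must not escape the rule by never reaching circular scoring);
bimodal overload (≥ 3 of 8 trials in a movement) and four-beat movers
are excluded first. The two merengue and two metronome tempi count as
separate trials, which is what makes 6 music and 2 metronome trials per
movement.

SR = −log₁₀ max(V, 10⁻⁶): the circular variance of well-synchronized
trials is log-normally distributed, and the sign flip makes higher mean
more regular. The 10⁻⁶ floor caps SR at 6 for numerically perfect
trials. Base 10 is a convention; any base gives the same ordering.
Group summaries weight each trial's SR by its response count, since a
beat-level trial holds twice the responses of a two-beat trial.

Trial accounting reports the poor percentage over classifiable trials
only: poor / (total − level-excluded − bimodal) × 100, one decimal.

## Self-paced production

Tempo is the mean of the 29 IRIs among the first 30 events ("events",
not intervals, taken literally); regularity is CV = sample SD / mean of
the same IRIs (the n−1 SD; the population-SD difference is ~2 % at this
n and immaterial). The CV is log-normalized like V, with the same floor.
The raw IRI SD is exposed as a secondary output; CV is the default
because it is the standard scale-free measure. Normative cut-offs are
mean ± 2 SD of the normal-synchronizer reference, rounded to the nearest
integer for integer-scored tests.

## Profile clustering

Success profiles are per-participant proportions of normal trials in
(bounce, clap) × (music, metronome); bimodal and four-beat trials leave
the denominator, failed trials stay in it, and a condition with no
classifiable trials is missing rather than zero. Clustering is
two-stage: Ward-linkage agglomerative clustering cut at k = 2…6, k
chosen by maximal mean silhouette (the source analysis reports an
"ideal" k without naming a criterion); then MacQueen's sequential
k-means — points visited in seeded random order, running-mean centroid
updates on every reassignment, never emptying a cluster — initialized at
the hierarchical clusters' means. At convergence each centroid equals
the mean of its members (verified to 1e-9). The seed only breaks visit
order; with separated clusters the result is deterministic.

The rank-sum test is the pair-count U (a < b pairs plus half-ties) with
a two-sided normal approximation and tie-corrected variance; it agrees
exactly with brute-force pair counting, and complements scipy's U
convention as U = n₁n₂ − U_scipy.

## Synthetic cohorts: what they emulate, and what they don't

Event timing: t follows a beat grid at period L·IBI·(1 + ρ), where ρ is
a tempo mismatch; the period follows a random walk with increment SD
`drift_sd_ms`; each event gets independent Gaussian jitter
(`phase_noise_sd_ms`), making the IRI SD √2× the jitter SD; and with
probability `bimodal_mix` an event is displaced by a fixed circle
fraction (bimodal phase mixture). Traces render bouncing as a
raised-cosine acceleration (continuous, minima at maximal flexion — no
kinematic model of the body is attempted) and clapping as biexponential
impact transients plus a low-amplitude (0.3×) forearm-swing oscillation
that carries the movement fundamental in the spectrum; white Gaussian
sensor noise is added to all axes. Defaults mirror the study conditions:
115 s paced trials, 120 s self-paced, 100 Hz, 8 stimuli × 2 movements
per participant.

Cohorts mix normal synchronizers (|ρ| ≤ 0.005, jitter 2 % of the circle)
with four poor archetypes patterned on the observed profile clusters —
global failure; music-only failure; graded (bounce worse than clap,
music worse than metronome); bounce-only failure — whose failing trials
get |ρ| ∈ [0.05, 0.09] and 8 % jitter. That mismatch keeps the produced
frequency inside the level tolerance while the relative phase sweeps the
circle, defeating the Rayleigh criterion: the trial fails *as a
synchronization failure*, not as an off-tempo exclusion. Within music,
the lowest-saliency stimuli fail first. These parameters are free
modeling choices: no quantitative timing distributions for real poor
synchronizers exist, so the archetypes are plausibility constructions,
not estimates of any real cohort — passing recovery tests shows the
pipeline's decision rules are consistent and well-calibrated on data
satisfying its assumptions, not that real poor synchronizers are
classified with the same accuracy. Real recordings also contain
movement-artifact nonstationarity, sensor saturation, orientation drift
and broadband motor noise that the generator does not model.

Determinism: every generator is a pure function of its parameters and
seed; per-trial seeds derive from the cohort seed via SeedSequence, so
identical seeds give byte-identical traces.

## Problem sizes

The classification acceptance check uses 60 participants (40 normal,
20 poor; 960 trials), large enough that a single misclassification
would drop sensitivity or specificity below 0.95. Rayleigh calibration
uses 5000 replicates of n = 30 (Monte-Carlo SE ≈ 0.003 on the rejection
rate). Cluster recovery plants 5 profiles per archetype at noise SD
0.03, roughly a tenth of the smallest inter-centroid distance.

## Known limitations

- No phase (asynchrony) analysis: the analysis is period-matching only,
  by design, and rotation invariance of all circular statistics is
  enforced by test.
- No time-resolved tempo tracking; the two-half stability rule cannot
  localize when a level switch happened.
- The bimodality rule's constants (α, 0.2 margin) are conventions, not
  fitted values; borderline mixtures (offset far from π, mix far from
  ½) lose power because axial doubling targets antipodal lobes.
- The hierarchical regression of regularity on movement type and beat
  saliency is out of scope; condition summaries are descriptive.
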