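# Methods

## The task and the analysis problem

The gradual-onset continuous performance task (gradCPT) probes sustained
attention with a continuous stream of cross-fading stimuli: each stimulus
fades in over one stimulus onset asynchrony (SOA) while its predecessor
fades out, so there is never an abrupt onset to anchor a response. Frequent
Go stimuli (90%) require a button press; rare No-go stimuli (10%) require
withholding. Two standard variants are supported: an auditory one at SOA
1.6 s (250 trials per 400-s run) and a visual one at SOA 0.8 s (500 trials
per run).

Because the stimulus stream is continuous, the analysis has to decide which
trial each keypress answers, classify trials into hits, misses, false
alarms (FA) and correct rejections (CR), summarize performance
(hit/FA rates, d′, median RT), and quantify the slow waxing and waning of
attention through the variance time course (VTC): the per-run absolute
z-scored RT series, whose dominant spectral frequency (~0.03 Hz in adults)
indexes the rhythm of attentional fluctuation. For event-related fMRI the
package also builds the design-matrix ingredients tied to these behavioral
quantities, and the group-level statistics are Pearson correlations with
default Bayes factors and credible intervals.

## Response assignment

The response window of trial *n* (onset `t_n`) opens at 70% of the
appearance phase and closes at 40% of the disappearance phase:
`[t_n + 0.7·SOA, t_n + 1.4·SOA)`. All presses inside a window belong to
that trial; with several presses, the earliest defines the RT and the rest
are discarded (the shortest-RT rule — later presses in the same window are
most plausibly anticipations of the next stimulus, which have their own
window). Presses in the inter-window gap `[t_n + 1.4·SOA, t_n + 1.7·SOA)`
are ambiguous between adjacent trials: they go to trial *n* if it is still
unanswered, else to trial *n+1* if unanswered, else they are discarded.
All intervals are half-open so a boundary press belongs to exactly one
region. Presses before the first window or after the last trial's gap are
ignored with a logged warning.

Consequences worth knowing: an RT attributed through a trial's own window
or gap lies in `[0.7·SOA, 1.7·SOA)`; a gap press handed forward to the next
trial yields an RT in `[0.4·SOA, 0.7·SOA)`. Every input press is assigned
to at most one trial, and the per-run log records assigned, surplus,
ambiguous and ignored counts so the assignment is auditable.

The test suite checks this implementation against an independently written
brute-force oracle (linear interval scan plus explicit case analysis) on
thousands of randomized small runs.

## Performance metrics

d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate), with each rate clipped to
`[1/(2N), 1 − 1/(2N)]` (N = trials of that category) — the standard
correction that keeps d′ finite at ceiling or floor. Rates are pooled over
a session's runs before the transform, not averaged per run. Median RT uses
observed responses only (hits and FAs); interpolated RTs exist solely for
the VTC. Note that d′ of group-mean rates is not the group mean of
per-participant d′ (Jensen's inequality): for mean rates (0.741, 0.238) the
former is 1.359 even where a cohort mean may print higher.

## Variance time course and fluctuation frequency

Per run: response-absent trials (misses, CRs) are filled by linear
interpolation between the nearest observed RTs (edge gaps copy the nearest
observed value); the full series is z-scored per run with the sample SD
(n−1); the VTC is |z|. The raw VTC is smoothed with a Gaussian kernel of
FWHM 7 s (σ = FWHM / (2√(2 ln 2)) ≈ 2.97 s, i.e. σ/SOA trials), truncated
at ±4σ and renormalized at the series edges so a constant series passes
through unchanged. The Gaussian transfer function e^(−2π²σ²f²) keeps >80%
gain at 0.032 Hz while suppressing trial-rate noise (<5% at 0.2 Hz), so
smoothing does not displace the band of interest.

The dominant fluctuation frequency is our own estimator construction (the
quantity itself, not the method, is what is standardly reported): per run
the mean-removed smoothed VTC's DFT amplitude spectrum on the grid
`k/(N·SOA)`; spectra averaged across runs; argmax within the search band
(default 0.005–0.10 Hz, configurable). For a 400-s run the frequency
resolution is 0.0025 Hz. Alternatives (unsmoothed VTC, other bands) are a
config key away.

## Synthetic observer

The generator defines the study conditions under which the pipeline is
validated. A deterministic latent state `s(t) = sin(2π·f0·t + phase)`
modulates the per-trial RT-noise SD, `σ_n = σ0·(1 + mod_depth·s(t_n))`,
and optionally the miss and commission probabilities. Go trials emit a
press at `onset + max(0.05 s, mu_rt + Normal(0, σ_n²))` unless missed;
No-go trials emit a commission press under the same RT law with the
state-dependent probability; misses and CRs emit nothing (they are exactly
the trials the VTC stage must interpolate). A sinusoid rather than a
stochastic (e.g. Ornstein–Uhlenbeck) latent process makes the
frequency-recovery check sharp: the VTC spectrum must peak at `f0`.

Defaults emulate the published task statistics: visual variant mu_rt =
0.625 s, miss rate 3.6%, FA rate 18.8%; auditory variant mu_rt = 1.558 s,
miss rate 25.9%, FA rate 23.8%; f0 = 0.032 Hz. The baseline noise SD
(0.08 s visual, 0.14 s auditory) is not separately published per run; it
was set once so that most presses fall inside their trial's assignment
window at the given mu_rt, which a practitioner would regard as the
realistic regime. What the generator does not emulate: drift-diffusion
response dynamics, post-error slowing, learning/fatigue trends, or
stochastic frequency drift of the attentional rhythm — so passing tests
demonstrate the pipeline's correctness and sensitivity under the assumed
narrowband structure, not cognitive realism of real observers.

## fMRI regressors

The canonical double-gamma HRF is `g(t; 6, 1) − g(t; 16, 1)/6` (gamma
densities parameterized by delay and dispersion), sampled on [0, 32 s] and
normalized to unit peak; it peaks near 5 s with a late undershoot. Stick
regressors place unit impulses at each outcome class's trial onsets on a
fine grid (dt = 0.1 s, ≤0.3% peak error), convolve with the HRF, and sample
at scan times `t0 + k·TR` with TR = 2 s and t0 = 10 s (five discarded
equilibration volumes). The VTC regressor weights the impulses by the raw
(non-smoothed) VTC values — the amplitude-modulated variant — with the
hemodynamic delay supplied entirely by the convolution; no extra lag is
added. The high-pass basis is the discrete-cosine set with periods ≥128 s
(`K = floor(2·N·TR/cutoff)` terms, e.g. 6 for 200 scans). GLM estimation,
prewhitening and inference are out of scope; the design-matrix tables are
written for external tools.

## Bayes factors and credible intervals

For a Pearson correlation, BF10 integrates the exact nuisance-free sampling
density of r — proportional to
`(1−ρ²)^((n−1)/2) (1−ρr)^(−(n−3/2)) ₂F₁(½, ½; (2n−1)/2; (1+ρr)/2)` —
against a stretched-beta prior on ρ over (−1, 1); width κ = 1 (the common
software default) makes the prior uniform. Quadrature is adaptive
(`scipy.integrate.quad`, relative tolerance 1e-10) with the likelihood
ratio evaluated in log space; |r| within 1e-12 of 1 returns an
infinite-evidence sentinel. The credible interval inverts the posterior CDF
on an 8001-point grid. The paired-t Bayes factor is the JZS form: a
noncentral-t marginal likelihood under a Cauchy(0, √2/2) prior on the
standardized effect, two-sided. Evidence categories use the conventional
cut points: BF ≥ 10 strong H1, 3–10 moderate H1, 1/3–3 absent, 1/10–1/3
moderate H0, ≤ 1/10 strong H0.

The quadrature route is cross-checked in tests against a Monte-Carlo
estimate of the same marginal likelihood (prior sampling) and against the
closed-form Jeffreys approximation for moderate r.

## Numerical and design choices

- i.i.d. No-go draws at rate 0.1 by default; an `exact_counts` flag places
  exactly round(rate·N) No-go trials for count-balanced designs.
- "No repeated stimuli" is implemented as no immediate exemplar
  repetition; with 10 exemplars and 250–500 trials, full-run uniqueness is
  impossible.
- Sample SD (n−1) in z-scoring; O(1/n) relative to the population
  convention, negligible at 250–500 trials.
- Degenerate inputs raise rather than propagate: zero RT spread, fewer
  than 2 observed RTs, empty sessions, unresolvable frequency bands.
- Determinism: every stochastic component takes a seed; the pipeline
  spawns per-run child seeds from one root via `numpy.random.SeedSequence`,
  so fixture directories are byte-reproducible.

## Problem sizes used in validation

The recovery checks simulate 4 × 400-s visual runs (2,000 trials) per
observer and repeat over 10 observer seeds; the estimator-bias property
uses 50 seeds at 2 runs each; the assignment oracle comparison uses 1,000
randomized runs of ≤20 trials. These sizes give sub-bin frequency accuracy
and tight binomial checks while keeping the whole suite in a few seconds.

## Known limitations

- The fluctuation-frequency estimator is one defensible construction; the
  published quantity's exact estimator (smoothed vs raw, per-run vs
  concatenated, spectral method) is not specified in the source
  literature, so cross-study comparisons of the estimate should state the
  construction.
- The paired-t Bayes factor is two-sided by default; published one-sided
  values will differ by roughly a factor of two at moderate t.
- Gap-press resolution when both adjacent trials are already answered
  (discard) is a convention; alternative conventions would differ on a
  small number of presses per run, all of which are counted in the log.
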