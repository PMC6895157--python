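# Methods

This note documents the models behind `herdvoice`, the parameter choices
that matter, and what the synthetic data do and do not establish.

## The scientific design

The analysis asks whether individual identity is encoded in cattle
high-frequency calls and whether that encoding survives a change of
emotional valence. The design is: measure 21 source-related and nonlinear
acoustic parameters per call; train a stepwise discriminant function
analysis (DFA) on the calls of one putative valence with the individual as
the grouping variable; report resubstitution and leave-one-out accuracy
within that valence and *transfer* accuracy on the opposite valence; test
every correct-classification count against the group-size chance
expectation 100/g % with an exact two-tailed binomial test; and confirm the
multivariate individual effect with a one-way MANOVA (Pillai's trace) per
valence plus univariate follow-up ANOVAs. Contexts map to valence as:
oestrus and feed anticipation → positive; feed denial, physical isolation
and physical+visual isolation → negative.

## Synthetic herds

Real datasets of this kind are rarely deposited, so the generator is a
first-class, tested component rather than a fixture. It emulates the
features the inference depends on:

- **Stable individual signatures.** Each individual's 21 parameter means are
  drawn once from a population hyperprior (`params.DEFAULT_POPULATION`:
  per-parameter population mean, between-individual SD, within-individual
  SD). The same signature drives that individual's calls in both valences.
- **Valence shifts.** A `ValenceShift` adds per-parameter offsets and scales
  the nonlinear-phenomena rates. The default negative-valence shift makes
  calls slightly longer, higher, noisier, and ~1.55× richer in phenomena
  (mirroring the field observation that phenomena occur in ~80% of positive
  but ~93% of negative calls). A zero shift leaves signatures untouched.
- **Unbalanced sampling.** Per-individual call counts come from shared
  gamma weights with a floor of one call per individual per valence; the
  default preset totals 170 positive + 163 negative = 333 calls from 13
  individuals.
- **Two routes.** `generate_feature_table` draws the 21-vectors directly
  from per-individual normals (diagonal within-individual covariance by
  default; a full covariance may be supplied) — milliseconds, used for all
  statistical work. `generate_dataset` synthesizes waveforms so the
  measurement chain itself can be validated.

Waveform synthesis is additive-harmonic and source-only — no vocal-tract
filter, since the analysis deliberately measures source-related parameters
(formants are poorly resolved at F0 near or above 1 kHz). The F0 contour
rises from a start value to a peak ~35% into the call and falls to an end
value, plus sinusoidal FM and a slow multiplicative drift scaled by the
jitter target; at least six harmonics with exponentially decaying amplitudes
sit on it. The envelope carries sinusoidal AM (depth set from the dB
extent), a shimmer-scaled slow modulation, 20 ms raised-cosine fades, and a
white-noise floor scaled by the entropy target. Nonlinear phenomena are
injected as non-overlapping segments placed uniformly at random —
subharmonics add components at odd multiples of F0/2; sidebands multiply by
a 110 Hz modulator; chaos cross-fades to band-limited noise — and frequency
jumps are instantaneous F0 steps (×1.25 / ×0.78, alternating) each followed
by a 10 ms silent gap. Every injected segment is logged in the call's
annotation, and the realized parameter values are stored as ground truth
(F0 statistics are taken over the contour outside chaos segments and jump
gaps, where a tracker can legitimately measure them).

**Calibration of the defaults.** The between-individual SDs are fixed so
that, at the study scale, stepwise DFA with leave-one-out cross-validation
classifies roughly 50–70% of calls correctly (measured ≈63% mean over
seeds) — clear but imperfect individuality, the regime the design is about.
Overlapping phenomena, vocal-tract resonances, background noise and
recording-channel variation are *not* modelled, so passing tests show the
statistical machinery and the measurement chain are correct, not that the
extractor would perform identically on field recordings.

## Feature extraction

- **Duration** is measured after trimming at −40 dB re peak (configurable).
- **Pitch**: frame-wise normalized autocorrelation (10 ms hop, window
  ≥ 3 periods at the floor, Hann window with a window-autocorrelation
  correction), up to four candidates per frame plus an unvoiced candidate,
  decoded by a Viterbi pass with an octave-jump cost (0.35/octave) and
  voiced↔unvoiced switch cost. Candidate strength includes a small penalty
  (0.12 per octave below the ceiling) so that a call with strong
  subharmonics is still tracked at F0 rather than F0/2. Floor and ceiling
  are set per individual and held fixed across both valences of that
  individual.
- **F0 var / AM var** sum |Δ| of the contour between *consecutive* voiced
  frames (gaps are not bridged) divided by call duration.
- **FM/AM rate and extent**: alternating extrema of the lightly smoothed
  contour with a minimum excursion (10 Hz for FM, 1.5 dB for AM), counted
  per contiguous voiced stretch so unvoiced gaps cannot fake cycles; rate =
  half the number of alternations per second, extent = mean interior
  peak-to-trough excursion. The inflection index counts reversals whose
  excursion exceeds one third of the contour range (threshold configurable;
  this index is under-specified in common usage and our definition is one
  reasonable reading).
- **FM extent is reported in Hz** (`fm_extent_hz`). Parameter tables in this
  literature sometimes print "FM extent (dB)"; a frequency-modulation
  excursion is a frequency quantity, and we treat the dB unit as a typo.
- **Jitter/shimmer** use period-synchronous peak marks guided by the pitch
  contour: mean absolute cycle-to-cycle difference of period (amplitude)
  over its mean, in percent. **Harmonicity** is the mean of frame-wise
  10·log10(r/(1−r)) with r the corrected autocorrelation maximum at the
  pitch period (6-period analysis windows; r is clipped below 1 so a
  perfectly periodic signal reports a large finite HNR).
- **Wiener entropy** is the frame-wise spectral flatness
  (geometric/arithmetic mean of the power spectrum, 1024-sample frames,
  9-bin spectral smoothing so broadband noise approaches 1), averaged over
  frames above the energy floor. It is 0-ish for a pure tone and >0.9 for
  white noise, and is invariant to overall gain.
- **Nonlinear phenomena are annotation-driven.** In field practice they are
  judged by eye from spectrograms; the percentages are the union length of
  each phenomenon's intervals over the measured duration, and jumps are a
  count, not a percentage. No automatic detector sits on the analysis path.
- **Missing data**: a call whose pitch, periodicity or intensity measures
  cannot be computed is excluded listwise (logged); the statistics only see
  complete 21-parameter vectors.

## Discriminant analysis

Scatter matrices are computed once; Wilks' Λ for any variable subset is
det(W_SS)/det(T_SS) over the sub-blocks, which keeps the stepwise search
cheap. The partial F for adding a variable to p already-entered ones is
((Λ_old/Λ_new)−1)·(n−g−p)/(g−1); entry requires F ≥ 3.84, and after each
entry any included variable whose removal F has fallen below 2.71 leaves.
Ties break lexicographically (logged).

Canonical functions come from the eigen-decomposition of W⁻¹B, scaled to
unit pooled within-group variance; standardized coefficients multiply raw
ones by the pooled within-group SDs. Function significance uses Bartlett's
chi-square, −(n−1−(p+g)/2)·ln Λ_residual, at α = 0.05.

Classification uses Fisher linear scores μᵀΣ⁻¹x − ½μᵀΣ⁻¹μ + ln π with the
pooled covariance (linear DFA only). Σ⁻¹ is a pseudo-inverse with a 1e-10
relative eigenvalue cutoff so rank-deficient leave-one-out folds degrade
gracefully. Priors default to training group sizes, and the overall percent
correct is total-correct/total-classified (both readings of "according to
the group sizes"); `priors="equal"` / `--equal-priors` switches to flat
priors. Leave-one-out refits means, pooled covariance and priors per fold
via exact moment downdates but holds the stepwise-selected variable set
fixed, matching the classical procedure; nested reselection per fold is
possible by re-running selection externally. The binomial test is exact and
two-tailed by the minimum-likelihood convention (sum of all outcome
probabilities not exceeding the observed one), with the tail-doubling
variant selectable.

**Null calibration and priors.** With proportional priors, leave-one-out on
a pure-noise herd is measurably pessimistic — the left-out call's own group
loses both prior mass and the pull of its mean, and null LOO accuracy falls
visibly below 100/g (a known small-sample property of cross-validated LDA,
strongest when few variables are used). The null-calibration tests
therefore use a balanced herd with equal priors and the full 21-variable
set, where the bias is negligible: null LOO accuracy centres on 7.69% and
the binomial test holds its nominal 5% type-I rate. Signal-regime analyses
keep the proportional-prior default.

## MANOVA and follow-ups

Pillai's trace V = tr(B(B+W)⁻¹) with the standard approximation
F = [(2n′+s+1)/(2m+s+1)]·V/(s−V), s = min(p, g−1), 2m = |p−(g−1)|−1,
2n′ = N−g−p−1, df1 = s(2m+s+1), df2 = s(2n′+s+1). For 13 groups and 21
responses these give df1 = 252 and df2 = 1776 (N = 170) or 1692 (N = 163).
Only Pillai's trace is implemented; calls are treated as independent within
individual (no repeated-measures structure), and the univariate follow-up
ANOVAs are uncorrected for multiplicity — both deliberate matches to the
classical workflow this package reproduces. Descriptives are mean ± SE
(SD/√n, ddof = 1) per individual × valence.

## Reproducibility and scales

One root seed drives everything; per-stage child streams are derived by
hashing the seed with a stage tag, so a change in one stage never perturbs
another. Identical configuration ⇒ byte-identical outputs.

Problem sizes used by the slow checks: parameter recovery uses 104
synthesized calls (13 × 8); the null calibration uses 500 replicates of a
13 × 24 balanced herd; the signal-regime check uses 50 study-scale seeds.

## Known limitations

- The pitch tracker is tuned for harmonic, high-F0 calls in low noise; it is
  not a general-purpose tracker for field recordings.
- Subharmonic segments can legitimately halve the perceived F0; the octave
  penalty keeps tracking at F0, which is the intended measurement but a
  modelling choice.
- The generator's diagonal within-individual covariance understates the
  parameter correlations real calls would show; supplying a full covariance
  is supported but no empirical covariance is shipped.
- Quadratic/regularized discriminant analysis and permutation-DFA
  (repeated-measures-aware) are out of scope.
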