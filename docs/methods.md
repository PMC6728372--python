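# Methods

## Task design

The arena is a 600 × 600 m plain with a centred 500 × 500 m explorable area,
four landmarks rendered at infinity (defaults: Mountain → N, Cathedral → S,
ClockTower → E, City → W; configurable) and four 40 × 2 m boundaries, two
with north–south long axes and two east–west, placed symmetrically 125 m from
the centre (the exact placement is configurable; only the categorical
structure matters downstream). The compass convention is N = +y, E = +x,
clockwise-positive rotations, so "right of heading" = heading + 90°.

Each boundary exposes two faces; the **allocentric boundary direction** of a
trial is the compass direction of the boundary from the participant (the
south face of a boundary is seen by someone standing to its south, for whom
the boundary lies north). Three paths per face put the boundary front, left
or right of the participant; front implies heading straight at the boundary,
left implies heading = boundary direction + 90°, right implies − 90°.
This gives 8 × 3 = 24 paths. A run repeats each path four times (96 trials),
twice with the cue object left of the path and twice right; the **allocentric
goal direction** is the heading rotated +90° (right cue) or −90° (left cue).
Trials last 8 s (2 s movement, 4 s blank, 2 s decision). Inter-trial
intervals are drawn uniformly from [0.5, 1.5] s (mean 1 s; whether the
original intervals were jittered is unspecified, so mild jitter was chosen
and the mean kept). Trial order is a uniform seeded permutation per run.
Runs start with a 10 s lead-in so the first trial's estimation window is
fully covered.

**Balance audit.** For each level of a factor the audit checks, per run:
equal left/right cue counts, equal left/right/front egocentric counts, equal
counts for the two boundaries serving that direction, and presence of all
four levels of the other factor. Note a structural property of this (and
any) ±90° goal assignment: the *joint* boundary × goal table is not uniform —
same-axis combinations occur at twice the rate of cross-axis ones
(8 vs 4 per run and level pair). Marginals, cue side, egocentric position
and textures are exactly balanced; the residual axis-level coupling matters
only when one factor's neural signal is very strong (see *Calibration*).

**Occupancy.** Exploration trajectories are binned on the 100 × 100 grid of
5 × 5 m bins over the explorable area (10,000 bins); each sample is weighted
by the time to the next sample (the last sample gets the median interval)
and the histogram normalised to 1. Each boundary face has a 40 × 5 m
proximity strip on its outward side, snapped to grid bins; fractions are
reported per allocentric direction (two strips each) and in total. Under
uniform occupancy the total is 8 · 200 / 250,000 = 0.0064.

**JRD.** The judgement-of-relative-direction set is all 12 ordered landmark
pairs; the clockwise disparity from facing to probe maps 90° → right,
180° → behind, 270° → left.

## Synthetic BOLD model

For each ROI and factor, four direction patterns are built as a shared
baseline plus `effect_amplitude` × four mutually orthonormal components
(the baseline is projected off their span, so all four patterns have exactly
equal norm and amplitude 0 collapses them to a single pattern). The neural
event of a trial is a boxcar over the stationary phase (2–6 s after onset)
convolved with the canonical double-gamma HRF (peak 6 s, undershoot 16 s)
and normalised to unit peak, sampled at volume acquisition midpoints;
planted amplitudes are therefore in peak-response units. Signal is the sum
of the boundary and goal patterns of each trial times its regressor —
additive and independent across factors, mirroring the orthogonalised design
logic.

Nuisance terms, all drawn independently of the planted amplitudes so that
equal seeds share noise exactly: cosine drifts with periods {890, 445, 297} s
(per-voxel random amplitude, SD 1.0, and phase) — all slower than the 128 s
cutoff so the high-pass demonstrably removes them; linear leakage of the
first two motion parameters into voxel baselines (per-voxel weights,
SD 0.5); an AR(1) process (φ = 0.3, stationary SD 1.0) plus white noise
(SD 0.5). Motion itself is a bounded Gaussian random walk (step SD 0.05,
clipped at ±50 steps). Defaults: 100 voxels per ROI (the order of magnitude
of high-resolution medial-temporal subfield masks), 28 participants, 3 runs
of 445 volumes at TR 2 s.

What the generator does **not** emulate: spatial autocorrelation between
voxels, physiological noise spectra, susceptibility dropout, inter-subject
anatomical variability, or attention/behaviour-linked amplitude
fluctuations. Passing recovery tests therefore shows the *pipeline* is
correct and unbiased, not that real data contain such signals.

## GLM

Order of operations: high-pass → confound regression (confounds filtered
identically) → per-trial GLM. The high-pass projects out a DCT-II basis with
K = ⌊2·T·TR / cutoff⌋ components (K = 13 at the defaults), restoring the
voxel mean; this implements the "periods slower than 128 s are removed"
contract rather than any particular scanner software's filter. In-band
attenuation: a 300 s cosine loses > 95% of its variance (phase-aligned
components; worst-case off-phase leakage is a few per cent), a 50 s cosine
keeps > 99%.

The motion model is the 24-regressor expansion: parameters, backward
differences (first sample 0), squares, squared differences. Residualisation
is per-voxel OLS against the 24 rows plus intercept; rank-deficient sets are
projected via the pseudoinverse (equivalent to dropping dependent rows) with
a warning.

Each trial's beta comes from its own 3-column design: an unconvolved boxcar
over the volumes whose acquisition midpoints fall in [onset + 6 s,
onset + 12 s) — exactly three volumes for on-grid onsets; jittered onsets may
give 3 ± 1, which is logged and accepted — plus a union boxcar of all other
trials' windows and an intercept. An intercept is included in every
per-trial model (the alternative of relying solely on preprocessing is not
stated anywhere; the intercept is harmless and safer).

## Decoding

Within each run, trials are grouped by the to-be-decoded label and the
within-label order randomly permuted, independently per run (seeded): the
positional average across runs then mixes unrelated values of every *other*
condition, weakening their contribution, which is the purpose of
condition-ordered averaging. The result is 96 samples, 24 per direction,
each the mean of one trial per run.

Accuracy is estimated with 3 outer stratified shuffle-splits holding out 20%
(20 samples, exactly 5 per class; three disjoint-from-training but possibly
mutually overlapping test sets, since three 20% folds cannot partition the
data). Inside each outer training set, a stratified 3-fold grid search over
C ∈ {1, 10, 100, 1000} picks the regularisation of a linear SVC (L2 penalty,
one-vs-rest); ties go to the smallest C (strongest regularisation). The
winning C is refit on the full outer-training set. Features are used as-is
(no per-feature standardisation) because betas already come from filtered,
residualized data; a `standardize` flag exposes the alternative.

## Group statistics

The group statistic is the mean of per-participant mean accuracies.
The BCa interval uses the standard bias correction (fraction of bootstrap
means below the observed mean) and jackknife acceleration; it is
cross-checked in the tests against an independent implementation
(`scipy.stats.bootstrap`). The Monte Carlo test shifts the sample to chance
(values − mean + 0.25), draws B = 10,000 bootstrap means of the shifted
sample as the null distribution, and reports
p = (#{null mean ≥ observed mean} + 1)/(B + 1), one-tailed, ties counted
against the alternative. The null distribution is a plain bootstrap of the
shifted values; BCa corrections adjust interval percentiles and do not
define a different resampling scheme, so they enter the reported CI, not the
null draw. The test is mildly anticonservative at n = 28 (measured type-I
rate ≈ 0.06 at α = 0.05 over 1500 null cohorts), as expected for a
bootstrap z-type test without a small-sample correction.

## Calibration of the planted effect

The default `effect_amplitude` is 0.6 peak-response units. The choice
balances two requirements at the 28-participant scale: the planted factor
must be recovered decisively (measured group mean accuracy ≈ 0.32–0.35,
Monte Carlo p ≈ 10⁻⁴), and the factor with amplitude 0 must stay at chance
(measured 0.244 ± 0.009 over 48 participants). Much louder amplitudes
(≈ 2.0, single-participant accuracy ≈ 0.85) break the second requirement:
the axis-level coupling in the design (above) lets a very strong boundary
code push goal decoding to ≈ 0.27–0.28. At realistic, group-level effect
sizes this leakage is unmeasurable.

## Problem sizes used in the tests

The stochastic suites use: 1500 null cohorts (type-I calibration),
1000 Gaussian replicates with B = 2000 resamples (BCa coverage — coverage is
insensitive to B at this scale; inference elsewhere uses B = 10,000),
one 28-participant dual-ROI cohort for the planted-signal dissociation and
one 28-participant null cohort for the chance-level check. The acceptance
script uses a 24-participant null cohort. These sizes give standard errors
comfortably inside the asserted tolerances.

## Known limitations

- Voxels are simulated independently; spatially correlated noise would slow
  but not bias the decoder.
- The beta estimator and the simulator share the canonical HRF family;
  HRF mismatch (real data) would attenuate but not bias recovered patterns.
- The three outer test sets are random 20% draws, so fold accuracies are
  correlated; only their mean is used downstream.
- With off-grid onsets the estimation boxcar may cover 2 or 4 volumes; the
  midpoint rule is kept deliberately rather than forcing 3.
- The shifted-null bootstrap test inherits the usual small-n
  anticonservatism quantified above; a t-test alternative is deliberately
  out of scope.
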