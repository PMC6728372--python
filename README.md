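# allodecode

Multivoxel pattern analysis of **allocentric boundary and goal direction**
from region-of-interest fMRI time series, packaged as a tested, reusable
pipeline with a synthetic-data generator so that every stage can be validated
against known ground truth.

## The problem

In a virtual arena surrounded by four global landmarks (one per cardinal
direction) and containing four elongated boundaries, every passively-viewed
trial simultaneously defines two world-referenced ("allocentric") directions:
the direction of the visible **boundary** relative to the participant
(N/S/E/W) and the direction of a cued **goal** (N/S/E/W, the heading rotated
±90°). Because the 24 approach paths counterbalance landmark views, egocentric
boundary position (left/right/front) and cue side, the two factors can be
decoded independently from the same trials. The scientific question is
whether a region's multivoxel activity patterns carry information about one
factor, the other, or both — e.g. boundary-vector-like coding without goal
coding.

## The pipeline

Per participant (3 runs × 96 trials, 445 volumes/run at TR = 2 s):

1. **Design** — build the arena, the 24 paths (8 boundary sides × 3
   egocentric positions) and randomised 96-trial run tables; audit the
   counterbalancing; BIDS-style events TSV output.
2. **Synthesis** — voxel × volume BOLD per ROI: planted per-direction
   patterns × HRF-convolved trial regressors + cosine drift + motion-coupled
   baselines + AR(1)+white noise; six-parameter motion traces.
3. **GLM** — 128 s cosine high-pass; regression of the 24-regressor motion
   model (parameters, differences, squares, squared differences); per-trial
   "Add"-model betas from an unconvolved boxcar spanning the three volumes
   6–12 s after trial onset (one model per trial: own boxcar + all-other-trials
   boxcar + intercept).
4. **Decoding** — trials condition-ordered and averaged across the three runs
   into 96 samples (24 per direction); linear SVC with L2 regularisation,
   nested cross-validation: 3 outer stratified 80/20 shuffle-splits, inner
   3-fold grid search over C ∈ {1, 10, 10², 10³}.
5. **Group inference** — per-participant mean accuracies → BCa bootstrap
   95% CI (B = 10,000) and a shifted-null Monte Carlo test against 25%
   chance: null sample = accuracies − group mean + 0.25,
   p = (#{null bootstrap means ≥ observed mean} + 1) / (B + 1); Bonferroni
   α/m for secondary ROIs.

## Worked example

```bash
python examples/04_group_inference.py
```

simulates 8 participants whose ROI carries a boundary-direction code
(amplitude 0.6) but **no** goal code, then decodes both factors and runs the
group test:

```
allo_boundary  group mean 0.300  95% BCa CI [0.256, 0.333]  p = 0.0049
allo_goal      group mean 0.273  95% BCa CI [0.219, 0.331]  p = 0.224
secondary-ROI Bonferroni alpha (3 ROIs x 2 factors): 0.0083
```

The planted factor is recovered (mean accuracy above the 25% chance level,
small Monte Carlo p), while the absent factor stays statistically at chance —
the dissociation logic the pipeline is built to test. The other examples
(`examples/01…03`) walk through the design audit, single-run beta recovery
and single-participant decoding.

A full run of the pipeline (simulate → GLM → decode → group) is available
both as a library call (`allodecode.run_all(RunConfig(), out_dir)`) and as a
CLI:

```bash
allodecode run-all --seed 1 --out runs/demo
allodecode simulate --n-participants 2 --seed 0 --out runs/cohort
```

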