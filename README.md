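# reciprsa

Analysis pipeline for a reciprocal partner-choice experiment: behavioral
statistics, cross-study neural pattern expression, and parcel-wise
representational similarity analysis (RSA), driven by a synthetic-data
generator that plants known behavioral and neural structure so every stage
can be verified by parameter recovery.

## What it does

The task crosses three reciprocal-efficiency conditions (A1S3, A1S1, A3S1 —
the label encodes the altruistic/strategic benefactors' payout multipliers)
with nine benefactor-cost levels. The pipeline implements:

- **`reciprsa.design`** — the factorial task structure and payoff
  arithmetic (pain reduction, benefactor receipt, relative self-payoff).
- **`reciprsa.simulate`** — synthetic ratings, choices/allocations, and
  voxel-level condition maps with planted motive-map loadings and planted
  parcel-level representational geometry, all recorded in a manifest.
- **`reciprsa.behavior`** — fixed-structure two-factor scoring of the six
  post-task ratings, per-condition mixed logistic choice regressions
  yielding the relative weight of communal concern, relative self-payoff
  comparisons (Mann-Whitney), Greenhouse-Geisser-corrected repeated-measures
  ANOVA, linear-trend contrasts, and paired comparisons.
- **`reciprsa.neural_expression`** — dot-product expression of condition
  maps on communal/obligation weight maps, min-max normalization, the
  neural relative weight of communal concern, and a within-participant
  condition-label permutation test (exhaustive for <= 6 participants).
- **`reciprsa.rsa`** — the four hand-coded cognitive dissimilarity models
  (general: 3/1/3, altruistic: 1/1/3, strategic: 3/1/1, linear: 1/2/3),
  per-parcel correlation-distance RDMs over the 27 condition cells,
  random-intercept mixed-model regression of neural on cognitive
  dissimilarity, Benjamini-Hochberg FDR across parcels, and an
  ROI-restricted mode.
- **`reciprsa.pipeline` / `reciprsa.cli`** — configuration, orchestration,
  and a structured, auditable run report.

## CLI

```sh
# generate a synthetic bundle (tables + NIfTI volumes + manifest)
reciprsa simulate --seed 1 --out run/bundle

# behavioral stage on trial/rating tables
reciprsa behavior --trials run/bundle/trials.csv \
    --ratings run/bundle/ratings.csv --out run/behavior.csv

# pattern expression with a 10,000-iteration permutation test
reciprsa express --maps run/bundle/neural --n-perm 10000 --seed 1 \
    --out run/expression.csv

# parcel-wise RSA, FDR 0.05, all four cognitive models
reciprsa rsa --maps run/bundle/neural \
    --models general,altruistic,strategic,linear --out run/rsa.csv

# everything at once, with a structured report
reciprsa run-all --seed 1 --out run/
reciprsa report --out run/
```

A YAML config (see `reciprsa.pipeline.RunConfig`) controls sample sizes,
generator parameters, and analysis switches (normalization scope,
beta-extraction mode, permutation count, alpha). Every run report echoes
the seed, a config hash, and the flags in effect.

## Notes

- The synthetic generator is a verification harness, not an empirical
  model: its logistic choice rule and orthonormal motive maps are fixture
  conveniences chosen to make planted parameters exactly identifiable.
- The mixed-model RSA uses a closed-form solution that is exact for the
  balanced shared-predictor design (verified against REML in the tests).
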