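# glottolearn

Are all languages equally easy to learn?  `glottolearn` operationalizes
*machine* learning difficulty of languages from text via lossless
compression, and tests whether difficulty is statistically associated with
speaker population size while controlling for the two classic sources of
non-independence in cross-linguistic data — shared ancestry (phylogeny)
and spatial proximity (Galton's problem).  It is aimed at quantitative
linguists and researchers in cultural/linguistic evolution who want a
fully testable, synthetic-ground-truth implementation of this analysis
design.

## What it computes

**Difficulty, two ways.**  A language model that compresses text well
predicts it well.  The package uses adaptive compressors as code-length
oracles (an internal PPM model with exact bit accounting, a pluggable
dictionary-coder backend) and derives:

1. *Learning-curve shape `b`* — compress a document incrementally,
   recording the rate `r_l` (bits/symbol over the first `l` symbols) at 20
   checkpoints, then fit the ansatz

       r_l = exp(h* + A · log(l) / l^b),    h = exp(h*)

   where `h` is the limiting entropy rate (difficulty of *predicting*)
   and `b` the convergence shape (difficulty of *learning*; higher `b` =
   easier).  Fitting is grid-initialized (`φ = 0.01, …, 10`, 1000 points)
   followed by exponential-parameterized nonlinear least squares.

2. *Rotation slope BLUP `µ`* — split a verse-parallel corpus into 10
   book-stratified folds; for each test fold, train on `f = 1..9`
   scheduled folds and record the incremental cross entropy
   `H_f = (R(T_f·T_test) − R(T_f)) / N_v` bits per test verse.  A REML
   mixed model of `log H_f` on `log f` (crossed language and test-fold
   intercepts, per-language random slope with unstructured covariance)
   yields per-language slope BLUPs `µ`; higher `µ` = faster learning.

**Association inference.**  With difficulty as outcome and log speaker
population as exposure:

- exhaustive mixed-model enumeration (2430 / 728 covariate subsets, each
  paired with a population-free reduced model), ΔAIC comparison, and
  frequentist model averaging `β_FMA = Σ ω_j β_j`,
  `ω_j ∝ c_j exp(−AIC_j/2)`;
- double-selection lasso over three nested candidate-control tiers (level
  indicators, geographic B-spline bases, environmental covariates), with
  Freedman–Lane permutation p-values;
- phylogenetic GLS under a Brownian-motion covariance from a language
  tree;
- spatial autoregressive error models with *two* inverse-distance weight
  matrices (geographic + lexical), moment-estimated, with permutation
  p-values.

**Synthetic world.**  A generator produces a Yule phylogeny, Markov text
sources with closed-form entropy rates and a controllable convergence-
speed knob, populations with a programmable effect `beta_true` on
learnability, nested metadata (families, macro areas ⊃ countries,
scripts, EGIDS), coordinates and distance matrices — so every stage of
the pipeline is verifiable against known ground truth.

## Worked example

End-to-end Study-2 analysis on a synthetic world (60 languages, 500
parallel verses, injected population effect −0.3 on learnability):

```console
$ glottolearn study2 --seed 42 --n-perm 500
beta_FMA  = -0.00067
beta_DS   = -0.00093 (p_perm = 0.0020)
beta_PGLS = -0.00110 (R2 = 0.735)
beta_SAR  = -0.00064 (p_perm = 0.0020)
```

All four estimators agree on the sign: larger populations are associated
with lower `µ`, i.e. slower learning, matching the sign of the injected
effect (the magnitudes are small because `µ` is a slope *deviation* in
log-bits; only sign and significance are comparable across methods).  The
permutation p-values (0.002 = smallest achievable at 500 draws) come from
Freedman–Lane residual permutation (DS) and exposure-permutation SAR
refits.

Replicate-world sign recovery:

```console
$ glottolearn benchmark --n-worlds 5 --n-languages 40 --n-verses 300 --seed 7
{
  "beta_fma": 1.0,
  "beta_ds": 1.0,
  "beta_pgls": 1.0,
  "beta_sar": 1.0
}
```

Every method recovered the injected negative sign in all five worlds.
Other subcommands: `glottolearn simulate` writes a world to disk in the
package's standard formats (verse-TSV corpora, metadata CSV, newick tree,
TSV distance matrices); `glottolearn study1` runs the learning-curve
route.  The same functionality is available as a library
(`glottolearn.pipeline.run_study1/run_study2/run_recovery_benchmark`).

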