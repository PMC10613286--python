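# Methods

`glottolearn` measures how difficult a language's written text is for a
language model to learn, and tests whether that difficulty is associated
with speaker population size once phylogenetic relatedness and geographic
proximity are accounted for.  This note documents the models, the
synthetic-data generator, the numerical choices, and the limits of what the
package's own validation can show.

## Learning difficulty from compression

All difficulty measures are built on ideal code lengths.  A lossless
compressor's model assigns each symbol a predictive probability
`p_t(x_t)`; the ideal (arithmetic-coding) code length of a text is
`R(X) = sum_t -log2 p_t(x_t)` bits, which differs from an actual coder's
output by O(1) bits.  Better prediction = shorter code = better language
model.

### The PPM code-length oracle

The internal model is prediction by partial matching over a fixed context
order `o` (default 2): prediction mixes the empirical distributions of the
contexts of length `o, o-1, ..., 0` and finally a uniform base
distribution, with method-C escapes — at a context with total count `n`
and `d` distinct successors, the escape probability is `d / (n + d)` and a
seen symbol gets `c(x) / (n + d)`.  Counts at every order are updated
after each symbol (full updates, no update exclusion).  The mixture sums
to exactly 1 over the base alphabet, so the code length is valid; this is
checked by exhaustive summation on small alphabets.  The base level is
uniform over the 4-byte code universe (`2^-32` per symbol) for
symbol-coded text, mirroring the convention that each distinct word or
sub-word type is replaced by one unique 4-byte code and the type table is
transmitted separately.

Two engines implement the same definition: a numba kernel over flat count
arrays when `sum_k V^(k+1)` cells fit a fixed budget, and a dict-based
fallback for large alphabets or orders, which also implements the optional
context-node budget (`memory_cap`, freeze-on-full: no new contexts are
allocated once the budget is reached; existing ones keep adapting).  Both
are validated against an independently written straight-line reference
evaluator to 1e-9 bits.

A dictionary coder (stdlib lzma at maximum preset) is the shipped external
backend; any callable mapping a byte stream to a bit count can be
registered, which is the hook for heavier neural compressors.  Symbol
*tables* are serialized as sorted two-column text and compressed with a
raw lzma stream using a 64 KiB dictionary: tables are a few hundred bytes,
and the maximum preset's ~64 MB dictionary allocation per call would
dominate the entire rotation design while compressing these payloads no
better.

### Study-1 difficulty: the learning-curve shape parameter b

Each document is compressed incrementally, recording the rate
`r_l = R(first l symbols) / l` at 20 checkpoints (every 5% of the
document).  The learning-curve ansatz fitted to these points is

    r_l = exp(h* + A * log(l) / l^b),      h = exp(h*), A > 0, b > 0.

`h` is the limiting entropy rate (bits/symbol, how hard the source is to
*predict*), and `b` is the shape parameter (how fast the rate converges to
`h`, i.e. how hard the source is to *learn*; larger `b` = easier).  The
additive form `h + A log(l)/l^b` is the first-order expansion of this
ansatz around the limit; the exponential form is what the fitting
procedure actually targets, and it is what the package uses as the forward
model throughout.

Fitting is two-stage.  For every `phi` on the grid `0.01, 0.02, ..., 10`
(1000 points), `log(r_l)` is regressed on `Phi = log(l)/l^phi` by OLS; the
grid point with the smallest RMSE among those with a positive slope
supplies starting values (a slope counts as positive only if it moves the
fitted line by more than 1e-10 over the observed `Phi` range, which
rejects constant curves whose slopes are pure rounding noise).  Stage two
minimizes the squared residuals of the exponential ansatz with a
Levenberg–Marquardt least-squares solver (`xtol = ftol = 1e-10`, ~200
evaluations per start).  Two starting points are tried —
`(beta_h, exp(beta_A), exp(phi_m))` for `(h*, A', b')`, which treats the
grid coefficients as natural-scale quantities, and the grid-consistent
initials `(beta_h, log beta_A, log phi_m)` (the grid fit *is* the ansatz
linearized at `b = phi`, so these place the optimizer at the grid
optimum) — and the lower-RMSE solution is kept.
This safeguarded initialization is deterministic and recovers noiseless
curves to better than 1e-3 relative in all tested configurations.
Documents whose grid search finds no positive slope are flagged and
excluded from downstream association analyses.

### Study-2 difficulty: rotation cross entropies and the slope BLUP mu

Verses are assigned to 10 folds, stratified by book (per-book fold sizes
within one of each other), with the assignment and the per-test-fold
training schedules (random permutations of the nine remaining folds)
shared across languages, so every language sees the same content in the
same order.  For `f = 1..9` training folds the incremental cross entropy
is

    H_f = ( R(T_f T_test) - R(T_f) ) / N_v        [bits per test verse]

with both `R(.)` terms including the compressed symbol-table size.  For
the PPM backend the implementation feeds folds into the model once per
rotation and encodes the test fold from a state snapshot; this is
bit-consistent with the from-scratch evaluation because PPM probabilities
depend only on observed counts.  At the BPE level the merge rules
(`floor(0.4 C)` merges, `C` = word types in the training data, ties broken
lexicographically) are learned from `T_f` only and applied to both
training and test text.  Negative `H_f` records — possible with real
byte-level backends on tiny inputs — are dropped with a warning.

The slope model is a linear mixed model of `log H_f` on `log f` with
crossed random intercepts for language and test fold and a per-language
random slope of `log f`, the language intercept and slope carrying an
unstructured 2x2 covariance, fitted by REML (ML would bias the slope
variance downward).  The per-language difficulty `mu` is the BLUP of the
slope deviation: a language that is still learning rapidly has a steeper
(more negative) individual slope and hence a lower `mu`; higher `mu` =
faster learning.

### The mixed-model engine

No installed Python fitter covers crossed random factors together with an
unstructured intercept–slope block, so the package ships a dedicated
engine (`lmm.py`): variances are profiled relative to the residual,
`sigma^2` and the fixed effects are profiled out analytically, and the
optimizer works on log-Cholesky covariance parameters with all linear
algebra routed through the q-dimensional Woodbury identity (cost scales
with the number of random-effect columns, not observations).  On the
single-factor random intercept+slope model — the special case statsmodels
MixedLM can express — fixed effects, the REML log-likelihood, the
random-effect covariance and the BLUPs agree with statsmodels to
measurement precision; the crossed cases are validated by simulation from
the generating model (slope-BLUP correlation > 0.9 at 50 groups).
Rank-deficient designs are fitted by least squares and flagged
`converged = False` rather than raising, so degenerate members of the
model enumeration are excluded gracefully.

## Association inference

The exposure is always the natural log of speaker population size (log
base affects only the slope's scale, never its sign or p-value).

**Multi-model LMER + FMA.**  The Study-1 grammar crosses five fixed-part
options ({}, h, L, h+L, h+L+h:L) with the language intercept in/out and
five grouping factors (corpus, family, macro area, country, script) each
absent / intercept / intercept+slope: 2430 full specifications, 4860 fits
counting the population-free reduced twin of each.  The Study-2 grammar
puts six grouping factors (script, macro area, country, family, subfamily,
sub-branch) in the same three states, excluding the all-absent cell: 728
full specifications, 1456 fits.  Reduced models drop the population fixed
effect *and* all random slopes (slopes without the fixed effect would
force the coefficient to zero).  Models are fitted by ML (AIC comparison
of fixed-effect structures) with iteration caps of 20 (Study 1) and 100
(Study 2); any solution reached by then is accepted and the convergence
flag recorded.  A full model counts as more apt than its reduced twin if
its AIC is lower or the reduced fit failed; ties favor the reduced model.
The frequentist model average is `beta_FMA = sum_j w_j beta_j` with
`w_j = c_j exp(-AIC_j/2) / sum_i c_i exp(-AIC_i/2)` (`c_j` the binary
convergence indicator); AICs are shifted by their minimum before
exponentiation, to which the weights are invariant.  In Study 1 the
outcome `b` and the controls `h` and `L` are standardized within corpus
before fitting.

**Double selection + Freedman–Lane.**  Candidate controls come in three
nested tiers: *small* = level indicators (corpus, family, script, macro
area, EGIDS — EGIDS treated as categorical), cubic B-spline bases for
latitude and longitude with interior knots at the 25/50/75th percentiles
(3 + 3 + 1 = 7 columns per axis), and continuous covariates (log h, log L,
log range size, log distance to water, log altitude, log number of
countries, two climate PCs); *medium* adds the 7x7 products of the two
coordinate bases; *big* adds pairwise products of the level indicators.
Constant and degenerate columns are dropped with a warning.  Two lassos —
exposure on candidates and outcome on candidates, penalty chosen by
seeded 10-fold cross-validation — select the control union; the final OLS
of the outcome on exposure + selected controls uses cluster-robust errors
(by language) when clusters are non-trivial, HC1 otherwise.  Significance
comes from the Freedman–Lane permutation test: the reduced
(controls-only) model's residuals are permuted onto its fitted values,
the full model is refitted per draw (vectorized across draws), and p
compares `|t*|` with `|t_obs|`.  Reported p-values are
`max(count, 1)/n_perm` so the smallest achievable value is `1/n_perm` and
p stays in (0, 1].

**PGLS.**  Generalized least squares with the Brownian-motion covariance
implied by the language tree (entry = shared root-to-MRCA path length),
fitted by maximum likelihood; AIC is compared against the intercept-only
refit and R^2 is the squared Pearson correlation of observed and predicted
difficulty.  On a star phylogeny the covariance is diagonal and the
estimate reduces to OLS (verified to 1e-8).

**SAR with two weight matrices.**  The error model is
`u = lambda1 W1 u + lambda2 W2 u + eps` with `W1` from Haversine
great-circle distances (Earth radius 6371 km) and `W2` from a lexical
dissimilarity matrix, both as row-standardized elementwise inverse
distances (zero off-diagonal distances are replaced by the smallest
positive distance).  `(lambda1, lambda2)` are estimated by quadratic-
moment matching on residuals: each moment `e' Q e` (Q in {I, W1, W1'W1,
W2, W2'W2, W1'W2}) is a bivariate quadratic in the lambdas whose
coefficients are precomputed from the residual vector, `sigma^2` is
profiled analytically, and the objective is minimized on a deterministic
three-level zooming grid over (-0.95, 0.95)^2 (final resolution ~1e-3).
The regression coefficient comes from feasible GLS on the whitened
system, iterated twice.  This moment formulation needs no determinant
evaluations, which is what makes permutation inference (refit per
permuted exposure) tractable: permutation refits are fully batched — one
vectorized OLS, one batched moment estimation and one small GLS per draw.

## The synthetic world

The generator supplies every input the pipeline consumes, with ground
truth recorded.

* **Phylogeny**: pure-birth (Yule) tree, unit height, tips `L001..`,
  deterministic given the seed.
* **Text sources**: order-k Markov chains (default order 1) whose
  transition rows are cyclic shifts of one base distribution with a
  prescribed entropy (geometric family, ratio found by bisection; default
  2.3 bits/symbol).  The chain is doubly stochastic, so its stationary
  distribution is uniform and its entropy rate is exactly the entropy of
  the base distribution — closed form, identical across languages.
* **Difficulty**: realized through vocabulary size (default range 6–30):
  a larger alphabet means more transition parameters to estimate from the
  same text, so compression rates converge more slowly at equal entropy
  rate.  Varying the source order as well is supported but off by
  default: at desk-scale corpus sizes order variation would entangle
  convergence speed with the effective depth the compressor can exploit,
  whereas vocabulary size isolates the intended knob.
* **Traits**: log population follows Brownian motion on the tree plus
  noise, mapped into [1e2, 1e9]; the latent learnability trait is
  `beta_true * log(population) + Brownian(sigma_phylo) + N(0,
  sigma_noise)`.  The trait is oriented like the fitted measures `b` and
  `mu` (higher = easier), so the injected `beta_true` is recovered with
  its own sign; `d_true` (higher = slower convergence) is its rank-based
  inverse and maps monotonically to vocabulary size.
* **Metadata**: families/subfamilies/sub-branches from clade cuts at
  depths 0.25/0.5/0.75 with explicitly nested labels; coordinates from
  Brownian motion on the tree; macro areas and countries by k-means
  clustering of coordinates with countries nested inside macro areas by
  construction; script tied to family; EGIDS decreasing in population
  with noise; positive environmental covariates lognormal.
* **Corpus**: 10 books with equal verse counts (default 500 verses
  total); verse keys shared across languages, verse lengths Poisson
  (default mean 12 symbols) drawn per language, texts sampled from each
  language's source as a continuous chain.  Word symbols render as
  `w000..` tokens.
* **Distance matrices**: Haversine geographic distances, and a synthetic
  lexical dissimilarity = patristic distance plus small symmetric noise.

What the generator does *not* emulate: real orthographies and morphology,
non-stationary style drift, verse-alignment errors, and the heavy-tailed
document-length and data-availability imbalances of real corpora.
Passing tests therefore demonstrate that the estimators recover known
effects under a clean generative model of the study design — not that the
substantive conclusions transfer to any real corpus.

## Problem sizes and determinism

The package's standard validation conditions are: 60-language worlds, 500
verses in 10 books, mean verse length 12, population effect -0.3, PPM
order 2 at the word level, 5 test folds per rotation (the reduced design
also used for expensive models), and a small deterministic slice of the
LMER grammar for model averaging (full enumeration is a switch).
Permutation calibration uses 300–500 simulated datasets at 500
permutations; recovery checks use 50 replicates at n = 100–150.  Every
run is a deterministic function of one master seed; stage seeds are
spawned from it, and identical configurations produce identical outputs
(tested).  Each output bundle carries a SHA-1 hash of its configuration.

## Known limitations

* The PPM variant is one concrete choice (method-C escapes, full updates,
  no exclusions); other variants shift absolute code lengths, though the
  difficulty *orderings* they induce are much more stable.
* `mu` magnitudes depend on the fold design and corpus size; they are
  comparable within a run, not across designs.
* The SAR moment estimator trades a little statistical efficiency for
  speed and determinism; inference rests on the permutation test, which
  only requires a consistent, deterministic estimator.
* The model-space grammar is defined so that it produces exactly
  2430/4860 (Study 1) and 728/1456 (Study 2) specifications/fits; other
  grammars could produce the same counts, and results under a different
  subset grammar could differ.
* Study-1 `b` estimation at desk scale uses short documents; `b` is then
  noisy and its association tests are correspondingly weaker than the
  Study-2 `mu` route, which the end-to-end benchmark uses.
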