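# Methods

## The problem

Sequencing-by-synthesis base callers read out, for every cluster and cycle,
four fluorescence channel intensities (A, C, G, T) and call the channel with
the largest signal. Downstream tools (variant callers, assemblers) consume
not the calls but their *Phred scores*,

    q = -10 * log10(eps),     eps = Pr(call is wrong),

so q = 30 means a 1-in-1000 error probability. `phredlogit` estimates eps
per base with a logistic regression over 74 signal and sequence-context
features, sparsified by backward deletion (AIC/BIC) or L1/elastic-net
regularization, and provides the statistics used to judge a quality scorer:
observed-score calibration, empirical discrimination power, and ROC/PR.

## The model

For base i with feature vector x_i (intercept first) and correctness label
Y_i in {0, 1},

    Pr(Y_i = 1 | x_i) = p(x_i; beta) = 1 / (1 + exp(-x_i' beta)),

fitted by maximizing the Bernoulli log-likelihood L(beta). The error
probability is eps_i = 1 - p(x_i; beta) and the score follows from the Phred
transform. Scores are reported both real-valued and as integers (round half
away from zero) capped at 60 — eps is floored at 1e-6 so a saturated model
cannot emit unencodable FASTQ qualities; realistic fits stay well below the
cap.

### Features (x0..x74)

| group | columns | meaning |
|---|---|---|
| intercept | x0 | constant 1 |
| cycle signals | x1, x2 | largest / second-largest channel intensity |
| read summaries | x3-x5 | mean(x1); mean and sample SD (ddof=1) of the margin d = \|x1-x2\| |
| transforms | x6-x8 | 1/x3, sqrt(x5), ln(x5) |
| hinge basis | x9-x17 | max(0, d - k_j), knots k_j at the 9 training deciles of d |
| position | x18, x19 | cycle number i; 1/(L - i + 1) |
| early cycles | x20-x26 | indicators for cycles 1..7 |
| context dummies | x27-x74 | 48 dummies "P(CS)": previous called base P, current called base C, second-largest channel S |

Read-level statistics are winsorized (x3 into [0.02, 3], x5 into [0.02, 1])
rather than dropped: dropping would leave whole reads unscorable, and the
clamp keeps 1/x3 and ln(x5) finite by construction. x19 uses the +1 offset
so that it equals 1 at the final cycle instead of dividing by zero. At
cycle 1 no previous base exists, so all 48 context dummies are zero;
every later base activates exactly one. The dummy columns are ordered with
the previous base slowest and the (called, second) pair in lexicographic
order among the 12 unequal pairs, matching the order in which coefficients
are conventionally tabulated (x27 = A(AC), ..., x74 = T(TG)).

A structural consequence worth knowing: the 48 context dummies plus the
cycle-1 indicator sum exactly to the intercept, so the full 75-column design
is rank deficient. Penalized fits are unaffected; unpenalized fits (MLE,
backward deletion) drop aliased columns first via pivoted QR, mirroring how
R's `glm` marks aliased terms NA. `model.drop_aliased_columns` exposes this.

### Fitting

*MLE* — iteratively reweighted least squares (Newton-Raphson) with
step-halving, converged when the relative log-likelihood change is below
1e-8 (cap 100 iterations). Near-singular (but full-rank) information
matrices fall back to a minimum-norm least-squares step; exact rank
deficiency raises an error naming the collinear columns. Separation is
declared when the standardized coefficient norm exceeds 30 *while* the
log-likelihood approaches its supremum of 0 (> -1e-8 n); a coefficient
bound alone would misfire, because the near-collinear transforms x5/x7/x8
and the high-knot hinge columns legitimately take offsetting coefficients
in the hundreds on real fits.

*Backward deletion* — from the full (de-aliased) model, tentatively remove
each remaining non-intercept feature, refit, and accept the removal with
the lowest AIC = 2k - 2L or BIC = k ln(n) - 2L (k counts non-zero
parameters including the intercept, natural log throughout); stop when no
removal lowers the criterion. Candidate refits warm-start from the current
coefficients. The deletion trace (feature, criterion) is recorded and is
strictly decreasing by construction.

*L1 / elastic net* — minimize

    -L(beta) + lambda * ( alpha*||beta_-0||_1 + (1-alpha)/2 * ||beta_-0||_2^2 ),

intercept unpenalized (the base-rate calibration should not be shrunk).
Solved by a glmnet-style proximal-Newton: each outer step builds the
weighted least-squares approximation and solves it by cyclic coordinate
descent with soft thresholding, active-set iteration, and step-halving on
the true penalized objective. No feature standardization is applied —
coefficients live on the raw feature scale and the penalty weighs features
in their natural units, which affects what L1 shrinks first and is
deliberate. Internally the quadratic subproblems are solved on centered,
unit-variance columns with per-coordinate thresholds carrying the inverse
scales; this is an exact reparameterization of the raw-scale objective,
adopted purely for conditioning. Convergence is a KKT stationarity check on
the 1/n-scaled objective, with violations normalized by each column's RMS
scale, at tolerance 1e-6; on the raw sum-loss scale an absolute 1e-6 would
be meaningless for n ~ 1e5. Cold starts run a short geometric lambda path
from the all-zero threshold down (warm-started homotopy); at lambda = 0 the
routine is the MLE.

*lambda by cross-validation* — stratified K-fold (default K=5), deterministic
given the seed, maximizing mean held-out AUC; ties broken toward the larger
lambda (sparser model). Each fold is solved pathwise from large to small
lambda with warm starts.

*t-scores* — the contribution of a feature is its coefficient divided by its
standard error. SEs come from the inverse observed Fisher information of an
unpenalized refit restricted to the selected support (standard
post-selection practice); for unpenalized methods the refit reproduces the
fit itself. The numerator is always the reported model's own coefficient.

## Error labels

Labels come from an aligned read layout: the consensus is the most frequent
nucleotide per reference position (ties broken A<C<G<T; zero coverage gives
N), optionally with known variant positions masked to N, and a base is
labelled correct iff it matches the consensus at its mapped position.
Unaligned bases (soft clips, insertions, unmapped reads) and bases over an
N are labelled MISSING and excluded from fitting and evaluation; deletions
contribute nothing. Producing the alignment itself is out of scope — the
package consumes SAM (M/I/D/S operations) or a flat (read_id, cycle,
ref_pos) table. One consensus round is used; at the coverage depths this
workflow targets (hundreds-fold) relabelling after a second round changes
nothing.

## Evaluation statistics

*Calibration* — bases are binned by integer predicted score q and the
observed score is q_obs = -10 log10(Err_q / (Err_q + Corr_q)); zero-error
bins are reported as "> ceiling" (infinite sentinel). Note the estimator's
own noise: a bin with m expected errors has q_obs standard deviation of
about 4.34/sqrt(m) score units, so bins need a few dozen expected errors —
not merely many bases — before |q_obs - q| is meaningful. High-q bins of a
sharp model are therefore excluded or read qualitatively.

*Discrimination power* — sort bases by descending score (stable, so ties
keep input order) and take the largest prefix whose empirical error
fraction is strictly below the threshold r; the power is that prefix's
share of all bases. The expectation-based variant replaces observed errors
with the mean *assigned* error probability of the ascending-eps prefix; it
is blind to calibration bias, which is why the empirical version is
preferred for comparing scorers. The default threshold grid covers
-log10(r) in [3.3, 3.7] (step 0.01), the high-quality regime where scorers
differ most; any grid can be supplied.

*ROC / PR* — positive class = correctly called base, score = quality;
trapezoid AUC equals the probability that a random correct call outscores a
random error (ties 1/2).

*Quench diagnostic* — for T-called bases in cycles 8-12, the called-channel
(T) signal is stratified by the preceding called base and a Gaussian KDE
with fixed kernel width 0.01 is evaluated per group (groups with < 2
observations are omitted with a warning). A depressed T-after-G curve is
the signature of GT-dinucleotide quenching. The called-channel signal (not
the generic largest intensity) is used; for T-called bases the two
coincide.

## The simulator

The generator emulates the qualitative error structure of
sequencing-by-synthesis signals without sharing the functional form of the
model's features, so feature-recovery tests are non-circular. Per cycle:
one-hot of the true base, scaled by (1-delta)^(cycle-1) decay, mixed with a
fraction phi of the previous cycle's one-hot (phi + g_delta after a G),
T-channel multiplied by gamma after a true G, premultiplied by a
row-stochastic crosstalk matrix, plus additive Gaussian noise clipped at
zero. The called base is the argmax channel; ground-truth labels follow.
Identical seed and configuration give bitwise-identical output.

Defaults: phi = 0.04, g_delta = +0.03, gamma = 0.75, sigma = 0.1,
delta = 0.004, identity crosstalk, uniform base composition. With
unit-scale one-hot signals this default noise level yields an essentially
error-free tile — useful for signal-structure diagnostics but not for
training. The package's standard *training condition* (`training_config`,
the "noisy-mixed" fixture) therefore adds mild crosstalk (0.94 diagonal,
0.02 off-diagonal) and sigma = 0.22, calibrated once at generation time to
an overall error rate of about 2% (inside the 0.5-5% window the fixture is
specified to occupy) and left fixed. Under this condition quench-driven
errors land exactly in the G(.T) context dummies — a true T after G loses
signal, gets miscalled as the runner-up channel with T second-largest —
which is what lets sparse fits rediscover the mechanism.

What the simulator does *not* emulate: image-level artifacts, spatial
cluster crosstalk, optical duplicates, coverage biases, indels, or the
heavy-tailed margin distribution of real tiles. Real data put much more
mass at intermediate error probabilities; simulated bases are mostly either
easy or hopeless. Passing tests therefore demonstrate the correctness of
the machinery and the recoverability of planted mechanisms, not real-data
performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 50k-200k
training bases and 100k-1M scored bases — sizes where every statistic of
interest is stable while a full run stays in minutes on one core. Further
fixed choices: knots persist with the model so scoring is train-consistent;
FASTQ integer scores clamp to [0, 60]; score ties in prefix orderings
resolve by stable input order; pileup ties resolve A<C<G<T; the CV fold
split is stratified and seeded; the BIC uses the natural log.

## Known limitations

- Unpenalized full-model fits require de-aliasing (see above); the CLI does
  this automatically, the library API leaves it explicit.
- t-scores for penalized fits borrow SEs from a post-selection refit and
  inherit that approximation.
- The separation detector is a heuristic; quasi-separated data converge to
  large finite coefficients rather than raising.
- Reads are assumed stored in reference orientation; reverse-strand
  handling belongs to the (out-of-scope) alignment step.
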