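# Methods

`triconf` implements a model-arbitration pipeline for perceptual
confidence in a three-alternative forced choice (3AFC) task: which of
three simultaneously shown stimuli (e.g. random-dot kinematograms of
different motion coherence) is strongest, and how confident is the
observer in that choice?

## Generative foundations

Each trial has true stimulus strengths `c = (c1, c2, c3)`. The observer
never sees `c`; it receives a noisy internal sample

    d ~ N(c, sigma * I3)

**Sigma scales variance, not standard deviation.** The per-subject noise
parameter multiplies the identity covariance entrywise, so the
per-component variance equals `sigma` and the SD is `sqrt(sigma)`. This
convention is applied consistently in simulation, fitting, and recovery;
it matters when comparing fitted values against other parameterizations.

Candidate strengths live on a discrete grid, 0 to 5 in steps of 0.5 (11
values, 1331 triplets). Priors are flat: `p(S_i) = 1/3` exactly, and the
prior over `c` is uniform on the grid, so all marginalizations are
discrete sums.

## The four observers

* **Full-grid ideal observer (`plio`).** The hypothesis "stimulus *i* is
  strongest" is identified with the region of the strength grid whose
  triplets have their maximum on axis *i*:
  `p(S_i | d) ∝ Σ_{c : argmax c = i} N(d; c, sigma I3)`.
  Grid triplets whose maximum is tied across axes split their prior mass
  equally among the tied hypotheses (this conserves mass and preserves
  permutation symmetry; an `exclude` switch drops them instead, and
  empirically fits the published effect sizes worse). Confidence is the
  posterior of the chosen option.
* **Hierarchical observer (`plh`).** Point-estimates each source at the
  observed evidence (`c*_i = d_i`, zero elsewhere), then compares the
  axis-aligned hypotheses. The posterior reduces to a softmax over
  `d_i^2 / (2 sigma)`, so its choice is `argmax |d_i|`: it deviates from
  the other observers exactly when a *negative* evidence component has
  the largest magnitude, and it reports high confidence on those trials.
* **Axis-aligned ideal observer (`aio`).** Restricts hypotheses to a
  single shared strength scalar on one axis,
  `p(S_i | d) ∝ Σ_c N(d; c·e_i, sigma I3)`, marginalized over the 1-D
  grid. Its type-1 choice equals `argmax d` (the grid is non-negative).
* **Response-congruent evidence (`rce`).** A heuristic: choose
  `argmax d`, report the raw evidence on the chosen axis as confidence.
  Unbounded, unlike the three posterior-based confidences in [0, 1].

All posterior computations run in log space with max-shift normalization
to avoid underflow at large strengths or small sigma. Exact evidence ties
(probability zero for continuous percepts) break uniformly at random from
the seeded stream in per-trial code, and to the lowest index in the
vectorized batch path.

## Grid simulation

Every model is simulated at every grid triplet (default 10,000 trials per
point; the test and acceptance runs use 2,000, which keeps the worst-case
Monte-Carlo SE on a pairwise effect size near 0.05). Percepts depend only
on (seed, point, trial), never on the model, so two models run with the
same seed see a common percept stream: their type-1 choices are
bit-identical wherever their decision rules agree, and any difference in
output is purely decisional. The common stream is a variance-reduction
choice of this package, not a claim about how the original simulations
were run.

Confidence is z-scored within a model, pooled either across the whole
grid (for cross-model effect-size comparison, since the heuristic's
confidence is not on the [0, 1] posterior scale) or across a listed set
of conditions (the scope observable in a three-condition experiment,
used in fitting and recovery).

## Condition selection

At each grid point and for each of the six model pairs we compute the
pooled-SD Cohen's d between the two models' z-scored confidences
(`d = (mu_B − mu_A) / sqrt((s_A² + s_B²)/2)`, sample variances with
ddof=1). Points are ranked by the sum of |d| over the six pairs —
summation is only meaningful on magnitudes, as the sign is an artifact of
pair ordering. Because the task is symmetric under permuting the three
screen positions, each triplet collapses onto its ascending-sorted
representative and the class score is the mean over members. Points
whose maximum strength is attained by two or more components are excluded:
they have no unambiguous correct answer. The three conditions used
throughout fitting and recovery are `[0,0,3.5]`, `[3.5,4.5,5]`, and
`[4,4.5,5]`.

Strengths translate to display coherences by a fixed scale of 0.16
(chosen so that performance is off ceiling). A condition whose two
non-maximal strengths are tied gets 0.0001 added to one coherence so
that "highest / second-best / lowest" is well defined; the perturbation
is applied in coherence space after scaling, giving `[0, 0.0001, 0.56]`
for the first condition.

**Known limitation.** Re-running the whole selection at covariance scales
0.5 and 1.5 does *not* preserve the relative order of the three selected
conditions at scale 0.5 in this implementation: at low noise, confidence
variance collapses at one-strong-target points and their effect sizes
balloon (summed |d| at `[0,0,5]` reaches ≈ 141 at scale 0.5 versus ≈ 10
at scale 1), promoting `[0,0,3.5]` from last to first among the three.
The whole-grid Spearman correlation of class rankings remains high
(≈ 0.87 vs scale 0.5, ≈ 0.97 vs scale 1.5), and the 1.0-vs-1.5 order is
identical. The robustness report therefore exposes both the rank
correlation and the order-identity flag rather than a single verdict.

## Fitting

**Type-1 stage.** The internal-noise scalar is fitted per subject by
minimizing the cross entropy between the subject's and the model's
choice-category distributions (highest / second / lowest coherence
chosen), per condition, conditions weighted by trial counts:
`CE1 = −Σ p(x) log q(x)` (natural log). The objective is evaluated on a
sigma grid, 0.25 to 6.0 in steps of 0.05, with the model's choice
distribution simulated from one frozen set of standard-normal draws
reused across all candidate sigmas (common random numbers): the
objective is then deterministic and smooth in sigma, and a grid argmin
is robust where a general-purpose optimizer on a noisy simulated
objective is not. Ties go to the smaller sigma.

Because the full-grid, axis-aligned and heuristic observers provably make
the same type-1 choice (argmax of the evidence — a property the test
suite verifies exactly), the shared-sigma mode fits one sigma from that
common rule; the per-model mode exists for the hierarchical observer's
`argmax |d|` rule. Fitting a hierarchical observer's data under the
shared rule inflates the fitted sigma (the magnitude rule errs more at
equal noise), which is the main driver of that model's recovery
failures at large true sigma.

**Type-2 stage.** Each model is re-simulated at its fitted sigma (2,000
trials per condition by default), its confidence z-scored within the
three conditions, and split into (condition × choice category) cells.
For each cell with at least 2 subject trials and nonzero variance, both
the subject's and the model's confidence samples are smoothed by a
Gaussian KDE and compared by discrete cross entropy on an evaluation
grid of 512 points.

Two estimator details matter and are deliberate:

1. **One bandwidth per cell, both sides.** Scott's rule evaluated on the
   *subject's* cell sample is applied to both the subject and the model
   KDEs. With per-sample bandwidths, a 6,000-trial model sample is
   smoothed far less than a 150-trial subject sample; the artificially
   widened subject estimate is then better matched by a wrong model with
   slightly wider confidence spread than by the true model. Equal
   smoothing removes this asymmetry: if the model's distribution equals
   the subject's, both KDEs estimate the same smoothed density and the
   cross entropy attains its Gibbs lower bound.
2. **One evaluation grid per cell, shared by all candidate models.** The
   discretized cross entropy shifts by −log(bin width), so per-model
   grids with different spans are not comparable; all candidates are
   evaluated on a grid spanning the subject's and every model's samples,
   padded by 3 bandwidths.

Cell cross entropies are weighted by the subject's empirical cell
frequencies. No flooring is applied to the model density: if the subject
produces confidences where a model's density underflows to zero, that
model's CE2 is +inf, which is informative (it drives the exclusion rule
in recovery). The best-fitting model is the argmin of finite CE2 values;
ties within 1e-9 are reported as ties with no winner.

## Model recovery

Synthetic observers are generated from each model at the three
conditions — 150 trials per condition, sigma drawn uniformly from
[0.5, 5], the three coherence levels assigned to screen positions by a
uniform random permutation per trial. The generator passes the model's
native confidence through within-session z-scoring only; no slider
mapping, motor noise, lapses or reaction times are simulated, so passing
recovery shows the pipeline separates the models' decision and
confidence structure, not that it is robust to those human nuisances.

Generation seeds come from independent child streams of a master seed
(any observer is reproducible in isolation); fitting seeds are derived
separately so the fit never reuses generation noise. An observer is
excluded only when *every* model's CE2 is non-finite — partial
infinities just eliminate those models from the argmin — and exclusions
are logged with reasons. Results are a confusion matrix (true × best-fit
model, plus a tie column), per-model and overall accuracy.

At 20 observers per model with 2,000 simulation trials per condition the
study reproduces the published pattern: overall accuracy ≈ 0.95, with
the hierarchical observer the hardest to recover (its errors go to the
axis-aligned observer at large sigma, where the shared-sigma fit is
biased upward and the two models' confidence distributions converge).

## Numerical and protocol defaults

| parameter | default | notes |
| --- | --- | --- |
| strength grid | 0–5 step 0.5 | 11 values, 1331 triplets |
| noise scale (selection) | sigma = 1 | variance scale; robustness at 0.5, 1.5 |
| trials per grid point | 10,000 | 2,000 in tests/acceptance runs |
| coherence scale | 0.16 | strengths → display coherences |
| tie epsilon | 0.0001 | coherence space, second-lowest component |
| sigma search grid | 0.25–6.0 step 0.05 | ties to smaller sigma |
| fit simulation trials | 2,000 per condition per candidate sigma | cached per (model, sigma) |
| KDE | Gaussian, Scott on subject cell, 512-point shared grid, 3-bandwidth pad | no flooring |
| min cell count | 2 subject trials | smaller cells skipped, logged |
| recovery cohort | 91 per model (config default); 20 in desk-scale runs | sigma ~ U(0.5, 5), 150 trials/condition |

## Limitations

* Covariances are isotropic and priors uniform throughout; correlated
  noise and unequal priors are out of scope.
* The sigma search stops at 6.0; hierarchical-observer data at large true
  sigma can rail against this cap under the shared-sigma rule.
* Absolute CE2 values are comparable only within one candidate set and
  cell partition (the discretization offset depends on the shared grid);
  only differences between models for the same subject are meaningful.
* The selection's noise-scale robustness holds between scales 1.0 and
  1.5 but not down to 0.5 (see above); conclusions drawn from the ranking
  at very low noise should use the full ranking table, not the top-k.
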