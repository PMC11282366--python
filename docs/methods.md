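# Methods

## The model

An ordered habitat grade `g ∈ {0, …, m−1}` (0 = fully marine) is treated
as the discretization of an unobserved continuous liability `l` evolving
along a rooted, time-calibrated tree. Thresholds
`t₀ = −∞ < t₁ = 0 < t₂ < … < t_{m−1} < t_m = +∞` partition the liability
axis; a node is in grade `k` exactly when `t_k ≤ l < t_{k+1}`. Two
transition pathways out of the sea (direct/marine-associated and
indirect/freshwater) are modeled as two separate ordered characters that
share grade 0 and are analyzed independently; a tip that is non-marine on
one pathway is coded grade 0 on the other.

Liability evolution along an edge of duration `b` is one of:

* **BM** — `l_child | l_parent ~ N(l_parent, σ²b)`;
* **OU** — `l_child ~ N(l_parent·e^{−αb} + θ(1−e^{−αb}),
  σ²(1−e^{−2αb})/(2α))` with the optimum θ equal to the sampled root
  liability, i.e. a pull back toward the ancestral state;
* **λ** — BM on a Pagel-λ transform (internal branches ×λ, pendant
  branches lengthened to preserve tip heights).

Identifiability: σ² is fixed at 1 and t₁ at 0, anchoring the liability
scale and origin; the root liability gets a vague `N(0, root_sd²)` prior
(default `root_sd = 1000`). Free thresholds have a flat prior on
`(0, thr_max)` with `thr_max = 20` liability units — a proper bound
matters because a threshold bordering a grade never observed at the tips
is otherwise data-free and diverges. The root may optionally be
constrained to grade 0 (`force_root_grade0`, default on), reflecting an
unambiguously marine ancestor.

Tips carry *prior rows* over grades rather than fixed states, built from
per-family species counts per grade: a tip's row is its family's grade
proportions, overridden by a point mass where a species-level coding
exists. In the MCMC the tip's grade is implicitly resampled through its
liability; proposals crossing a threshold are weighted by the prior ratio
π(new grade)/π(old grade), and a zero-prior grade is rejected outright.

## The sampler

Metropolis-within-Gibbs with one elementary update per *generation*,
cycled deterministically: each liability (nodes linked by zero-length
edges share one liability "group" — exact inheritance), each free
threshold (sliding window, order-preserving), the model parameter (log
random walk for α with a half-Cauchy-like vague prior; reflected walk on
[0,1] for λ), and one **global scale move** that multiplies all
liabilities and free thresholds by a common factor `c` (log-uniform
proposal, Jacobian `c^{G+K}`). The scale move exists because, under
point-mass tip priors, a threshold can never cross a tip liability in a
single-site update; the joint scale of thresholds and liabilities is then
the slowest direction of the chain by orders of magnitude. Proposal
widths are auto-tuned toward 25–45% acceptance during burnin only, so the
retained chain satisfies detailed balance. Defaults: `ngen = 2×10⁶`
generations, thinning 200, burnin 20% of samples — desk-scale settings;
production analyses should scale `ngen` with the number of nodes
(the preset pipeline uses 2×10⁷ on 200 tips).

Correctness was checked against two independent oracles: exact
multivariate-normal orthant quadrature for node-state posteriors on a
3-tip, 2-grade fixture (agreement within Monte-Carlo error, < 0.01), and
a one-dimensional grid integration of the free-threshold posterior on a
4-tip, 3-grade fixture (posterior mean and 95% interval agree to ~0.005).
The kernel is compiled with numba; chains are reproducible bit-for-bit
given a seed.

**Deviance and DIC.** The deviance recorded per sample is −2× the
*augmented* log-likelihood (edge transition densities × tip-prior terms;
root prior excluded). `DIC = D̄ + p_D` with `p_D = D̄ − D(posterior
means)`, the plugin point being posterior-mean liabilities, thresholds
and parameter. Augmented-likelihood DIC is a pragmatic choice — the
marginal likelihood over liabilities is unavailable — and is used only to
rank liability models on identical data.

**Threshold spacing.** Interior interval widths `t_{k+1} − t_k` measure
how much liability change a grade absorbs; posterior means, credible
intervals and successive-width ratios are reported. Ratios, not absolute
widths, are meaningful because the scale is anchored by σ² = 1.

## Stochastic character mapping

The collapsed three-state dataset (marine / non-marine-direct /
non-marine-indirect, configurable) evolves under an Mk rate matrix Q.
Pruning uses per-edge matrix exponentials with per-node rescaling; soft
tip priors enter as tip partials. ML fits optimize log-rates (L-BFGS-B,
three starts scaled to tree height) under ER/SYM/ARD/ordered structures;
the root prior defaults to the stationary distribution of the fitted Q.
Histories are drawn by sampling node states root-to-tips from their
conditional distributions (tips included, so a soft-coded tip's state is
sampled), then endpoint-conditioned paths per edge: forward rejection
sampling capped at 1000 attempts, then uniformization (Poisson-mixed
powers of `R = I + Q/Λ`, backward state sampling, uniform order-statistic
jump times). The two path samplers are statistically indistinguishable on
fixed edges and match a quadrature formula for the expected conditioned
transition count.

## Transition bookkeeping

Node grades are called by maximum posterior probability with a minimum
probability (default 0.5; ties break to the lower grade with a warning;
below-threshold nodes are "uncertain"). A *node shift* is an edge from a
grade-0 parent to a non-marine internal child; a *reversal* the converse;
edges with an uncertain endpoint are skipped and reported. Edges leading
to single tips are tallied separately: with family-level priors a lone
non-marine tip is within-family evidence, not a reconstructed origin.
Combining pathways pools shift edges; an edge inferred as a shift in both
reconstructions counts once plus a pathway switch. The origin range adds,
to the node-shift minimum, one possible origin per family whose tips
carry at least `mass_cutoff` prior mass at non-marine grades (default:
any nonzero mass) without a reconstructed non-marine ancestor, plus
user-supplied fossil transitions outside the tree.

## Chronogram comparison (bgPCA)

Posterior chronogram samples sharing the reference topology are aligned
clade-by-clade into a samples × internal-nodes age matrix (node ages, in
Myr, not raw branch lengths; outgroups can be dropped first; per-run
burnin fraction defaults to 25%, with 50% recommended for unconverged
chains). Between-group PCA takes the eigenvectors of the covariance of
the (unweighted) group-mean age vectors — at most g−1 axes for g groups —
and projects all centered samples onto them. Ages are analyzed raw by
default; a z-scaling option exists. Extreme chronograms at
`mean ± k·SD·loading` (SD of sample projections on the axis) are
converted back to branch lengths, clipping child ages into `[0, parent]`
and counting clips (warning above 10% of nodes, error in strict mode).

## Synthetic data: what it emulates and what it does not

The generator produces constant-rate birth–death trees conditioned on the
tip count (optionally rescaled to a fixed height, since σ² = 1 sets the
liability clock), BM/OU liabilities simulated root-to-tips, grades cut at
the true thresholds, and tip priors softened by a Dirichlet centered on
the true grade's indicator with a concentration parameter (∞ = point
masses; small values mimic diffuse family codings). Chronogram ensembles
add group-specific age offsets plus Gaussian noise, repaired to respect
parent ≥ child.

The **crab-like preset** (200 tips) plants a known history shaped like
the empirical problem: 3 direct-pathway and 4 indirect-pathway clade
origins at grades 2–4, one marine-again reversal radiation nested inside
each pathway's largest planted clade, 9 singleton families carrying 25%
prior mass at grade 1 with no planted node shift, and 1 fossil transition
outside the tree — so the planted bookkeeping is min 7, node+tip 16,
max 17 convergent origins. Planted clades are reshaped into family-like
units — radiations compressed to height 0.1 with stems stretched to ≥ 0.6
(tip depths preserved) and pairwise separation between planted stems —
because clade origins are only decisively recoverable when a long stem
decouples the clade from its marine background; grade-1 clades are
deliberately *not* planted, as the lowest non-marine grade's interval
abuts the marine threshold and such origins are intrinsically borderline
(the preset's soft-prior singletons represent exactly that regime). The
preset's end-to-end recovery is checked at three fixed seeds.

What the generator does **not** emulate: real codings are noisy and
family counts incomplete; real chronograms carry topological and age
uncertainty jointly; real liability evolution need not be any of BM/OU/λ;
and real family clades are not perfectly grade-homogeneous. Passing the
synthetic checks therefore demonstrates correctness of inference under
the model's own assumptions, not robustness to their violation.

## Calibration experiments (test conditions)

* **Threshold recovery** — 200-tip trees of height 3 (in σ² units), root
  liability at the marine baseline 0, true thresholds (0, 0.5, 1.5),
  point-mass priors; inference with a matched near-point root prior
  (`root_sd = 0.1`), 10⁷ generations, thin 1000. Height 3 ensures every
  grade is populated in every replicate; with shorter trees the top grade
  is often empty and its threshold data-free, which no sampler can
  recover. Coverage is counted per (replicate, threshold) pair.
* **Model selection** — OU data (α = 2) on height-1 trees; DIC compares
  BM and OU chains of 4×10⁶ generations each.
* Both experiments, the oracle fixtures and the preset runs fit in a few
  minutes on one CPU; problem sizes are stated in the tests and the
  acceptance script.

## Numerical choices and limitations

* Liability groups give exact state inheritance across zero-length edges;
  a user-supplied liability vector violating equality across such an edge
  has density −∞ (flagged).
* `expm` is evaluated per edge (k ≤ 6 states); uniformization truncates
  its Poisson series at relative tail mass 10⁻¹².
* Tip order is canonical (label-sorted), so permuting input order cannot
  change any result; internal nodes are indexed in postorder.
* DIC on augmented likelihoods can behave non-standardly when the plugin
  point falls in a zero-prior grade for some tip (p_D becomes infinite);
  this cannot happen with point-mass or interval-consistent priors.
* The threshold model shares the known limitation that transitions into
  high grades require large liability excursions: origins directly into
  the lowest non-marine grade on short stems are often called uncertain
  rather than recovered — a property of the model, not a sampler defect.
* No hidden-state Mk variants, no correlated characters, no multivariate
  liabilities, no reversible-jump over the number of grades.
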