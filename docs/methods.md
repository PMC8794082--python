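# Methods

## The model

`navmix` clusters genetic variants by the *direction* of their multi-trait
association profiles. A variant j with estimated associations
β̂<sub>j·</sub> = (β̂<sub>j1</sub>, …, β̂<sub>jm</sub>) across m traits and
covariance matrix Σ̂<sub>j</sub> is first standardised,
z<sub>j</sub> = Σ̂<sub>j</sub><sup>−1/2</sup> β̂<sub>j·</sub>, and then
normalised to a unit vector x<sub>j</sub> = z<sub>j</sub>/‖z<sub>j</sub>‖.
Two variants acting through a shared mechanism have proportional — not
equal — associations, so it is the direction of x<sub>j</sub> on the unit
(m−1)-sphere that carries mechanistic information, while the magnitude
(largely a function of allele frequency and effect size) is discarded.

Directions are modelled with a mixture of K von Mises–Fisher (vMF)
distributions plus one fixed *noise* component:

    p(x | Θ) = Σ_{k=1}^{K+1} π_k C_m(κ_k) exp(κ_k μ_k' x)

The vMF density has mean direction μ (a unit vector) and concentration κ ≥ 0;
κ = 0 is the uniform distribution on the sphere. Component K+1 has κ fixed at
1e-4 — effectively uniform — and its mean pinned to the global sample mean
direction (the value is immaterial for a near-uniform density). Observations
fitting none of the K directional clusters accumulate there, making the
recovered clusters robust to outliers. Only the noise component's mixing
proportion is updated during fitting.

Standardisation uses the symmetric (eigendecomposition) inverse square root,
the unique positive-semidefinite root; with no trait-correlation matrix it
reduces to elementwise z-scores β̂/se. A single m×m trait correlation is
applied to every variant, reflecting the approximation
cor(β̂<sub>jk</sub>, β̂<sub>jl</sub>) ≈ cor(X<sub>k</sub>, X<sub>l</sub>),
which is variant-independent.

## Fitting

Maximum likelihood by EM:

* **E step** — responsibilities γ<sub>jk</sub> ∝ π_k f(x_j | μ_k, κ_k),
  normalised per observation; computed in log space with max-subtraction.
* **M step** — μ̂_k is the normalised responsibility-weighted resultant
  vector; κ̂_k is obtained from the mean resultant length r̄_k through the
  Banerjee et al. closed form κ̂ = (r̄m − r̄³)/(1 − r̄²), capped at 500
  (r̄ → 1 would otherwise drive κ, and the Bessel evaluations, to
  overflow); π̂_k are responsibility means. The noise μ and κ are not
  updated.

The closed-form κ update is an approximation to the exact root of
I<sub>m/2</sub>(κ)/I<sub>m/2−1</sub>(κ) = r̄, so the EM objective can dip by
an amount of the order of the approximation error (observed ≤ 5e-3 on random
problems); `kappa_method="exact"` switches to root-finding inversion, which
is strictly ascending, at a modest cost. The approximation's worst relative
error over κ ∈ [0.5, 50] is ≈ 6.5% on the circle (m = 2, near κ ≈ 4.5) and
< 2% at m = 9.

Each run is initialised from a spherical k-means partition (cosine-similarity
k-means, centroids seeded from random observation rows): the assigned cluster
receives initial responsibility 1 − 0.05, the noise column 0.05, and EM
starts at the M step. Five random restarts are fitted and the best final
log-likelihood kept. Convergence is declared when successive log-likelihood
values differ by less than 1e-4 (at most 500 iterations). A restart whose
component loses essentially all responsibility mass (< 1e-8·n) is abandoned
and re-initialised, up to three extra attempts — the M step is undefined at
zero weight.

All Bessel-function work uses the exponentially scaled `scipy.special.ive`,
so densities are finite up to the κ cap; the normalising constant at κ = 0
uses the continuity limit (the reciprocal sphere surface area).

## Choosing K and assigning membership

K is selected by minimising the BIC

    φ_m(K) = −2 l_K(Θ̂) + r_m(K) log n,     r_m(K) = (m + 2)K + m

over K = 1, 2, …. The search stops after the criterion has exceeded its
running minimum for `patience` consecutive values of K (or at `k_max_cap`,
default 10). The default patience is 2: a single deterioration is often a
local-optimum artefact of one K's fit, and stopping there measurably
under-counts clusters when one true cluster is small; patience = 1
(stop at the first deterioration) is available for the cheapest search.
The returned model is the argmin over all evaluated K.

Hard assignment takes argmax<sub>k</sub> γ<sub>jk</sub> (ties to the lowest
index, for determinism). A threshold mode leaves observations unassigned
when the best membership probability is below a cutoff; a soft mode assigns
each observation to every cluster whose probability clears the cutoff.

## The synthetic-data generator

The simulator emulates a single-sample GWAS of N = 20 000 individuals and
n = 100 independent biallelic variants (80 clustered, 20 noise):

* maf<sub>j</sub> ~ U(0.01, 0.5), G<sub>ij</sub> ~ Binomial(2, maf<sub>j</sub>);
* each cluster k drives a latent factor
  L<sub>ik</sub> = Σ<sub>j∈k</sub> β<sub>jk</sub> G<sub>ij</sub>, with
  β ~ U(0.03, 0.06) except that with per-cluster probability
  φ ~ U(0.05, 0.2) a variant instead draws the stronger N(0.1, 0.02²);
* trait l: X<sub>il</sub> = Σ<sub>k</sub> δ<sub>kl</sub> L<sub>ik</sub> +
  Σ<sub>j noise</sub> α<sub>jl</sub> G<sub>ij</sub> + γU<sub>i</sub> +
  √(1−γ²) ε<sub>il</sub>, with U, ε standard normal. γ ∈ {0, 0.4, 0.8}
  controls the residual inter-trait correlation (γ² on the unit-variance
  noise scale) from a shared confounder;
* the fixed δ matrices (built in for m ∈ {2, 9}, K ∈ {1, 2, 4}) set each
  cluster's trait signature, e.g. rows (1, 1) and (1, −1) for the
  two-trait, two-cluster design; cluster sizes are 80; 40/40; 30/20/20/10;
* noise-variant direct effects α<sub>jl</sub> ~ U(−0.1, 0.1) are drawn
  independently per trait, so each noise variant has an arbitrary
  association direction rather than a shared one — this is what makes them
  "noise" in direction space;
* associations are estimated by simple per-variant OLS of each trait on each
  genotype (intercept included), exactly as a GWAS would.

Under these settings the 100 variants explain ≈ 5–10% of each trait's
variance and clustered variants reach per-trait |z| of roughly 2.5–6 at
N = 20 000. Options: per-trait sample sizes drawn from U{10 000, 50 000}
with independent row subsamples per trait (overlap is allowed; the sampling
frame is the largest drawn size), and a genome-wide significance filter
(two-sided normal p < 5e-8 on at least one trait; normal rather than t, a
< 1e-12 difference at these sample sizes). All randomness flows from one
master seed through named substreams, so datasets are bit-reproducible.

What the generator does *not* emulate: linkage disequilibrium between
variants (variants are independent), case-control traits, winner's-curse
ascertainment of effect sizes, allele-orientation errors, or population
structure. Passing benchmarks on this generator therefore demonstrates
correct recovery under the stated sampling model, not robustness to those
real-data complications.

## Evaluation metrics

The adjusted Rand index is computed from the pairwise contingency table
under the permutation model; the noise cluster is treated as an ordinary
label in both partitions, since allocating a variant to noise is an
informative statement. The silhouette coefficient uses great-circle
distance d(x, y) = arccos(x'y) (inputs clipped to [−1, 1]; self-distances
forced to exactly zero), with singleton clusters scoring 0 by Rousseeuw's
convention, and is the mean over all observations including noise-labelled
ones.

## Benchmark problem sizes

The replication harness (`navmix benchmark`, `scripts/acceptance.py`,
and the scenario tests) uses 100 replicates per scenario at the generator's
default N = 20 000. Scenario means reported with these sizes carry
Monte-Carlo standard errors of roughly 0.01–0.1 on the mean selected K
(largest in the four-cluster, two-trait scenario, where selection is
genuinely variable) and ≈ 0.3–0.5 on the mean noise-cluster size.

## Known limitations

* Mean-direction and concentration estimates are approximate-MLE (Banerjee
  closed form); exact inversion is available but not the default.
* The m = 2 concentration approximation error (up to ~6.5%) slightly biases
  fitted κ on the circle; selection and assignment are insensitive to it.
* One trait-correlation matrix is shared across variants; per-variant
  overlap structures are not representable.
* Allele harmonisation across source GWAS files is assumed done upstream;
  the package only offers sign orientation to a primary trait.
* The BIC search is greedy in K; pathological φ landscapes with broad flat
  regions could stop early (mitigated by `patience` and `k_max_cap`).
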