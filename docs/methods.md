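# Methods

## The two-level assimilation scheme

The package treats an agent-based model (ABM) as a black-box stochastic
dynamical system over *microstates* μ (agent lists plus lattice fields) and
performs Bayesian filtering over *macrostates* M = S(μ), where the
summarization map S collects permutation-invariant summaries: agent counts
per type, lattice-field totals, categorical-label counts, and a running
event tally. Filtering on macrostates sidesteps the four structural
obstacles to Kalman filtering of ABMs — dimension changes from birth/death,
lack of agent correspondence across ensemble members, non-vector
(categorical) agent states, and the intractable dimension of spatial fields.

The filter is the stochastic (perturbed-observation) ensemble Kalman filter
with state augmentation: each member's filter vector is the transformed
macrostate concatenated with its transformed model parameters. Perturbed
observations were chosen over square-root variants because the scheme
explicitly refits a Gaussian and resamples a fresh macrostate ensemble after
every update (step 4 of the loop), which pairs naturally with stochastic
updates and makes the posterior available to the synthesis step as an
explicit distribution. Observation noise lives in transformed space; the
measurement model is y = H·T(S(μ_truth)) + N(0, R).

Parameter learning uses a random-walk model: between updates each member's
transformed parameters take an additive N(0, Q) step. The walk is applied in
the forecast phase (before the update), so the last analysis always
contracts the noise it injected; the truth trajectory's parameters are never
perturbed. Positive rate parameters are log-transformed, so the walk
preserves positivity and keeps parameters on the same scale as the
log-transformed state variables.

## Variable transforms

Counts whose distribution concentrates near zero (wolves, which frequently
go extinct) use the shifted log W′ = log(ε + W) with ε = 0.001 and the
clamped inverse W = max(0, exp(W′) − ε). Large counts are scaled to O(1–10):
sheep by 0.1, grass by 0.01, so that the least-squares filter does not
prioritize the largest-magnitude variable. The infection model's field
totals and event tally use the shifted log; its categorical counts are
scaled by 10/side². Continuous filter output is mapped back to feasible
macrostates by clipping to domains and capacities and integerizing counts —
per-entry round-half-to-even for free counts, largest-remainder (Hamilton)
apportionment with lowest-index tie-break for count groups constrained to a
fixed total (the categorical lattices). Hamilton apportionment was chosen
because it preserves the group total exactly and stays within one unit of
proportionality per entry.

## Microstate synthesis

Synthesis rests on two principles: *continuity* (nearby macrostates admit
nearby microstates, so each posterior sample is paired to the closest
predictive member and edited minimally — pairing by Gale–Shapley stable
matching on Euclidean distance in filter space, predicted side proposing,
ties by index) and *local similarity* (edits should respect existing
spatial structure).

Well-mixed model (WSG): surplus agents are deleted uniformly at random;
deficits are filled with uniformly placed agents whose energies are drawn
from the empirical energy distribution of the surviving population (uniform
on (0, 2·gain] if none survive); grass flips uniformly chosen patches.

Spatially structured model (infection): molecular fields are rescaled
multiplicatively to the target total (exact total, spatial correlations
untouched; a zero field receiving mass is filled uniformly, since no spatial
information exists). Categorical lattices go through the three-step
pipeline:

1. **One-hot encoding** of labels to standard basis vectors, so category
   counts become column sums.
2. **Rescaling** of every site vector componentwise by new/old count
   ratios; a 0/0 ratio is defined as 1, and a category growing from zero
   count is deposited uniformly over all sites.
3. **Quantization with error diffusion**: sites are visited most-confident
   first (largest max component weight, ties broken by a seeded random
   permutation — raster order would imprint directional artifacts, and a
   purely random order lets category-capacity exhaustion force labels at
   arbitrary late sites, scattering spatial structure; confident sites
   claim capacity first and their diffused surplus raises the weights of
   adjacent uncertain sites before those are visited). At each site the
   label q minimizing
   L(q) = λ₁‖e_q − s‖² + λ₂(−log(c·e_q)) + λ₃·score(q, neighbourhood)
   is chosen among categories with remaining capacity. c is the
   pseudocount-regularized (constant 1) distribution of already-quantized
   labels in the 3×3 neighbourhood. The quantization error Δ = e_q − s is
   subtracted, split equally, from the unquantized sites of the 3×3
   neighbourhood, or spread over all remaining unquantized sites when the
   neighbourhood is exhausted; components driven negative are clipped at
   zero and the clipped mass re-spread uniformly (up to 8 passes) so
   per-category mass is conserved. Capacity counters make the final counts
   equal the target exactly (pigeonhole over the site total). Loss ties —
   typical at zero-weight sites left by vanishing categories — are broken
   toward the category with the largest remaining capacity, then lowest
   index: an uninformative site should absorb the category most in demand,
   which is also what the exhaustive small-instance optimum does.

The optional third loss term scores the candidate against a
Laplace-smoothed frequency table of neighbourhood patterns (center
category, 8-neighbour label counts, log-binned local virus level: one bin
for zero, then decade bins) tabulated from previous model runs; unseen
patterns get a finite score above every seen pattern. Default weights are
(1, 1, 0), or (1, 1, 1) when a neighbourhood model is supplied. During
quantization the neighbour counts fed to the table come from
already-quantized sites only, so early sites see sparser patterns than the
training snapshots; smoothing keeps those scores finite and the term acts
as a bias rather than a hard constraint.

Immune-agent counts are adjusted per type: uniform random removal of
surplus; deficits recruited at uniformly chosen activated endothelial sites
(uniform over the lattice if none are activated).

## Demonstration models

**Wolf-Sheep-Grass.** A re-implementation of the classic NetLogo library
predator–prey model. Parameters default to the library model's (sheep
reproduce 0.04, wolf reproduce 0.05, sheep gain 4, wolf gain 20, grass
regrowth 30, move cost 1). Movement is a random walk — uniform new heading
each tick, forward step of fixed length on a torus; the per-agent "velocity"
is realized as heading plus fixed speed, re-randomized each tick. Phase
order per tick: move → pay move cost → eat (wolves then sheep, conflicts
resolved by uniform random within-patch ranks) → death at energy ≤ 0 →
reproduction (energy split exactly between parent and child) → grass
regrowth (patches eaten this tick keep their full counter until next tick).
Sheep always pay the move cost (grass dynamics are integral to the
macrostate). Co-location means the same integer patch.

**Reduced viral-infection model.** A compact (~12-parameter) testbed with
the state structure that makes synthesis hard — categorical epithelial and
endothelial lattices, ten nonnegative diffusing fields (virus, T1IFN, TNF,
IL1, IL6, IL8, IL10, IL12, IFNg, PDAMPs), and four mobile immune-agent
types (macrophage, neutrophil, NK, DC) — rather than a full physiological
virology model: the assimilation and synthesis algorithms only require
hot-spot spatial structure, categorical states, and field/agent coupling.
Fields evolve by an explicit 5-point Laplacian with reflecting boundaries
(keeps hot-spots localized; stability requires 4·D ≤ 1 per tick),
geometric decay, and secretion from infected sites and immune agents.
Healthy sites are infected with probability 1 − exp(−β·virus); infected
sites apoptose exactly at the apoptosis timer (incrementing the
virus-apoptosis tally) or on NK contact, and necrose above a virus
threshold; endothelium activates where local TNF+IL1+IL6 exceeds a
threshold and dies above a tenfold multiple of it; immune agents are
recruited Poisson-distributed at activated sites, random-walk with a bias
up the virus+PDAMPs gradient, and are cleared after a fixed lifespan.
Intracellular virus is not modelled separately (one virus field). The
macrostate is the fixed-order vector of 10 field totals, 5 epithelial
counts, 3 endothelial counts, 4 immune counts, and the virus-apoptosis
tally — a structural analogue, smaller than a full physiological roster.

## Evaluation

Surprisal is the negative log density of the truth's transformed
(state + parameter) vector under the Gaussian fitted to the predictive
ensemble, in nats, computed per time point (the time series makes update
effects visible as downward spikes). The Gaussian fit adds a ridge
δ = max(1e-10, 1e-8·trace/d) so the belief is strictly positive definite
even for collapsed ensembles. Phenotype analysis flattens each run's
(T+1)×V macro trajectory to a vector, standardizes per column (raw scales
would let grass and sheep dominate, contrary to the scaling logic used in
the filter itself), projects onto 3 principal components, and clusters by
k-means with k ∈ 2..6 chosen by silhouette over 20 seeded restarts
(degenerate inputs fall back to k = 2). Per-cluster, per-time-point
Gaussians are compared with the closed-form 2-Wasserstein distance
W₂² = ‖Δm‖² + Tr(P_a + P_b − 2(P_b^{1/2} P_a P_b^{1/2})^{1/2}), with PSD
square roots by eigendecomposition and tiny-negative clipping. Linear
phenotype boundaries in parameter space are fitted with a linear SVM and
reported as a unit normal plus training accuracy.

## Study conditions and problem sizes

Twin experiments use a virtual-patient truth with fixed parameters;
observations are the truth's transformed macro variables plus N(0, R)
noise. Default observation cadence is every 50 ticks. The shipped
experiment sizes are chosen so the full suite runs in minutes on one CPU:

- Surprisal-skill experiments: WSG on a 32×32 world (20 wolves, 60 sheep,
  half grass), 300 ticks, 20 members, sheep observed every 50 ticks at
  R = 0.01, Q = 0.01, 50 replicates, against a no-assimilation control with
  identical truths.
- Parameter recovery: WSG on a 51×51 world at the library model's densities
  (50 wolves, 100 sheep), 150 ticks with updates every 25 ticks, truth
  sheep-reproduction probability drawn from the log-normal prior
  (log-mean log 0.04, log-sd 0.3). The 150-tick window covers the sheep
  growth transient, where the reproduction probability is dynamically
  identifiable; once the population reaches its grass-limited equilibrium
  the sheep count carries almost no information about the parameter, so
  updates past that point only add random-walk noise.
- Categorical synthesis checks: lattices up to 32×32, the infection model
  at 16×16.

## Numerical choices and degenerate inputs

- EnKF solves go through Cholesky of the innovation covariance (SPD by
  construction); the ensemble covariance gets a 1e-10 ridge.
- Posterior sampling uses the symmetric eigendecomposition square root with
  negative eigenvalues clipped at zero, so marginally conditioned
  posteriors never fail.
- Synthesis infeasibility for a member (e.g. a posterior sample outside the
  model's reachable set) is handled by resampling that member once from the
  posterior and, failing that, keeping its forecast state.
- All stochastic operations draw from `numpy.random.Generator` streams
  spawned from a single run seed (`SeedSequence`), so full experiments are
  reproducible bit-for-bit from config plus seed.

## What the synthetic studies do and do not show

The generators emulate the study conditions of a twin experiment: known
truth, Gaussian observation noise in transformed space, priors centered
near the truth's parametrization. They do not emulate model error (the
ensemble runs the same dynamics as the truth), measurement-device
systematics, or irregular observation timing. Passing tests therefore
demonstrate the internal consistency and skill of the assimilation
machinery under a correctly specified model, not robustness to model
misspecification. Known limitations inherited from the method: the Gaussian
(unimodal) posterior cannot represent diverging phenotypes — after a wolf
extinction the filter commits to one of the two consistent attractors and
further wolf measurements cannot correct it; and the filter operates on
single-time observations (a filter, not a smoother).
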