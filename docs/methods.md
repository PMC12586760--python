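# Methods

This note documents the models and procedures implemented in
`pengrowth`, the defaults that matter, and the choices made where the
design was genuinely open.

## Growth-curve parameterization

A chick's record is a strictly increasing series of (age, mass) pairs,
ages in integer days post-hatching, masses in grams.  Weighing starts
at the end of the guard phase, so the age at first measurement is used
as the guard-duration proxy.  Records with fewer than five measurements
are excluded (and reported); duplicate-age rows are averaged before any
analysis.  A chick is flagged *fledged* when it leaves the nest after
day 45 having reached a peak mass of at least 800 g; non-fledged chicks
still receive parameters and carry the flag for downstream filtering.

Eleven descriptors are computed per chick:

* **Magnitude** — peak mass (first maximum on ties: mass recession
  follows the peak, so the first maximum is the biological peak), mass
  at the last measurement (fledging mass), relative mass loss
  (peak − last)/peak, and the sibling delta
  d = mean_i[(m_A,i − m_B,i) / mean(m_A,i, m_B,i)] over the N exactly
  shared measurement ages (broods are weighed together, so exact
  matches dominate; no interpolation).  d is signed from the focal
  chick's side and antisymmetric by construction; singleton chicks get
  a missing value handled by imputation, never row deletion.
* **Rate** — guard duration; the steepest sustained growth segment,
  found by exhaustive search over all contiguous measurement windows
  with ≥ 3 points spanning ≥ 5 days, fitting OLS mass ~ age per window
  and keeping the maximum slope (ties resolve toward the longer, then
  the earlier, window); ages at peak and at fledging.  The window
  minima are configurable; the exhaustive-window oracle is part of the
  test suite.
* **Form** — the irregularity index: the mean absolute residual of a
  loess smooth of the series (tricube weights, nearest-neighbour window
  of ceil(span·n) points, local degree 2, span 0.9, no robustness
  iterations).  It is zero for data lying on any quadratic and scales
  linearly with mass.

## Phenotyping

Seven weakly correlated descriptors enter the clustering: peak mass,
relative mass loss, sibling delta, guard duration, steepest slope, age
at peak, irregularity.  They are z-scored (n−1 denominator).  Missing
cells are completed by iterative PCA: initialize at column means, then
alternate rank-`ncp` truncated-SVD reconstruction with overwriting of
the missing cells only, to a 1e-6 fixed-point tolerance (observed cells
are never altered; non-convergence — possible on structureless data
when trailing singular values cross — is an error, and the
cross-validation below penalizes it).  The imputation rank is chosen by
leave-out cross-validation: 20 repeats of masking 5% of observed cells
and scoring mean squared reconstruction error per candidate rank (the
masking fraction and repeat count are package choices, sized for
n ≈ 2000 rows).

PCA is the eigendecomposition of the correlation matrix of the
completed data; the sign convention makes each loading vector's
largest-magnitude entry positive so stored models compare across runs.
Clustering is Ward-linkage agglomeration on Euclidean distances of the
principal-component scores.  The cluster count k is selected from the
tree cuts at k = 2..max_k by maximizing the relative within-cluster
inertia loss (W(k−1) − W(k))/W(k−1), evaluated for k ≥ 3 with the k = 2
cut as baseline (the ratio is undefined at k = 1, and a minimum of
three clusters mirrors the reference HCPC implementation).  By default
the cut labels are consolidated by k-means started from the cut
centroids.  Two distinct ranks are kept deliberately separate: the
imputation rank (cross-validated) and the number of axes the clustering
consumes (default 5, the reference PCA implementation's default).  On
synthetic data the cross-validated imputation rank is typically 1 —
the between-type structure is essentially one magnitude axis plus
weakly correlated rate axes — and clustering on a single axis cannot
separate fast from slow growth; clustering on five axes can.

Cluster portraits map labels to phenotype names by rule: *light* is the
cluster with the lowest mean peak mass; of the remaining two, *fast*
reaches peak mass earlier and *slow* later.  Per-parameter one-way
ANOVAs accompany the portraits.  A bootstrap stability check (resample
rows, rerun the pipeline, tally the chosen k and pairwise co-assignment
agreement against the full-data partition) quantifies robustness.

## Vital rates

Proportion-type rates (hatching success h, fledging success f,
first-reproduction probabilities P2–P4, second-clutch probability C)
are binomial estimates with Wilson 95% intervals; phenotype contrasts
use a fixed-effects binomial GLM on the phenotype indicator, which is
saturated, so fitted probabilities equal per-group proportions, with
pairwise Wald z-tests.  The random parental/individual effects of a
full GLMM would not change the per-phenotype rates the demographic
model consumes, so fixed effects are used throughout.  Degenerate
all-0/all-1 groups are flagged and kept out of the z-tests.  Third
clutches are dropped as negligible; individuals never observed breeding
are excluded from age-at-first-reproduction estimation (P_a is the
discrete hazard: first breeding at age a among breeders still unbred at
a).

Survival comes from a Cormack–Jolly–Seber model conditional on first
release (fledging): survival by age class (S0 = fledging to first
anniversary, then S1, S2, S3, and Sa for all older ages) crossed with
phenotype, detection by age class only (p1 for one-year-olds, a shared
adult p thereafter).  The likelihood uses the standard never-seen-again
(chi) backward recursion, aggregated over unique (release, history)
patterns.  Maximization is quasi-Newton (L-BFGS-B) on the logit scale
from seeded random restarts; 95% CIs come from the inverse
finite-difference observed information, transformed back to
probabilities.  A singular information matrix leaves CIs missing with a
warning.  Transience, trap-dependence and cohort structure are out of
scope.

## The life cycle and its Markov chain

Five transient states: egg E, juveniles J1–J3 (ages 1–3), breeder B;
death is the implicit absorbing state; projection interval one year,
post-breeding census.  Columns of U index the *from* state (both
orientations circulate in the demography literature; this one is fixed
throughout).  Transitions: E→J1 = h·f·S0; J1→J2 = S1(1−P2);
J1→B = S1·P2; J2→J3 = S2(1−P3); J2→B = S2·P3; J3→B = S3·P4 (P4 = 1);
B→B = Sa (Pa = 1, no skipped breeding).  Column deficits are mortality.

* **Longevity** from state i is the i-column sum of N = (I − U)⁻¹,
  counting the starting year; occupancy of a state set is the
  corresponding row sum, and its fraction of lifetime divides by
  longevity.
* **Recruitment**: reach probabilities solve
  q(i) = Σ_j U[j,i]·q(j), q(B) = 1.  The conditional mean time to first
  breeding is computed on the success-conditioned chain
  (Ũ[j,i] = U[j,i]·q(j)/q(i)); ages anchor as E = 0, J1 = 1, so steps
  from the egg equal age in years and recruitment happens at ages 2–4.
* **LRO**: rewards of m = 2·(1+C) eggs (both sexes; a `--female-only`
  switch halves this, and a fledgling variant uses m·h·f) are credited
  on every transition entering B, *including* B→B persistence — a
  census-time breeder breeds again only upon surviving another year.
  This timing is the only one consistent with LRO being maximal from J3
  for phenotypes with S3 > Sa but from B when S3 < Sa.  Expected
  accumulated rewards solve ρ(i) = Σ_j U[j,i]·(R[j,i] + ρ(j)).
  Published LRO comparisons are ratios and therefore invariant to the
  clutch scaling.  The fertility matrix F (F[E,B] = 2·sr·(1+C)·Sa) is
  assembled for completeness but no headline output uses it.

Every matrix quantity has an independent oracle in the test suite:
exhaustive path enumeration (the chain is acyclic before B) checks
reach probabilities and conditional passage times exactly, and a
vectorized Monte-Carlo simulator (200,000 trajectories in the
acceptance suite) checks longevity, occupancy and LRO to within three
standard errors.

## Synthetic data

The growth generator emulates the field protocol: per-brood weighing
schedules starting at guard end with 2–3-day cadence, one or two chicks
per brood (singleton probability 0.27, putting ~2.2% of the parameter
matrix missing via the sibling delta), sibling type concordance 0.65.
Each chick grows along a logistic curve (asymptote A, rate k,
inflection t0) to an individual peak age, then recedes linearly;
feeding-gap dips (Gaussian in time) inject irregularity, and
measurement noise of 10 g reflects the coarser field scale's precision.
A chick dies before fledging with probability 1 − f of its type,
truncating its series (never below five measurements).  Type defaults
encode the published phenotype contrasts: maximum growth rates
A·k/4 = 28 / 25 / 18 g/day for fast / slow / light, a light asymptote
350 g below fast (800 vs. 1150 g), a slow inflection 10 days after fast
(peak shifted 10–20 days), a fast guard phase 6 days longer (14 vs.
8 days), and the slow type carrying deep frequent dips.  The life-history
generator draws age-class survival, recruitment (P2–P4), annual
breeding with second clutches, and detection thinning (p1 = 0.76 at
age 1, 0.9 older) from a vital-rates block, defaulting to the packaged
table.

What the generator does *not* emulate: environmental covariates and
cohort-year effects, growth-law heterogeneity beyond
logistic-plus-recession, sibling competition dynamics, and the
state-vs-age subtlety that an early recruit's survival is Sa rather
than its age-class rate.  Passing recovery tests therefore show the
pipeline recovers structure *of this kind* at realistic noise, not that
the field data contain it.

## Numerical choices and problem sizes

Loess windows must hold at least degree + 2 points (the farthest point
carries zero tricube weight).  Steepest-slope ties use a 1e-9 relative
slope tolerance before the longer/earlier tie-break.  The CJS
likelihood returns −inf for parameters outside (0, 1), keeping the
optimizer in bounds without constraints.  Imputation tolerance 1e-6,
maximum 1000 iterations.  The k-means consolidation uses a fixed
random state, making the whole pipeline deterministic given its seed
and invariant to row order up to relabeling.

Test problem sizes are chosen to be decisive yet quick: 2298 synthetic
chicks (the study's scale) for clustering recovery; 50 replicates of
2000 releases over 12 occasions for CJS coverage; 100,000–200,000
Monte-Carlo trajectories for oracle agreement.

## Known limitations

* The clustering recovers the three synthetic types with ARI ≈ 0.84;
  real data would add measurement idiosyncrasies the generator omits,
  and exact published cluster sizes or variance fractions are not
  reproducible without the field data.
* The CJS model omits transience, trap-dependence and cohort effects;
  its CIs are Wald-type on the logit scale and can be optimistic near
  boundaries (e.g. rates estimated from a handful of birds).
* Only first moments of LRO are computed; variance and higher moments
  of the reward distribution are a natural extension.
* No population projection, growth rate, or sensitivity analysis is
  included.
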