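# pengrowth

Growth-trajectory phenotyping and life-history demography for little
penguin (*Eudyptula minor*) chicks.

Early growth conditions can leave lifelong marks on survival, age at
first reproduction and lifetime fitness ("silver spoon" effects).  This
package implements the full analysis chain needed to test that idea in
a long-term colony monitoring dataset:

1. **Growth-curve parameterization** (`pengrowth.growthcurves`) — each
   chick's longitudinal mass series becomes eleven descriptors of
   growth *magnitude* (peak mass, fledging mass, relative mass loss,
   sibling mass delta), *rate* (guard duration, steepest sustained
   slope with its onset and duration, ages at peak and fledging) and
   *form* (an irregularity index: mean absolute deviation from a loess
   smooth of the curve).
2. **Phenotyping** (`pengrowth.clustering`) — the seven weakly
   correlated descriptors are z-scored, missing cells (sibling delta of
   singleton chicks) are completed by iterative-PCA (EM) imputation,
   and chicks are grouped by Ward-linkage hierarchical clustering on
   principal-component scores (HCPC) with automatic cluster-count
   selection, yielding *fast*, *slow* and *light* growth phenotypes.
3. **Vital rates** (`pengrowth.vitalrates`) — per-phenotype fledging
   success, first-reproduction and second-clutch probabilities
   (binomial fits, Wilson intervals) and age-class survival from a
   Cormack–Jolly–Seber capture–recapture model (survival structured by
   age class × phenotype, detection by age class, Hessian-based CIs).
   The published vital-rate table is packaged as a fixture.
4. **Demography** (`pengrowth.lifecycle`) — a five-state absorbing
   Markov chain over (E, J1, J2, J3, B) with death implicit.  With U the
   transition matrix (columns = from-state), the fundamental matrix
   N = (I − U)⁻¹ gives expected state occupancies; its column sums give
   expected longevity.  First-passage analysis to the breeder state B
   gives the probability of recruiting and the conditional mean age at
   first reproduction.  Lifetime reproductive output (LRO) is the first
   moment of a Markov chain with rewards: a clutch of 2·(1+C) eggs is
   credited on every transition entering B, including the B→B
   persistence loop.
5. **Synthetic data** (`pengrowth.synthdata`) — seeded generators for
   chick mass measurements (three latent growth types, sibling broods,
   post-guard weighing every 2–3 days, feeding-gap dips) and for
   capture histories / breeding records, with ground truth, so the
   whole chain is testable without any field data.

## Worked example

Demography of the three phenotypes straight from the packaged
vital-rate table:

```sh
pengrowth lifecycle --out demo_run
```

```text
cluster start  longevity  years_breeder  frac_breeder  reach_breeder    lro  age_first_repro
   fast     E      2.155          0.922         0.428          0.092  2.433            2.654
   slow     E      1.826          0.608         0.333          0.073  1.582            2.944
  light     E      1.074          0.043         0.040          0.010  0.096            2.416
   fast     B     10.000         10.000         1.000          1.000 23.760              NaN
...
```

Reading the egg-state rows: a fast-phenotype egg can expect to live 2.2
years, spending 43% of that lifetime as a breeder; it recruits with
probability 0.092 at a mean age of 2.65 years and accumulates 2.43 eggs
of expected lifetime output.  Light chicks pay a heavy toll before
age 1 (egg-to-yearling passage 2.5% vs. 15.3% for fast chicks) and
almost never breed.  A recruited breeder of the fast phenotype keeps
the state for 1/(1−Sa) = 10 more years and is worth 23.76 expected
eggs.  The companion `ratios.csv` reports recruited-bird longevities
(12.65 / 11.28 / 6.76 years for fast / slow / light) and the
state-averaged LRO ratio fast/slow = 1.19.

The full synthetic pipeline — simulate a colony, parameterize and
cluster the growth curves, estimate vital rates, run the demography:

```sh
pengrowth pipeline --out run --seed 1
```

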