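# Methods

This note documents the model implemented by `agedrift`, the assumptions
behind it, parameter choices, how the synthetic populations are generated,
numerical choices, and known limitations. Everything stated here is
computed by the code in this repository; no empirical claims are made
beyond what the package itself produces.

## 1. Life tables

A life table is a survivorship vector `l_x` on one-year age classes,
1-based ages, with `l_1 = 1` (stored 0-based internally). Derived
quantities:

* per-class survival `P_x = l_{x+1} / l_x` for `x = 1..k−1`; the terminal
  class always dies (`P_k = 0`), so every table is implicitly closed;
* death distribution `d_x = l_x − l_{x+1}` with `l_{k+1} = 0`, which
  telescopes to `Σ d_x = 1`.

Tables may be built from raw cohort counts (`from_counts`), from
parametric families (section 5), or read from CSV (`age` column plus `l`
or `n`; extra columns are carried as annotations, e.g. a fecundity column
`m`). Validation rejects non-monotone survivorship and names the
offending rows.

## 2. Fecundity

A fecundity schedule is a per-age vector `m_x` (expected daughters per
female in class `x`). The default is Gaussian in age, `m_x ∝
N(x; mean = 27, sd = 7)`, evaluated at integer ages and normalized so the
net reproductive rate

```
R0 = Σ l_x m_x = 1
```

making the population stationary. Generation time is the mean age of
mothers, `T = Σ x l_x m_x / R0`, and the intrinsic growth rate is
approximated by `r = ln(R0)/T` (exactly 0 at `R0 = 1`).

**Shifting.** Displacing reproduction by `Δ` years re-evaluates the
Gaussian at `mean + Δ`, truncates to the age range, and re-normalizes to
`R0 = 1`; tabulated (non-Gaussian) schedules are rolled by whole years
instead. Shifting therefore changes `T` while holding `R0` fixed, which is
the comparison the whole package is built around. Truncation at the ends
of the age range means shift round-trips are exact only while no
probability mass falls off the table.

**Effective fecundity.** Under a birth-pulse, post-breeding census the
newborns attributed to class `x` parents are produced at rate
`f_x = P_{x−1} m_x`. The package uses `f_x` to weight parents when drawing
newborn allele frequencies. The deterministic projection matrix, however,
places `m_x` (not `f_x`) in the first row: with newborns censused at
birth, `R0 = Σ l_x m_x = 1` makes the dominant eigenvalue exactly 1 and
the stable age distribution proportional to `l_x`. Using `f_x` in the
first row would give `λ < 1` for any table with first-year mortality and
contradict the stationarity convention.

## 3. Demography metrics

* **Pace**: life expectancy `e0 = Σ l_x` (rectangle rule on yearly
  classes).
* **Keyfitz entropy**: `H = e† / e0`, where `e† = Σ d_x e_x` is life
  expectancy lost to death and `e_x` is the remaining expectancy of class
  `x`. This discrete life-table estimator gives `H = 1` exactly in the
  memoryless (constant-hazard) limit and `H → 0` for rectangular
  survival, which is why it is the default; the integral form
  `H = −Σ l_x ln l_x / Σ l_x` is available (`method="log"`, rectangle or
  trapezoid rule) and converges to the same values as the per-class
  hazard shrinks. Lifespan equality is `ln(1/H)`.
* **Shape**: `Ω/e0`, where `Ω` is the age by which 95% of *adults* have
  died, i.e. the first age where `l_x / l_maturity ≤ 0.05`; maturity
  defaults to the first age with appreciable fecundity.

## 4. Effective population size

The age-structured effective size is

```
Ne = Nnb · T / (1 + Σ_{x=1}^{k} l_x s_x d_x v_{x+1}²),   v_{k+1} = 0
```

with `Nnb` the annual newborn cohort size (census size divided by `Σ l_x`
in a stationary population), `T` the generation time, `d_x` the death
distribution, and `v_x` the reproductive value. Two choices are exposed:

* `v_mode="fisher"` (default): `v_x = Σ_{i≥x} l_i m_i / l_x`, Fisher's
  reproductive value with `v_1 = R0 = 1` and `v = 0` after the last
  reproductive age;
* `v_mode="as_printed"`: `v_x = R0 / l_x`, a simplification that ignores
  reproduction already completed.
* `s_mode="survival"` (default): `s_x = P_x`, the per-class survival
  probability, making the correction term a dimensionless demographic
  quantity independent of census size;
* `s_mode="counts"`: `s_x = Nnb · l_x`, which makes the correction scale
  with population size. With this weighting the Type-II `Ne(T)` curve is
  *decreasing* in the package's parameter regime rather than plateauing,
  contradicting both the linear/plateau contrast the formula is meant to
  exhibit and the forward simulations; it is retained only for
  comparison.

Structural property used in testing: if no deaths occur at any age with a
live reproductive future (`d_x v_{x+1}² = 0` for all `x`), the correction
vanishes and `Ne = Nnb·T` exactly.

## 5. Synthetic populations

All study populations are generated programmatically (no external data):

* **type1_modern** (`k = 101`): hazard = background 0.002 plus a Gompertz
  term `0.01·exp(0.12(x − 60))` after onset at age 60. Gives `e0 ≈ 72`,
  survivorship above 0.9 through the childbearing years, near-zero
  survival at the last class.
* **type1_preindustrial**: the modern hazards plus a juvenile spike
  `0.22·exp(−0.5(x−1))`; reduces exactly to the modern table when the
  spike amplitude is zero. `e0 ≈ 40`.
* **type2**: constant 10% annual mortality (`l_x = 0.9^{x−1}`), the
  memoryless reference with `H = 1` and `e0 → 10`.
* **type3**: power-law survivorship `l_x = x^{−2.126}`, front-loaded
  mortality.
* **rectangular** and **exponential** fixtures for analytic limits.

An optional lognormal hazard jitter (seeded) roughens the parametric
curves for robustness testing; it is off by default.

## 6. Drift simulator

One biallelic locus (A/B), genotype-resolved age-structured projection
with census size `N_total` (default 1000) on the stable age distribution.
Each replicate year:

1. **Reproduction**: the parental allele frequency is the
   effective-fecundity-weighted frequency over all classes,
   `p = Σ f_x (n_AA,x + n_AB,x/2) / Σ f_x n_x`. A fixed newborn cohort of
   `Nnb = round(stable newborn class)` individuals is drawn multinomially
   from Hardy–Weinberg proportions `(p², 2pq, q²)` — random mating with a
   constant annual birth pulse.
2. **Survival**: each age class is culled binomially at `P_x`
   per genotype (`cull_mode="binomial"`, default). A `"faithful"` variant
   instead keeps `floor(P_x · n_x)` survivors deterministically and
   allocates them multinomially across genotypes, pinning class totals.
3. **Selection**: with `s > 0`, the BB survival is multiplied by `(1 − s)`
   in the reproductive age window (classes with non-negligible `m_x`).
4. **Recording**: heterozygosity of the newborn cohort, `2p̂(1−p̂)` of the
   realized newborn frequency by default (`het_mode="expected"`) or the
   heterozygote fraction (`"observed"`). A replicate is absorbed once the
   whole population is monomorphic; heterozygosity stays 0 afterwards.

Randomness: one `numpy.random.SeedSequence(seed)` is spawned into
independent PCG64 streams, one per replicate, so runs are bit-reproducible
for a given seed and replicate count and replicates are statistically
independent.

**Reduction to Wright–Fisher.** With a single age class (`l = [1]`,
`m = [1]`) the model collapses to Wright–Fisher: the newborn allele-copy
count is `Binomial(2N, p)` exactly, which the acceptance suite checks
against the binomial oracle by chi-squared and by `Var(Δp) = p(1−p)/2N`.

**Martingale caveat.** The initial population apportions Hardy–Weinberg
genotype counts to integers within each age class (largest-remainder
rounding). For small classes the realized reproductive-value-weighted
allele frequency can deviate from the nominal `p0` by up to ~1%, and it
is this realized frequency — not nominal `p0` — that the neutral dynamics
conserve in expectation. Tests and analyses that need an exact starting
frequency should use configurations where the Hardy–Weinberg split is
integral.

**Implied Ne.** Fitting `H_t = H_0 ρ^t` by least squares on `log H_t`
gives a per-year retention `ρ` and an implied per-year effective size
`1/(2(1−ρ))`; dividing by `T` converts to per-generation units.

## 7. Numerical choices

* The stable age distribution is computed by power iteration on the
  Leslie matrix (at least 100 steps, then continued to a step-to-step
  relative change below 1e-12, capped at 50000 iterations). Step-to-step
  convergence at 1e-12 leaves a residual against the exact eigenvector of
  order 1e-8 relative when the subdominant eigenvalue is close to 1;
  consumers needing eigenvector-grade accuracy should use a dense solver.
* Dot-product round-off can push the parental allele frequency a few ULPs
  outside `[0, 1]`; it is clamped.
* Yearly rectangle-rule quadrature is used throughout (life expectancy,
  entropy, generation time); this is consistent with the 1-year class
  width and keeps identities like `Σ d_x = 1` exact.
* Simulation integer work uses numpy's vectorized binomial/multinomial
  samplers; no compiled extensions are required.

## 8. Limitations

* One sex (female-tracking), one locus, two alleles; no mutation,
  migration or linkage.
* Stationary populations only (`R0` normalized to 1); the simulator holds
  the newborn cohort size fixed rather than letting census size fluctuate.
* Viability selection only, applied to one homozygote in the reproductive
  window; no fecundity selection or dominance coefficient.
* The demography metrics assume single-year age classes; tables with
  other class widths must be resampled first.
* Synthetic survivorship families are stylized (constant background +
  Gompertz, constant hazard, power law); they are meant to span the
  survivorship-type spectrum, not to fit any particular species.
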