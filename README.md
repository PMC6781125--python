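# agedrift

Age-structured population genetics from life tables: demography metrics
(pace, shape, Keyfitz entropy), the age-structured effective population
size of Felsenstein's weighted-generations formula, and a stochastic
Leslie-matrix simulator of genetic drift and viability selection.

## The science in one paragraph

In a population with overlapping generations, the census size wildly
overstates how much genetic drift matters: many individuals alive at any
moment are before or past their reproductive years and contribute nothing
to the next newborn cohort. How much the effective population size `Ne`
falls below the census size — and how it responds to the *timing* of
reproduction — depends on the shape of the survivorship curve. With
Type-I survival (low mortality until a steep senescent decline, the
industrial-era human pattern), delaying reproduction stretches generations
without killing prospective parents, so `Ne` grows almost linearly with
generation time `T`. With Type-II survival (constant mortality at every
age), delaying reproduction exposes parents to proportionally more
cumulative mortality and the gain saturates. This package builds those
survivorship regimes synthetically, computes the demography and `Ne`
analytically, and checks the analytical story against a forward-in-time
stochastic simulation of heterozygosity loss.

## The model

* **Life table**: survivorship `l_x` on one-year age classes, `l_1 = 1`,
  with per-class survival `P_x = l_{x+1}/l_x` and the terminal class dying.
* **Fecundity**: per-age schedule `m_x`, by default Gaussian in age
  (mean 27, sd 7 years), normalized so the net reproductive rate
  `R0 = Σ l_x m_x = 1` (stationary population). Shifting the schedule
  along the age axis moves the generation time
  `T = Σ x l_x m_x / R0` without changing `R0`.
* **Demography metrics**: life expectancy `e0 = Σ l_x` (pace), Keyfitz
  entropy `H = e†/e0` and lifespan equality `ln(1/H)`, and the shape score
  `Ω/e0` where `Ω` is the age by which 95% of adults have died.
* **Effective size**: `Ne = Nnb·T / (1 + Σ l_x s_x d_x v_{x+1}²)`, where
  `Nnb` is the annual newborn cohort size, `d_x` the fraction of a cohort
  dying in class `x`, `v_x` Fisher's reproductive value and `s_x` the
  per-class survival probability (alternative weightings are exposed as
  `s_mode` / `v_mode`).
* **Drift simulator**: one biallelic locus, genotype-resolved Leslie-matrix
  projection. Each year a fixed newborn cohort is drawn multinomially from
  Hardy–Weinberg proportions at the fecundity-weighted parental allele
  frequency, then every age class is culled binomially at `P_x`; optional
  viability selection multiplies the survival of one homozygote by
  `(1 − s)` during the reproductive ages. Heterozygosity `2p(1−p)` of each
  newborn cohort is recorded until fixation or the time horizon.

## Worked example

```python
import agedrift as ad

populations = ad.default_populations()      # three synthetic populations
print(ad.metrics_table(populations, N_total=1000.0)
        [["population", "e0", "H", "shape", "T", "Nnb", "Ne"]].round(3))
```

Output (census size 1000):

```
         population     e0     H  shape      T     Nnb      Ne
       type1_modern 71.936 0.165  1.251 26.904  13.901 358.234
type1_preindustrial 40.313 0.703  2.183 26.896  24.806 392.742
              type2 10.000 1.000  3.000 21.864 100.002 758.725
```

The modern Type-I table lives long (`e0` ≈ 72, near-rectangular survival:
`H` ≈ 0.17), produces only ~14 newborns per year at census 1000, and has
`Ne` ≈ 358 — about a third of the census size. The Type-II table turns
over fast (`e0` = 10, `H` = 1) with 100 newborns a year.

Sweeping the reproductive schedule ±20 years
(`examples/02_ne_vs_generation_time.py`):

```
type1_modern            T  10.4.. 58.5  Ne  143.3.. 730.1  R^2 0.999
type1_preindustrial     T   9.9.. 58.5  Ne  162.5.. 820.2  R^2 1.000
type2                   T   7.5.. 53.8  Ne  526.5.. 837.0  R^2 0.785  (plateau)
```

and the forward simulation agrees (`examples/03_drift_across_life_histories.py`,
200 replicates × 300 years, seed 12345): with Type-I survival the fast
life history (T ≈ 9) retains a median heterozygosity of 0.436 against
0.490 for the slow one (T ≈ 47) — clearly separated boxes — while for
Type-II the two are statistically indistinguishable (0.489 vs 0.486).
Under strong selection (s = 0.1) the differences between survivorship
types collapse (`examples/04_selection_regimes.py`).

The `examples/` directory contains five narrative scripts covering each
capability; `examples/05_custom_life_table.py` shows the CSV-based
workflow for your own data. A thin CLI wraps the same functions:

```bash
agedrift synth --family type1_modern --k 101 --out modern.csv
agedrift metrics modern.csv
agedrift ne-curve modern.csv --shifts=-20:21:2 --out curve.csv
agedrift drift --lifetable modern.csv --years 300 --replicates 200 \
    --seed 1 --out run/
```

## Reproduction

All headline quantities can be recomputed from scratch with

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~4 minutes on one CPU; every stochastic stage derives its seed from the
one `--seed`, so the JSON is bit-reproducible). The test suite's
`tests/test_acceptance.py` asserts the qualitative claims above: analytic
life-table limits, exactness of the `Ne` formula against an independent
single-expression oracle, linear-vs-plateau `Ne`(T) curves, agreement of
the one-age-class limit with a Wright–Fisher binomial oracle, the
martingale and absorption properties of the neutral simulator, the
fast/slow drift comparison, the two selection regimes, and implied-`Ne`
recovery from geometric heterozygosity decay.

See `docs/methods.md` for assumptions, parameter choices, numerical
details and limitations.
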