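# thermoniche

Antibiotics reshape how *E. coli* responds to temperature: they can shift
the optimal growth temperature (usually to the left), narrow the thermal
niche, and — in drug pairs — hand control of the combined optimum to a
single "driver" drug. `thermoniche` is an analysis pipeline for
quantifying these effects from endpoint growth data (OD600 at 24 h across
a panel of incubation temperatures), aimed at microbiologists and
ecologists studying stressor-by-temperature interactions.

## The model

Growth versus temperature is described by the modified Briere curve

```
g(T) = c (T − Tmin)^a (Tmax − T)^b ,     a, b ≥ 0,
```

a flexible-skew thermal performance curve with closed-form optimum
`Topt = α·Tmax + (1 − α)·Tmin`, `α = a/(a+b)`. It is fit in the canonical
parametrization `(g_max, α, s, Tmin, Tmax)` with `s = a + b`, where
`g_max` is peak growth, `α` locates the optimum and `s` sets steepness.
The *thermal niche* is the interval between the two temperatures giving
half-maximal growth; its width is the breadth.

Per condition (no drug, single drug, or drug pair), observations follow a
hierarchical Gamma model:

```
y_i | g(T_i), σ_Ti ~ Gamma(mean = g(T_i), sd = σ_Ti)
σ_T | β           ~ halfCauchy(β)         one σ per plated temperature
β                 ~ halfCauchy(0.3)
```

The posterior is approximated by a full-rank Gaussian in unconstrained
space (mode + curvature), sharpened by Pareto-smoothed importance
resampling; conditions the PSIS diagnostic flags are refit with a seeded
ensemble MCMC sampler. Point estimates are posterior means; intervals are
equal-tailed 95% credible intervals, with derived quantities (`Topt`,
half-max temperatures, breadth) computed per draw.

Downstream stages:

* **Shift classification** — a condition's optimum/breadth is called
  left- or right-shifted when its credible interval does not overlap the
  control's.
* **Combination-optimum models** — for each drug pair, the fitted pair
  optimum is compared to five candidate rules (`min`, `max`, `mean` of
  the single-drug optima, or `attenuated`/`elevated` beyond both by more
  than a 2.20 °C cutoff); single-driver categories attribute a driver
  drug.
* **Driver-dominance permutation tests** — a global dispersion statistic
  D = Σ_d (M_d − n_d/2)² and per-drug counts M_d are tested against the
  fair-coin null that either member of a pair is equally likely to drive,
  with Benjamini–Hochberg correction for the per-drug tests.
* **Bliss independence** — the expected drug curve under independence is
  `g̃_a(T) = g_0(T) · g_a(Tref)/g_0(Tref)` with `Tref` the unstressed
  optimum; growth below the null is temperature–drug synergy, above it
  antagonism.

A synthetic-data module generates study-shaped datasets (7 temperatures:
22–46 °C, 4 replicates, 12 drugs, configurable pairs) from known truth
curves using exactly the fitting likelihood, so every stage can be scored
against ground truth without any download.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_fit_response_curves.py
python analysis/03_classify_niche_shifts.py
python analysis/04_select_combination_models.py
python analysis/05_test_driver_dominance.py
python analysis/06_bliss_interaction_profiles.py
```

Output from a run of scripts 01–04:

```
wrote 924 observations (12 single drugs, 20 pairs + control) to .../results/synthetic_study
control truth: t_opt 37.7 C, breadth 15.0 C, g_max 0.50

fitted 33 conditions -> .../results/fits/summaries.csv
no-drug optimum: 36.94 C (95% CI 36.23-37.59; generating truth 37.7 C)
no-drug niche breadth: 15.15 C (truth 15.0 C)

single-drug optimum shifts vs control: {'overlap': 8, 'lower': 4}
single-drug breadth calls: {'overlap': 12}

model frequencies: min 25%, max 25%, mean 15%, attenuated 15%, elevated 20%, multiple 0%
single-driver share: 85%
truth recovery on well-separated pairs: 8/10
```

Reading this: the fitted no-drug optimum lands within ~0.8 °C of the
generating truth with a ~1.4 °C-wide credible interval; the four drugs
engineered with the largest left shifts (GEN, TOB, STR — the
aminoglycoside-like effects — plus TMP) are exactly the ones called
`lower`; and the five-model classifier recovers the
generating combination category for 8 of the 10 pairs whose single-drug
optima are at least 2 °C apart (misses occur when the truth places the
pair optimum within fit noise of the 2.20 °C cutoff).

The same pipeline runs on real data from a tidy CSV with columns
`drug1, drug2, temperature_c, replicate, od600_24h`:

```bash
thermoniche run-all growth.csv --out results/run --seed 1
```

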