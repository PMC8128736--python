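# iwspkpd

Mechanism-based PKPD modelling of **iatrogenic withdrawal syndrome (IWS)**
in critically ill children.

Children in intensive care who receive opioids and sedatives by continuous
infusion for days to weeks become physically dependent; weaning those
infusions too fast precipitates withdrawal. `iwspkpd` is for
pharmacometricians and intensive-care researchers who want to treat IWS
risk as a *dynamic* quantity — driven by the dosing history — rather than
a static incidence, and to compare weaning strategies quantitatively.

## The model

For each drug *j*, plasma concentration C_plasma(t) (from a linear
compartmental PK model with allometric weight scaling) feeds a
hypothetical *dependence compartment*:

    dC_dep/dt = k_dep,j · (C_plasma − C_dep)

C_dep is the exposure level the child has adapted to. The *concentration
shortage* drives withdrawal severity linearly and only when plasma no
longer covers the dependence level:

    Effect_j = slope_j · (C_dep − C_plasma)   if C_dep > C_plasma, else 0
    λ_i(t)   = Baseline · e^{η_i} + Σ_j Effect_j(t),    η_i ~ N(0, ω²)

The integer withdrawal score Y ∈ {0,…,10} follows a truncated generalized
Poisson distribution with dispersion δ, p(y) ∝ λ(λ+δy)^{y−1}e^{−λ−δy}/y!,
renormalized over 0–10, with a Markov probability inflation (π0|0, π0|x,
π±1 = π±2) on scores within two points of the previous observation.
Scores above 3 indicate IWS requiring intervention, so P(Y > 3) is the
risk read-out. Parameters are estimated by Laplace-approximated marginal
maximum likelihood (adaptive Gauss–Hermite quadrature as an oracle), with
OFV/AIC model comparison, empirical-Bayes η's, numerical-Hessian standard
errors, and residual/mirror diagnostics. A seeded synthetic-cohort
generator reproduces the whole data-generating chain for recovery studies.
See `docs/methods.md` for the full account.

## Worked example: how should a morphine infusion be weaned?

A typical 10-kg child has received intravenous morphine at 20 mcg/kg/h for
14 days. Compare stopping abruptly with tapering by 10% of the initial
rate every 24 h or every 48 h:

```python
from iwspkpd import WeaningScenario, compare_strategies, published_params
from iwspkpd.synthetic import default_pk_parameters

pk, iws = default_pk_parameters(), published_params()
scenarios = [
    WeaningScenario("morphine", weight=10.0, initial_rate_per_kg=0.02,
                    treatment_duration_h=336.0, abrupt=True, label="abrupt stop"),
    WeaningScenario("morphine", weight=10.0, initial_rate_per_kg=0.02,
                    treatment_duration_h=336.0, step_fraction=0.1,
                    step_interval_h=24.0, label="10% every 24 h"),
    WeaningScenario("morphine", weight=10.0, initial_rate_per_kg=0.02,
                    treatment_duration_h=336.0, step_fraction=0.1,
                    step_interval_h=48.0, label="10% every 48 h"),
]
print(compare_strategies(scenarios, pk["morphine"], iws).to_string(index=False))
```

```
      scenario  peak_risk  time_of_peak_h  risk_auc_above_baseline  hours_above_1.5x_baseline
   abrupt stop   0.232773           347.5                19.239627                      179.0
10% every 24 h   0.149235           557.5                18.803095                      239.5
10% every 48 h   0.117864           775.0                18.482324                      205.0
```

The drug-free baseline risk of a typical patient is 0.071. Abrupt
discontinuation roughly triples it (peak 0.233 shortly after the stop at
day 14), because two weeks of infusion have raised C_dep near steady
state while plasma washes out in hours. Tapering narrows the gap between
plasma and dependence concentrations: the 10%/24 h taper peaks at 0.149
and the gentler 10%/48 h taper at 0.118, at the cost of a longer weaning
period — the area of risk above baseline is similar, but the peak (the
moment of highest clinical concern) is much lower. Because fentanyl
equilibrates its dependence ~30× faster than morphine, the same
comparison for fentanyl favours *small, frequent* rate reductions, while
morphine weaning is insensitive to the step interval.

The same machinery is available from the shell:

```
iwspkpd generate --n 20 --seed 7 --out run/
iwspkpd fit --data run/cohort.csv --seed 1 --out run/fit/
iwspkpd diagnose --data run/cohort.csv --fit-json run/fit/fit_result.json --out run/diag/
iwspkpd scenario --drug morphine --rate 0.02 --treatment-days 14 --abrupt --out risk.csv
```

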