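# ichthyospec

Size-structured trophic transfer modelling of deep-sea ichthyolith
(microfossil fish tooth) records.

## The problem

Fish teeth are essentially the only fossil that pelagic fish leave in
deep-sea red clay, and their accumulation rate (IAR, ichthyoliths cm⁻²
Myr⁻¹) is a proxy for total fish production.  Given a record of individual
tooth lengths and accumulation rates through time, plus an independent
paleotemperature curve, two questions follow:

1. How does total fish production relate to ocean temperature on
   million-year timescales?
2. Which ecological driver — trophic transfer efficiency, total primary
   production, or predator–prey size structure — best explains the observed
   changes in the tooth size–abundance distribution?

`ichthyospec` answers both with a minimal size-spectrum food-web model
calibrated to the record by least squares, a battery of single-parameter
time-varying experiments ranked by RMSE reduction, and a quadratic
IAR–temperature regression.  A synthetic-data generator built on the same
forward model makes every stage testable without any downloads.  It is aimed
at quantitative paleoecologists and modellers working with microfossil
accumulation records.

## The model

Body sizes live on `N = 200` log-spaced bins spanning 10⁻⁷–10¹ m.  Primary
production is Gaussian in arithmetic size with mean `P₁^µ` and spread `P₁^σ`
(µm).  Production passes up five trophic levels: each transfer multiplies
the total by the trophic efficiency `α` and redistributes it by a Gaussian
diet kernel in log₁₀ size centred on the preferred prey size `φ·s` (a
fraction `φ` of predator size `s`) with spread `σ`.  Level totals obey

    Σᵢ P_{i,l} = α^(l−1) · Σᵢ P_{i,1}        (exactly, by construction)

Top-level production is mapped to tooth lengths through a community-average
power-law allometry `S_body = a·S_tooth^b` and compared, as a density on a
106–2000 µm axis, with the kernel-smoothed observed tooth densities in each
Myr bin.  The static reference fit calibrates
`θ = {a, b, α, σ, φ, P₁^µ, P₁^σ}`; the time-varying experiments then free
one parameter per Myr bin and report the RMSE reduction factor versus the
reference — the model-ranking statistic.  See `docs/methods.md` for the full
account, including why predictions use the single top level and why
propagation is exactly mass-conserving.

## Worked example

Simulate a record in which trophic transfer efficiency drives a ~10-fold
production excursion, fit the reference model, and rank the four candidate
drivers:

```python
from ichthyospec import RunConfig, run_full_analysis

report = run_full_analysis(RunConfig(scenario="alpha-driven", seed=1, n_starts=8, run_sweep=False))
r = report["results"]
print(f"IAR fold range        : {r['iar_fold_range']:.1f}")
print(f"intra-bin SD          : {r['intra_bin_sd_pct']:.1f} %")
for name, tv in r["time_varying"].items():
    print(f"reduction factor {name:9s}: {tv['reduction_factor']:6.2f}"
          f"  (max change {tv['max_pct_change_per_bin']:.0f} %/Myr)")
print(f"size-scaling RMSE ratio: {r['pp_size_scaling']['rmse_ratio_vs_unscaled']:.2f}")
reg = r["regression"]
print(f"IAR ~ T + T^2: R^2 = {reg['r_squared']:.2f}, "
      f"F p = {reg['p_value']:.2g} (n = {reg['n']})")
```

prints

```
IAR fold range        : 11.3
intra-bin SD          : 10.3 %
reduction factor alpha    :   8.18  (max change 15 %/Myr)
reduction factor total_pp :   8.18  (max change 75 %/Myr)
reduction factor phi      :   1.35  (max change 16 %/Myr)
reduction factor sigma    :   1.32  (max change 64 %/Myr)
size-scaling RMSE ratio: 5.98
IAR ~ T + T^2: R^2 = 0.97, F p = 3.9e-06 (n = 29)
```

Reading this: the record spans an 11-fold IAR range with ~10% within-bin
noise.  Freeing efficiency (`alpha`) or total primary production per Myr bin
improves the fit ~8-fold over the static reference — the two are
observationally equivalent scale controls and tie — while the predator–prey
experiments (`phi`, `sigma`) barely help.  The discriminating diagnostic is
the variation each driver needs: efficiency explains the record with ~15%
changes per Myr where primary production needs ~75%.  Forcing phytoplankton
mean size to track production (`size-scaling`) makes the fit six times
worse, and binned IAR is a strongly significant quadratic function of
temperature.

The same pipeline runs from the shell:

```sh
ichthyospec simulate --scenario alpha-driven --seed 1 --out runs/demo
ichthyospec fit-reference --data-dir runs/demo
ichthyospec fit-timevarying --data-dir runs/demo --param alpha --max-pct 10
ichthyospec regress --data-dir runs/demo
ichthyospec run-all --scenario alpha-driven --seed 1 --out runs/full
```

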