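# flcseason

Analysis toolkit for seasonal chromatin regulation of *FLC*-type floral
repressors in naturally fluctuating environments. The package is aimed
at molecular ecologists and systems biologists working with long-term
field time series of gene expression and histone modifications
(ChIP-qPCR / RT-qPCR at biweekly resolution over multiple years), and
implements four connected analyses plus the synthetic-data generators
needed to validate them end to end:

1. **Temperature-memory regression** — linear regression of each
   molecular variable on simple moving averages (SMA) of past daily
   temperature over a scan of window lengths; the window maximising R²
   is the variable's temperature memory.
2. **Lissajous phase analysis** — per-year min–max normalisation of two
   cyclical series and a signed-area (shoelace) rotation statistic that
   formalises clockwise/anticlockwise phase readings.
3. **Empirical dynamic modelling (EDM)** — from-scratch delay
   embedding, simplex projection with embedding-dimension selection by
   minimum forecast RMSE (E = 1–24), lagged convergent cross-mapping
   (tp = −8…4), seasonal surrogates, and a two-criterion causality
   verdict (surrogate exceedance at the maximum library size and
   convergence of cross-map skill with library size > 0.1).
4. **Temperature-forced chromatin-state model** — four locus states of
   H3K27me3 over the nucleation region (NR) and distal nucleation
   region (DNR) cycling UU → MU → MM → UM → UU, H3K4me3 balance
   equations at both regions, four logistic thermosensors (thresholds
   5, 10, 15, 5 °C), three mark–mark feedbacks, model variants 1–4, a
   per-locus stochastic counterpart whose ensemble mean matches the
   deterministic equations, an mRNA link
   `log10(RNA) = σ·log10(K4 at NR) + ω`, and the two-stage fitting
   procedure (uniform random search within [0, 100], then simulated
   annealing).

The model, in the field's notation (uN = 1−aN, uD = 1−aD):

    d(uNuD)/dt = λ·uNmD      − μ(T)·uNuD
    d(mNuD)/dt = μ(T)·uNuD   − ν(T)·mNuD
    d(mNmD)/dt = ν(T)·mNuD   − κ·aN·mNmD
    d(uNmD)/dt = κ·aN·mNmD   − λ·uNmD
    d(aN)/dt   = ξ(T)·(1−aD)·uN − φ·(mNuD+mNmD)·aN
    d(aD)/dt   = τ(T)·(1−aN)·uD − ψ·(mNmD+uNmD)·aD

with μ, τ cold-activated and ν, ξ warm-activated logistic functions of
temperature, e.g. μ(T) = ζ / (1 + exp(α(T − θ₁))).

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

Generate a synthetic two-year campaign (biweekly sampling, 4
replicates, 10% multiplicative noise, seasonal AR(1) temperature
forcing) and run the temperature-memory scan and phase analysis:

```python
import numpy as np
from flcseason import (
    TemperatureModel, ObservationNoise, default_params,
    gen_temperature, gen_observations, scan_windows,
    normalise_yearly, lissajous,
)

temp = gen_temperature(TemperatureModel(seed=1), n_years=3)
obs = gen_observations(default_params(), temp, ObservationNoise(seed=2))

for label in ("mRNA", "K4_NR", "K4_DNR", "K27_NR", "K27_DNR"):
    res = scan_windows(obs[label], temp, np.arange(1, 169))
    print(f"{label:8s} best window {res.best_window:3d} d  "
          f"R2 = {np.nanmax(res.r2):.3f}")

liss = lissajous(normalise_yearly(obs["K4_NR"]),
                 normalise_yearly(obs["K27_NR"]))
print(f"K4 vs K27 Lissajous: {liss.orientation}, "
      f"signed area {liss.signed_area:+.3f}")
```

```
mRNA     best window  35 d  R2 = 0.884
K4_NR    best window  35 d  R2 = 0.877
K4_DNR   best window  20 d  R2 = 0.935
K27_NR   best window  28 d  R2 = 0.904
K27_DNR  best window  28 d  R2 = 0.435
```

The distal nucleation region responds to a markedly shorter stretch of
past temperature than the other variables — the signature of distinct
thermosensors at the two regulatory regions — and

```
K4 vs K27 Lissajous: clockwise, signed area -0.081
```

the clockwise rotation of the K4–K27 trajectory means the repressive
mark's seasonal cycle is delayed relative to the active mark's.

Causality is tested by convergent cross-mapping. On a benchmark where
the direction is known — coupled logistic maps in which y forces x and
not vice versa — the verdict machinery recovers it:

```python
from flcseason import AnalysisConfig, detect_causality, \
    gen_coupled_logistic

cfg = AnalysisConfig(n_library_draws=25)
x, y = gen_coupled_logistic(3.8, 3.7, beta_xy=0.1, beta_yx=0.0,
                            n=1000, seed=2)
for r in detect_causality(x, y, cfg, labels=("x", "y")).values():
    print(r.summary())
```

```
{'direction': 'x xmap y', 'best_tp': -1, 'rho_max': 0.926,
 'surrogate_q95': 0.076, 'convergence_delta': 0.884, 'verdict': 'causal'}
{'direction': 'y xmap x', 'best_tp': 4, 'rho_max': 0.211,
 'surrogate_q95': 0.060, 'convergence_delta': 0.073,
 'verdict': 'not causal'}
```

"x xmap y" (predicting y from x's reconstruction) tests the effect of y
on x: the best skill at a negative lag, far above the surrogate
envelope and strongly convergent, declares the true direction causal,
while the reverse direction fails both the lag and convergence
criteria. On the synthetic campaign itself, the same test between
K27_NR and K4_NR returns "not causal" in both directions: the simulated
marks are almost entirely seasonally driven, and the seasonal-surrogate
null absorbs their mutual predictability — exactly the guard against
seasonality-induced false positives doing its job.

A shell interface wraps the same library:

```bash
flc-season synth --out campaign/ --seed 4
flc-season sma --obs campaign/obs.csv --temp campaign/temp.csv \
    --windows 1:168 --out scan.csv
flc-season lissajous --obs campaign/obs.csv --x K4_NR --y K27_NR \
    --out liss.csv
flc-season fit --obs campaign/obs.csv --temp campaign/temp.csv \
    --draws 200 --out fit/
```

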