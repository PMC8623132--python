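# decorpkin

Kinetic analysis of whole-body radionuclide **decorporation** — the removal
of an internally deposited radionuclide (here ⁶⁵Zn) from the body by
chelation therapy (Zn-DTPA). The package is aimed at radiobiologists and
pharmacokineticists who need to turn whole-body counting time series from
small-animal chelation studies into rate constants, half-lives and
model-comparison verdicts, and to test those analysis steps on simulated
data with a known ground truth.

## What it computes

Given group-level percent-retention series (whole-body activity normalized
to a reference day, mean ± SEM over animals), decorpkin provides:

* **Model-free summaries** — area under the retention curve (AURC,
  trapezoidal, %·day), retention at a query day, and OLS dose–response
  lines of those metrics against chelator dose.
* **Compartmental models.** The two-compartment system (blood *b*, deep
  tissue *d*, urinary elimination)

  ```
  dC_b/dt = −(k_bd + k_e) C_b + k_db C_d,    C_b(0) = C₀
  dC_d/dt =   k_bd C_b − k_db C_d,           C_d(0) = 0
  ```

  with its closed-form biexponential solution
  `C_b(t) = A e^{−αt} + B e^{−βt}` where α ≥ β are the roots of
  `λ² − (k_bd+k_db+k_e)λ + k_db k_e = 0`, exact micro ↔ macro parameter
  conversion, half-lives `t½ = ln2/k`, a numeric ODE oracle, and the
  degeneration to a mono-exponential when one phase vanishes.
* **Diffusional model.** Fick diffusion from an "infinite" tissue
  reservoir into a semi-infinite medium: profile
  `C(x,t) = C_d0 erfc(x/2√(Dt))`, boundary flux `J = C_d0 √(D/πt)`,
  cumulative transfer `Q(t) = 2AC_d0 √(Dt/π)`, the empirical square-root
  retention law `%R = a − b√t`, and a Crank–Nicolson finite-difference
  oracle.
* **Fitting & selection** — bounded trust-region least squares with
  curve-stripping initialization and multi-start, two-phase segmented
  log-linear regression with exhaustive breakpoint search, and R²-based
  model comparison.
* **Synthetic data** — a generator reproducing the three rat experiment
  designs (7 rats/arm, daily whole-body counts; immediate single/repeated
  chelator dosing measured days 0–10, and a delayed five-day course on
  days 12–16 measured days 13–23) with exact piecewise compartmental
  kinetics and log-normal measurement noise.

## Worked example

```python
from decorpkin import fit_model, fit_two_phase, simulate_group
from decorpkin.simulate import default_truth, get_design

design = get_design("exp2_high")                     # 5 mg pre-dose arm
truth = default_truth("exp2_high", noise_sigma=0.02, seed=1)
rats, series = simulate_group(design, truth)         # 7 rats, days 0-10

res = fit_model("bicompartment", series, options={"observable": "blood"}, seed=1)
print(res.summary())
```

```
Model: bicompartment   window: [0, 10] d   n = 11
R2 = 0.999941   SSE = 0.313818   converged = True
         param       estimate      std err
          k_bd        1.76354      0.05836
          k_db        1.21012      0.04487
           k_e       0.188728     0.002052
            c0            100       0.2117
derived: alpha = 3.088, beta = 0.07395, t_half_e = 3.673, t_half_terminal = 9.373
```

The fit recovers the generating transfer rates (k_bd = 1.77, k_db = 1.21,
k_e = 0.19 day⁻¹) from the noisy group mean; the derived elimination
half-life `ln2/k_e ≈ 3.7 d` and the fast/slow exponents α, β follow. A
segmented log-linear fit on the same data locates the biphasic inflection:

```python
print(fit_two_phase(series, window=(1, 10)).summary())
```

```
Two-phase log-linear fit on [1, 10] d
breakpoint = 2.5 d   pooled SSE (log) = 0.000430422
phase 1: slope = -0.15118 /d  intercept = 3.7849  R2 = 1.00000  t1/2 = 4.585 d
phase 2: slope = -0.07478 /d  intercept = 3.6349  R2 = 0.99817  t1/2 = 9.269 d
```

The same operations are available from the shell:

```
decorpkin simulate --arm exp2_high --seed 1 --out data/
decorpkin analyze --out results/            # full pipeline, JSON report
decorpkin compare --input data/exp2_high_group.csv --models sqrtlaw,monoexp
```

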