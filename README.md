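# eslreg

Robust linear regression with the **exponential squared loss (ESL)**,
built for covariate-adjusted efficacy estimation in randomized
controlled trials whose residuals are not normally distributed —
outcome scores contaminated by measurement error or a heavy-tailed
mixture component, where ordinary least squares (OLS) loses efficiency
or breaks down outright.

## The estimator

For the linear model y_i = x_i'β + ε_i, the coefficients maximise

> l_n(β) = Σ_i exp(−(y_i − x_i'β)² / γ),

equivalently minimise the total bounded loss
Φ_γ(t) = 1 − exp(−t²/γ).  Boundedness caps the influence of any single
observation; the tuning parameter γ trades robustness against
efficiency (γ → ∞ recovers OLS).  The pipeline is:

1. **Initial estimate** — a high-breakdown MM regression estimate
   (bisquare S-stage at c0 = 1.547 with 500 elemental subsamples, then
   a bisquare M-stage at c1 = 4.685 with the S-scale fixed).
2. **Pseudo-outlier screen** — residual scale S_n = 1.4826 · MAD;
   observations with |r_i| ≥ 2.5 S_n form the pseudo-outlier set
   (size m).
3. **Data-driven γ** — among a geometric grid of candidates whose
   feasibility functional ζ(γ) = 2m/n + (2/n) Σ Φ_γ(r_i) lies in
   (0, 1], pick the γ minimising det V̂(γ), the determinant of the
   sandwich covariance V̂ = Î₁⁻¹ Σ̂ Î₁⁻¹.
4. **Re-maximise** l_n at the selected γ by monotone IRLS, and repeat
   2–4 until ‖β_old − β_new‖ < 10⁻².

Inference is by case-resampling percentile bootstrap, re-running the
entire pipeline (including γ re-selection) on every resample.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Fit a synthetic two-arm, eight-centre trial table (the bundled
generator emulates a cognitive-score RCT with a 90/10
normal/heavy-tail error mixture and a true treatment effect of zero):

```python
import eslreg as E
from eslreg.simulation import mci_like_spec

frame = E.mci_like_frame(214, 106, seed=1)           # 2:1 allocation
model = E.ESLRegression.from_dataframe(frame, mci_like_spec())
res = model.fit(config=E.FitConfig(mm=E.MMConfig(seed=1)))
ci = res.bootstrap_ci(B=400, seed=1)
print(res.summary(ci))
```

```
Exponential-squared-loss regression
=================================================================
n = 320    p = 16    gamma = 146.081    m (pseudo-outliers) = 11
converged = True (outer iterations: 3)
-----------------------------------------------------------------
term                estimate       lower       upper  excl. 0
const                 1.4036     -2.8557      6.3643
age                  -0.0783     -0.1387     -0.0228        *
bmi                   0.1086     -0.0119      0.2074
ADAS1                 0.3659      0.2896      0.4449        *
group                -0.1607     -1.0352      0.6742
centre[1]             1.5845      0.0890      3.0461        *
...
-----------------------------------------------------------------
95% percentile bootstrap, B = 400, failed resamples = 0
=================================================================
```

Reading the output: the selected γ ≈ 146 sits well above the squared
residual scale, so clean observations keep weights near 1 while the
11 flagged pseudo-outliers are down-weighted.  The baseline score
(`ADAS1`, estimate 0.37) is significant — worse baselines leave more
room for improvement — while the treatment-arm coefficient (`group`,
−0.16 with interval (−1.04, 0.67)) is indistinguishable from its true
value of zero.

The Monte-Carlo benchmark comparing ESL with OLS under t(1)
contamination is available both from Python
(`eslreg.run_replications`) and the CLI:

```bash
eslreg simulate --contamination 0.2 --reps 100 --n 300 --seed 1 --out sim
eslreg fit --data trial.csv --config model.yaml --out fit
eslreg bootstrap --data trial.csv --config model.yaml -B 1000 --seed 1 --out ci
```

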