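# burstfish

Tools for quantifying transcriptional bursting from single-molecule RNA FISH
(smFISH) data. Bacterial genes are often transcribed in bursts — short
episodes of mRNA synthesis separated by silent intervals — and smFISH gives
the per-cell transcript counts from which burst kinetics can be inferred.
`burstfish` covers the full quantitative path:

* **Spot calibration** — convert per-spot integrated fluorescence intensities
  into per-cell mRNA copy numbers: a false-positive threshold at the 99.9th
  percentile of a no-target control, a Gaussian-mixture fit whose first
  (lowest-mean) component is the single-molecule unit intensity, and the
  total-intensity / unit-intensity division rule.
* **Noise statistics** — per-population mean μ, standard deviation σ, noise
  CV² = σ²/μ², burstiness (Fano factor F = σ²/μ, with F = 1 the Poisson
  line), silent (count 0) and transcriptionally-on (count ≥ 1) fractions,
  exact small-sample Spearman permutation tests, and one-phase exponential
  decay regression y(x) = (y₀ − plateau)·e^(−kx) + plateau.
* **Burst inference** — a Bayesian zero-inflated negative binomial (ZINB)
  model of the count distribution,

      P(0)   = ω + (1 − ω)(1 − p)^r
      P(k>0) = (1 − ω)·C(k+r−1, k)·p^k·(1 − p)^r,

  fitted by Metropolis–Hastings MCMC with Uniform(0,1) priors on ω and p and
  a half-normal (σ = 20) prior on r. The NB component is the stationary law
  of a gene producing geometric bursts, so the posterior maps directly to
  repression ω, burst size b = p/(1 − p), and burst frequency f = r; the MAP
  and equal-tailed 95% credible intervals are reported.
* **Synthetic data** — ZINB count samplers, an exact telegraph-model
  (two-state promoter) simulator used as an independent mechanistic oracle,
  and quantal spot-table generators, so the whole pipeline runs and is tested
  without any external data.

## Worked example

```python
import burstfish as bf

# ground truth: half the cells repressed, bursty NB counts otherwise
truth = bf.ZINBParams(omega=0.5, r=2.0, p=0.7)     # b = 2.33, f = 2
counts = bf.sample_zinb(truth, 2000, seed=4)

# emulate smFISH spots (unit intensity 100 a.u., 5% CV) and re-quantify
table = bf.generate_spot_table(100.0, 0.05, counts, n_control=2000,
                               control_scale=12.0, seed=5)
cal = bf.IntensityCalibrator(n_components=3, random_state=0).fit(table)
est_counts = bf.quantify_counts(table, cal.calibration_)

summary = bf.summarize_counts(est_counts)[0]
print(f"mu={summary.mu:.3f} fano={summary.fano:.3f} "
      f"silent={summary.frac_silent:.3f}")

model = bf.ZINBBurstEstimator(n_iter=50_000, burn_in=10_000, thin=25,
                              random_state=7).fit(est_counts)
print("MAP:", {k: round(v, 3) for k, v in model.map_.items()})
print("95% CI:", {k: [round(x, 3) for x in v] for k, v in model.ci95_.items()})
```

Output:

```
mu=2.441 fano=5.576 silent=0.531
MAP: {'omega': 0.489, 'b': 2.254, 'f': 2.121}
95% CI: {'omega': [0.464, 0.516], 'b': [1.862, 2.635], 'f': [1.813, 2.615]}
```

The Fano factor well above 1 flags bursty expression; the MAP burst size 2.25
and frequency 2.12 recover the generating values b = 2.33 and f = 2 within
their credible intervals, and ω ≈ 0.49 recovers the repressed fraction.

The same stages run from the shell:

```bash
burstfish all --config config.json --seed 1 --out-dir results/
```

producing count tables, `noise_summary.csv`, `stats.json` (Spearman and decay
fits of noise/burstiness versus mean), and `burst_estimates.json` per
strain × condition group.

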