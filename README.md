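# egmentropy

Sample Entropy robustness analysis of atrial electrograms under
acquisition artifacts.

## The problem

During catheter ablation of atrial fibrillation, intracardiac atrial
electrograms (AEGM) are mapped to locate complex fractionated atrial
electrograms (CFAE) — the irregular, multi-deflection signals that mark
candidate ablation sites. Sample Entropy (SampEn) is an attractive
single-number discriminator between non-fractionated ("NC") and
fractionated ("C") electrograms, but catheter recordings are plagued by
one-sample spikes (sensor artifacts) and missing samples (poor contact,
unstable positioning). This package quantifies how much of the NC/C
separation survives those artifacts.

For a series x₁,…,x_N, templates of length m are compared with the
Chebyshev distance d_ij = max_k |x_{i+k} − x_{j+k}|, self-matches
excluded, and

    SampEn(m, r, N) = −ln( A / B ),

where B is the number of template pairs with d_ij(m) ≤ r and A the number
still within r at length m+1. Throughout, m = 2 and r = 0.2 × SD of the
analysed signal. Higher SampEn = less predictable = more fractionated.

Because the clinical recordings this analysis was designed around are
confidential, the package ships a calibrated synthetic cohort: 113
signals (64 NC, 49 C) of 1500 samples at 1 kHz, built from jittered
activation trains of biphasic deflections plus band-limited interstitial
activity, with a single per-class "fractionation" knob bisected until the
class-mean SampEn matches the reference baselines (0.196 for NC, 0.371
for C). Three artifact models are then swept Monte Carlo style:

* **spikes** — one-sample impulses, per-sample occurrence probability
  p_s, amplitudes uniform within ±3× the host's peak-to-peak amplitude;
* **distributed sample loss** — a fraction η of samples removed at
  scattered random positions;
* **consecutive sample loss** — one contiguous block of ηN samples
  removed.

Per level the pipeline reports class means, SD, μ ± 2σ intervals, a
two-sided Mann–Whitney U test between classes (α = 0.01), the Pearson
correlation ρ_xy between baseline and perturbed per-signal SampEn
(ρ_xy > 0.8 is the robustness rule), linear SampEn-vs-η fits, and ROC
curves.

## Worked example

```python
import egmentropy as eg

# calibrate the two class generators and build the cohort
nc = eg.calibrate_generator(eg.NC_BASELINE_TARGET, 0.01, eg.NC_PARAMS, "NC",
                            n_signals=50, seed=1234)
c = eg.calibrate_generator(eg.C_BASELINE_TARGET, 0.02, eg.C_PARAMS, "C",
                           n_signals=50, seed=1234)
spec = eg.CohortSpec(nc_params=nc.params, c_params=c.params, master_seed=1234)
cohort = eg.generate_cohort(spec)

# sweep distributed sample loss over the study grid
report = eg.run_sweep(cohort, "loss_distributed",
                      n_realisations=10, master_seed=1234)
print(report.linear_fit["NC"])
print(report.summary(0.5).p_value, report.summary(0.5).rho_xy)
```

Running the numbered scripts in `analysis/` executes the full study and
prints, for example (reduced scale, 10 realisations per signal):

```
NC: knob 0.2500 -> mean SampEn 0.1928 (converged)
C:  knob 0.3600 -> mean SampEn 0.3706 (converged)
Mann-Whitney U=0.0, two-sided p=1.07e-19 (significant at alpha=0.01)

loss_distributed:
  NC: linear fit f(eta%) = 0.001683*eta + 0.189, R^2 = 0.980
  C:  linear fit f(eta%) = 0.002572*eta + 0.363, R^2 = 0.990
  separation p <= 1.07e-19 at every level; rho_xy >= 0.994

spikes:
  p_s= 0.1: p=1.20e-18 rho_xy=+0.835 robust
  p_s=0.15: p=4.88e-12 rho_xy=+0.628 NOT robust
```

Read: the calibrated classes separate essentially perfectly at baseline;
scattered sample loss *raises* entropy linearly (the record whitens) but
classes stay separated with ρ_xy ≈ 0.99 even at 50% loss; consecutive
loss leaves SampEn within a few percent of baseline; spikes first
*lower* SampEn (they inflate the SD-relative tolerance, regularising the
record), then raise it as spike-train entropy dominates — the robustness
rule ρ_xy > 0.8 holds up to p_s = 0.10 and fails beyond.

There is also a CLI (`egmentropy synth | entropy | perturb | study |
report`) for running the same steps on signal files; see
`egmentropy --help`.

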