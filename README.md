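# gradcpt

Analysis pipeline for the gradual-onset continuous performance task
(gradCPT), a sustained-attention paradigm in which stimuli cross-fade
continuously — 90% frequent "Go" stimuli requiring a keypress, 10% rare
"No-go" stimuli requiring response inhibition — at a fixed stimulus onset
asynchrony (SOA; 1.6 s auditory, 0.8 s visual, 400-s runs). It is written
for researchers who need the full behavioral chain from raw keypress logs
to publication statistics, plus a synthetic observer so every stage is
testable without recorded data.

The pipeline implements:

- **Response assignment** — each press is attributed to a trial through
  the window `[t_n + 0.7·SOA, t_n + 1.4·SOA)` (70% of the fade-in to 40%
  of the fade-out); the earliest press per trial defines the RT; presses
  in the inter-window gap are given to whichever adjacent trial is still
  unanswered. Trials are classified hit / miss / false alarm (FA) /
  correct rejection (CR).
- **Performance metrics** — hit and FA rates, sensitivity
  d′ = Φ⁻¹(H) − Φ⁻¹(F) with 1/(2N) clipping of extreme rates, median RT.
- **Variance time course (VTC)** — per run, missing RTs are linearly
  interpolated, the series is z-scored, and |z| is taken as the
  trial-by-trial index of attentional fluctuation; a 7-s-FWHM Gaussian
  kernel smooths it, and the dominant fluctuation frequency is the peak of
  the cross-run-averaged amplitude spectrum (healthy adults show ~0.03 Hz).
- **fMRI regressors** — canonical double-gamma HRF, per-outcome stick
  regressors, the amplitude-modulated (raw-VTC-weighted) regressor sampled
  at TR = 2 s, and a 128-s discrete-cosine high-pass basis.
- **Bayesian statistics** — Pearson r with two-tailed p, the default
  Bayes factor for a correlation (exact r sampling density integrated
  against a stretched-beta prior, width 1 = uniform), central credible
  intervals, the JZS paired-t Bayes factor, and evidence-category labels.
- **Synthetic observer** — a latent sinusoidal attentional state
  modulates RT noise and error rates, generating keypress logs (and
  optional synthetic BOLD) with a known fluctuation frequency for
  end-to-end validation.

## Worked example

```python
from gradcpt import (
    ObserverParams, assign_presses, bf10_correlation, evidence_label,
    fluctuation_frequency, make_schedule, rho_credible_interval,
    session_metrics, simulate_observer, vtc_from_table,
)

# one 400-s visual run: 500 trials at SOA 0.8 s, 10% No-go
sched = make_schedule(400, 0.8, 0.1, seed=1)
params = ObserverParams(mod_depth=0.6, f0=0.032, seed=2)  # 0.032-Hz attention rhythm
table = assign_presses(sched, simulate_observer(sched, params))
m = session_metrics([table])
print(f"hit rate {100*m.hit_rate:.1f}%  FA rate {100*m.fa_rate:.1f}%  "
      f"d' {m.d_prime:.2f}  median RT {1000*m.median_rt:.0f} ms")

# four runs -> VTC spectra -> dominant fluctuation frequency
vtcs = []
for run in range(4):
    s = make_schedule(400, 0.8, 0.1, seed=1000 + run)
    p = ObserverParams(mod_depth=0.6, f0=0.032, seed=2000 + run)
    t = assign_presses(s, simulate_observer(s, p))
    vtcs.append(vtc_from_table(t, soa=0.8).smoothed_vtc)
print("estimated fluctuation frequency:", fluctuation_frequency(vtcs, soa=0.8), "Hz")

# group statistics from a reported correlation
bf = bf10_correlation(0.50, 25)
print("BF10 =", round(bf, 2), evidence_label(bf))
print("95% CI:", tuple(round(v, 3) for v in rho_credible_interval(0.50, 25)))
```

prints

```
hit rate 95.1%  FA rate 33.3%  d' 2.09  median RT 630 ms
estimated fluctuation frequency: 0.0325 Hz
BF10 = 5.31 moderate-H1
95% CI: (0.102, 0.715)
```

The observer's hit rate and median RT track its parameters (miss base
3.6%, mean RT 625 ms); the session FA rate exceeds the 18.8% commission
base because heavily modulated RT noise pushes some Go presses into
adjacent No-go windows — exactly the erratic-responding regime the VTC is
meant to capture. The frequency estimate 0.0325 Hz is the spectral bin
(resolution 0.0025 Hz at 400 s) nearest the generative 0.032 Hz, and
BF10 = 5.31 is moderate evidence for a true correlation of 0.50 at n = 25,
with a credible interval excluding zero.

The same stages are scriptable from the shell:

```sh
gradcpt simulate --out sim/ --participants 5
gradcpt analyze --in sim/ --out results/
gradcpt group --metrics results/metrics.csv --covariates glx.csv --pairs d_prime:glx
```

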