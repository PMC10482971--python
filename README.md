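# tdcss

Analysis toolkit for **time-dependent cell-state selection (TDCSS)**
experiments: live-cell imaging of single-cell cytokine secretion is
monitored in real time, each cell is flagged at the onset of its own
secretion, recovered within a short delay, and sequenced — so the
short-lived *transition state* of an activation process (for example
IL-33-stimulated group 2 innate lymphoid cells starting IL-13 secretion)
can be sampled at each cell's individual timing instead of at a fixed
snapshot time.

The package implements the computational core of that workflow:

* **Secretion-onset detection.** A per-well secretion signal
  (background-referenced mean well fluorescence) is monitored causally: an
  ordinary-least-squares line over the signal history is extrapolated, and
  the cell is flagged when the last three samples each exceed their
  predicted value by one standard deviation.  Offline, the onset is
  refined by least-squares fitting of the continuous two-segment model

  ```
  signal(t) = a·t                      0 < t < t̂
  signal(t) = b·(t − t̂) + a·t̂         t ≥ t̂
  ```

  with drift `a`, secretion slope `b` and onset time `t̂` (exact profile
  search over the sample grid plus bounded 1-D refinement).  The interval
  between onset and cell recovery, Δt, is binned to the nominal recovery
  delays (0.5 / 1.0 / 1.5 h).

* **Transition-mode gene classification.** From a gene × cell count
  matrix with per-cell state labels (pre-stimulation, transition,
  activated, silent), genes varying across states are selected by one-way
  ANOVA on normalised log2 expression, summarised as per-state z-scored
  profiles, clustered by K-means (k = 14 four-state / 8 three-state) and
  merged into named transition classes by correlation with pattern
  templates: EIG/ERG (early induced/reduced), LIG/LRG (late), SIG (silent
  induced), and **TIG — transiently induced genes**, up only in the
  transition state and invisible to snapshot sampling.  Snapshot-style
  Mann-Whitney/Benjamini-Hochberg DEG selection and a direct
  transient-induction rule are included for comparison.

* **Onset-timing survival analysis.** The time course of the secreting
  proportion is estimated with the Nelson-Aalen cumulative hazard
  Ĥ(t) = Σ dᵢ/nᵢ (variance Σ dᵢ/nᵢ², 95% CI on the log-hazard scale,
  proportion 1 − exp(−Ĥ)), and two groups (e.g. with/without an
  inhibitor) are compared with the log-rank test.

* **qPCR utilities.** Comparative-Ct (2^−ΔΔCt) relative expression and
  the variance-ratio F-test used to compare expression dispersion between
  recovery strategies.

* **Synthetic data with ground truth.** Seeded generators for secretion
  traces (drift + onset + Gaussian noise, broad lognormal onset
  latencies), two-channel traces with configurable inter-cytokine lags,
  negative-binomial count matrices with planted transition-mode classes
  and spike-in rows, and onset/censoring cohorts — so every stage is
  testable end to end without external data.

## Worked example

```python
from tdcss import (TraceSimConfig, simulate_secretion_traces,
                   detect_onset_online, fit_piecewise_onset,
                   compute_delta_t, bin_delta_t)

cfg = TraceSimConfig(n_cells=4, frac_secreting=1.0, seed=8)
traces, truth = simulate_secretion_traces(cfg)
for tr, onset in zip(traces, truth["onset_h"]):
    flag = detect_onset_online(tr)                  # causal monitoring flag
    fit = fit_piecewise_onset(tr, t_init=flag)      # two-segment refinement
    dt = compute_delta_t(fit, fit.onset_t_hat + 0.5)
    print(tr.cell_id, onset, flag, fit.onset_t_hat, bin_delta_t(dt))
```

Output (4-min scanning, drift 0.1, slope 2.0, noise 0.04):

```
cell      true onset  flagged fitted t^  drift a  slope b dt bin
cell0000       1.048    1.733     1.062    0.122    2.001    0.5
cell0001       1.281    1.733     1.286    0.105    2.001    0.5
cell0002       1.266    1.733     1.269    0.097    2.001    0.5
cell0003       2.097    2.133     2.100    0.104    2.002    0.5
```

The online flag arrives a few scans after the true onset (it can only fire
once the baseline is long enough), while the offline two-segment fit
recovers the onset to a fraction of a scan interval and the generative
drift/slope almost exactly; recovering each cell 0.5 h after its fitted
onset lands every cell in the Δt = 0.5 h bin.

The same stages are available from the shell:

```sh
tdcss simulate traces --n-cells 100 --seed 1 --out traces.csv
tdcss detect --traces traces.csv --out calls.tsv
tdcss simulate counts --seed 11 --out-dir counts/
tdcss classify --counts counts/matrix.mtx --mode mouse6 --seed 11 --out classes.tsv
tdcss survival --cohort cohort.tsv --out-dir survival/
```

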