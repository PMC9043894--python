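# soildecay

Degradation kinetics of protein residues in soil: model fitting, half-life
estimation, repeated-measures ANOVA, and factor-influence ranking for
factorial incubation experiments.

The package analyses long-format time courses of residue concentration
(ng per g dry soil) measured under combinations of soil site, temperature,
water content, and sterilization:

* **Models** (`soildecay.models`) — the first-order decay model
  `Y = a·e^(−bt)` and the plateau model `Y = y0 + a·e^(−bt)` (decay to a
  non-degradable residual), with the half-life functional `DT50 = ln2/b`.
* **Fitting** (`soildecay.fitting`) — bounded nonlinear least squares per
  condition with data-driven initial guesses and deterministic restarts;
  reports R², the regression F-test p-value, DT50, and a nested-model
  comparison (the plateau fit's R² can never fall below the first-order
  fit's, up to optimizer tolerance).
* **Repeated-measures ANOVA** (`soildecay.anova`) — split-plot
  decomposition with within-subject factor *time* (18 levels by default)
  and crossed between-subject factors, Greenhouse–Geisser-corrected
  p-values from the pooled within-cell covariance, and orthonormal
  polynomial time contrasts (rank- or metric-spaced).
* **Factor influence** (`soildecay.factors`) — per-factor-level means of
  an early-stage metric (DT50 from first-order fits) and a late-stage
  metric (y0 from plateau fits), their ranges, and the resulting factor
  ranking.
* **Synthetic data** (`soildecay.simulate`) — a deterministic generator
  for the reference 36-condition design (4 sites × 3 temperatures × 3
  water contents, 18 sampling times from 0 h to 96 d, triplicate →
  1944 records) plus a sterilized/nonsterilized pair, with truncated
  Gaussian noise (proportional SD with a floor) and per-condition child
  seeds.
* **Pipeline & CLI** (`soildecay.pipeline`, `soildecay.cli`) — CSV/YAML
  I/O with provenance headers and an end-to-end runner.

Bundled reference parameter values (fitted models, printed half-lives,
and per-level summary means) live in `soildecay.reference` and serve as
simulation defaults and regression baselines.

## Command line

```sh
soildecay simulate --seed 1 --out measurements.csv          # draw a dataset
soildecay fit measurements.csv --out fits.csv               # fit both models
soildecay compare measurements.csv --out comparison.csv     # R² comparison
soildecay anova measurements.csv --out-prefix anova         # split-plot RM-ANOVA
soildecay rank fits.csv --out ranking.csv                   # factor ranking
soildecay report measurements.csv --out report.md           # markdown report
soildecay run --outdir results --seed 1                     # everything
```

`run` accepts `--config config.yaml` (see the sidecar YAML written next to
every simulated dataset), `--use-means` to fit per-time-point means
instead of raw replicates, `--max-poly-order`, and `--plots` (requires
matplotlib). Identical seeds give byte-identical CSV outputs; every output
file carries its config hash and seed in `#` comment headers.

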