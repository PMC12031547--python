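# underice

Spatiotemporal modelling of heavy-metal concentration in lake water
beneath seasonal ice.

In lakes of cold, arid regions the winter ice cover rejects dissolved
solutes into the water below while sediments keep releasing metals at the
bottom. The resulting vertical profiles are **C-shaped** — enriched just
below the ice and near the sediment, dilute in the middle — and they
drift as the ice thickens. `underice` is a pipeline for limnologists and
environmental-toxicology modellers who monitor such lakes: it turns
sparse depth-profile campaigns (a handful of sampling dates, tens of
depths, several metals) into a continuous concentration surface
HM(*h*, *t*) over depth and freeze duration.

## The model

Each metal's profile at one sampling date is a sum of two exponentials in
depth *h* (cm below the ice–water interface),

```
HM(h) = a·e^{b·h} + c·e^{d·h},        b ≤ d  (canonical ordering)
```

and each characteristic parameter evolves linearly with freeze duration
*t* (days): `Y(t) = α·t + β` for `Y ∈ {a, b, c, d}`. Identification is
two-stage least squares — bounded multi-start nonlinear fits per date,
then an OLS line per parameter — and the fitted surface is validated
against two generic smoothing baselines (dyadic wavelet denoising and a
centred moving average) with a per-metal mean-relative-error report.
The package also computes the standard stratification statistics
(upper/middle/lower layer means over 15 cm bands, C-shape
classification, rapid/stable/melting ice-stage means and stage-change
arithmetic) and ships a synthetic-data generator with known ground truth
that emulates the study design (9 metals × 8 dates × 30 depths), so every
stage is testable without field data.

## Worked example

```python
import underice as ui

config = ui.default_config(seed=1, noise_cv=0.05)   # study-shaped synthetic data
dataset = ui.generate_dataset(config)               # 2160 records + ice trajectory
result = ui.run_pipeline(dataset)

fit = result.fits.query("metal == 'As' and time_d == 64").iloc[0]
print(f"As, t=64 d: a={fit.a:.3f}, b={fit.b:.5f}, c={fit.c:.3f}, d={fit.d:.5f}")
evo = result.evolutions["As"]
print(f"As evolution: a(t) = {evo.a.alpha:.4f} t + {evo.a.beta:.3f}")
summary = result.layer_table["As"]
print(f"As layer means: upper={summary.upper_mean:.2f}, "
      f"middle={summary.middle_mean:.2f}, lower={summary.lower_mean:.2f} "
      f"-> {result.shape_classes['As']}")
lo, hi = result.errors.ranges["c-type"]
print(f"C-type model error across metals: {lo:.2f}% - {hi:.2f}%")
```

prints

```
As, t=64 d: a=4.399, b=-0.01169, c=0.980, d=0.00817
As evolution: a(t) = 0.0102 t + 3.362
As layer means: upper=5.68, middle=4.37, lower=4.84 -> C-shaped
C-type model error across metals: 3.73% - 9.56%
```

The first line is the stage-1 fit for arsenic on the first sampling date
(freeze day 64): a decaying term of ~4.4 μg/L and a growing term of
~1.0 μg/L, i.e. ~5.4 μg/L at the interface with an interior minimum in
the middle layer. The second line is the stage-2 evolution of the
amplitude *a* — it grows by about 0.01 μg/L per freeze day. The layer
means show the C-shape (middle below upper and lower), and the last line
is the model-vs-measurement error range across the nine metals at 5%
measurement noise. (Smoothers evaluated at the points they smooth
partially reproduce the measurement noise itself, so on synthetic data
their in-sample errors can undercut even an exactly-specified model; see
`docs/methods.md` for why.)

The same pipeline runs from the shell on CSV files:

```
underice simulate --seed 1 --profiles obs.csv --ice ice.csv
underice run-all --profiles obs.csv --ice ice.csv --outdir results/
```

## Layout

| Module | Contents |
| --- | --- |
| `underice.ctype` | biexponential model, closed-form minimum, per-date fits |
| `underice.evolution` | per-parameter OLS evolution, surface reconstruction |
| `underice.smoothers` | wavelet and moving-average baselines |
| `underice.stratify` | layer/stage statistics and C-shape classification |
| `underice.evaluate` | mean-relative-error report per metal and method |
| `underice.synthetic` | study-shaped generator with known ground truth |
| `underice.io` / `underice.cli` / `underice.config` | CSV formats, pipeline, YAML config, CLI |
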