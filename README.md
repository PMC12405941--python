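# photorf

Analysis toolkit for single-photoreceptor intracellular recordings:
receptive-field (RF) mapping from grid-scan flashes, weighted elliptical
Gaussian RF decomposition with photoreceptor-coupling detection,
polarization-sensitivity (PS) and preferred e-vector angle estimation,
Hill intensity-response fitting with the inverse-Hill sensitivity
transformation, visual-pigment spectral-peak fitting, eye-region
classification and group statistics — plus a ground-truth simulator that
makes every stage verifiable by parameter recovery without any external
data.

## What it does

A grid-scan recording (one UV flash per position, 1° steps over a
20°×20° field, row-major) is turned into a spatial-sensitivity map in
three stages: per-epoch max-minus-min voltage extraction, Gaussian
smoothing (sigma 1°), and normalization + inverse-Hill transformation
using the cell's own fitted intensity-response curve. The final map is
decomposed into an offset plus up to three weighted elliptical Gaussians
(BIC-selected); the strongest component is the main (punctured) cell,
weaker disjoint lobes are candidate coupled neighbours. Coupling is
flagged when at least two lobes exceed a peak threshold and are separated
by a low-sensitivity valley, and per-component response-delay differences
are measured from the trace. Polarizer-series recordings yield PS
(max/min sensitivity ratio, with an artefact cap above which cells are
excluded) and phi_max (cos²-model fit). Cell records are aggregated into
two-way ANOVA (Type-II), Shapiro-Wilk residual checks, Tukey HSD with a
compact letter display, and an OLS model of RF size against PS with
species and eye-region terms.

The `synth` module simulates all three stimulus protocols (grid scan,
V-log(I), polarizer series) from cells with known RF components, Hill
nonlinearity, cos² polarization tuning, an A1 pigment template and
band-limited Gaussian noise, so the whole chain is tested end to end.

## Command line

```sh
photorf simulate --out sim/ --seed 1            # traces + ground truth
photorf fit-hill --trace sim/<id>_vlogi.csv --out hill.json
photorf ps --trace sim/<id>_pol.csv --hill hill.json
photorf fit-rf --trace sim/<id>_grid.csv --hill hill.json --out rf.json
photorf classify --cells cells.json
photorf stats --cells out/cells.csv
photorf run --out out/ --seed 1                 # full demo pipeline
```

`photorf run` simulates a 12-cell population, runs every estimator,
classifies the cells and writes `cells.csv`, per-cell JSON artifacts and
`report.json` with the group statistics. Runs are byte-identical for a
fixed seed.

## Interchange formats

* Traces: CSV `time_s,voltage_mV` plus a JSON sidecar
  (`sampling_rate`, `t0`, stimulus markers).
* Grid maps: CSV matrix (top row first) plus a JSON sidecar with stage
  and angular coordinates.
* Fits, ground truth, configs and reports: JSON (angles in deg,
  voltages in mV, delays in ms).

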