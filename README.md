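# mitovolt

Quantification of intramitochondrial membrane-potential heterogeneity from
two-channel fluorescence time-lapse imaging, plus a forward simulator that
renders ground-truthed phantoms so every analysis stage is verifiable
without microscope data.

A potentiometric cationic dye (TMRE/TMRM/Rho123 class) partitions across
membranes Nernstianly, so intensity ratios between sub-organelle
compartments convert to millivolt differences via `kappa * ln(FI_a/FI_b)`
with `kappa = RT/F` (~26.73 mV at 310.15 K). The pipeline:

1. **preprocess** — rolling-ball background subtraction, Otsu
   segmentation of the structural channel, whole-object morphometrics
   (circularity, aspect ratio), long-axis skeleton extraction.
2. **compartments** — axial intensity profiling, crista detection
   (prominence-based peaks with sub-pixel refinement), pixel
   classification into matrix / inner boundary membrane (IBM) / crista /
   vesicle, detached-vesicle detection, dye co-partitioning correlation.
3. **potentials** — Nernst conversion with bound-dye (potential
   independent) correction, per-compartment and per-crista potential
   tables against selectable references (cytosol, whole-mito mean,
   adjacent IBM), and group statistics (per-experiment averaging +
   two-tailed t-tests). Because sub-resolution membranes are mixed with
   their surroundings by the PSF, potentials are recovered through a
   geometric contrast-restoration step: indicator images of the detected
   geometry are blurred with the known PSF and the linear mixing system
   is solved for the underlying compartment concentrations.
4. **dynamics** — crista tracking, flicker detection and decomposition
   into potential-dependent/-independent components, within- vs
   between-crista variability, partial-depolarization calls, and
   depolarization-wave quantification (front position, speed, wavelike
   vs instantaneous classification).
5. **simulate** — capsule-shaped phantoms with 1-px membranes, Nernstian
   dye equilibrium, Gaussian PSF + Poisson/read noise, events (flicker,
   wave, partial depolarization), and named presets for the experimental
   conditions (control, oligomycin, FCCP, MICOS/Opa1 knockouts,
   hyperpolarized-vesicle models).

## CLI

```sh
# render a phantom (TIFF stack + JSON metadata + ground truth)
mitovolt simulate --preset control --seed 7 --out runs/control
mitovolt simulate --scenario my_scenario.json --seed 7 --out runs/custom

# analyze one stack (CSV tables + manifest + LUT render)
mitovolt analyze --input runs/control --out runs/control_analysis

# analyze a directory of stacks, then aggregate/compare
mitovolt batch --input runs --out results
mitovolt report --results results --out summary.json
```

`analyze` accepts `--config file.json|yaml` (see `mitovolt.config.RunConfig`
for every tunable and its default) and `--stop-after preprocess|compartments`.

## Layout

```
src/mitovolt/
  simulate/        scenario, geometry, dye equilibrium, renderer, presets
  preprocess.py    background, segmentation, morphometrics, axis
  compartments.py  cristae, label maps, vesicles, profiles
  potentials.py    Nernst conversion, contrast restoration, statistics
  dynamics.py      tracking, flicker, variability, waves
  io.py            TIFF/CSV/JSON/PNG IO, LUT rendering
  pipeline.py      stage orchestration
  cli.py           simulate / analyze / batch / report
```
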