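# aptw

Amide-proton-transfer-weighted (APTW) CEST MRI quantification and cohort
analysis for pH-sensitive imaging of ischemic stroke — with a multi-pool
Bloch–McConnell simulator so the entire processing chain is testable
without patient data.

## The problem

Chemical exchange saturation transfer (CEST) imaging saturates labile
protons with off-resonance RF and reads the effect out on the water
signal. For backbone amide protons of mobile proteins (+3.5 ppm downfield
of water), the exchange rate is base-catalyzed and therefore falls with
intracellular pH: ischemic, acidotic tissue gives a lower APTW signal than
healthy tissue, and signal recovery after treatment tracks clinical
improvement. The APTW signal is quantified as the z-spectrum asymmetry

```
MTRasym(3.5 ppm) = [S_sat(-3.5 ppm) - S_sat(+3.5 ppm)] / S0
                 = APTR + MTR'asym(3.5 ppm)
```

reported in percent of the bulk water signal, where APTR is the amide
proton transfer ratio proper and MTR'asym is the negative background from
nuclear Overhauser enhancement and semisolid magnetization transfer.

The package implements, for 2D single-slice series acquired with a
31-offset / 61-acquisition protocol (CW saturation, 800 ms at 2 μT):

* **image_io** — NIfTI series/mask/map I/O, offset tables, cohort CSVs
  (`aptw.io`);
* **synthetic phantoms** — Bloch–McConnell z-spectrum simulation with
  exact ground-truth decomposition, pH-dependent amide exchange, B0
  fields, Rician noise, motion, and simulated 43-patient cohorts
  (`aptw.phantom`, `aptw.cohort`);
* **registration** — rigid 3-DoF alignment of every frame to the +3.5 ppm
  reference (`aptw.registration`);
* **z-spectrum pipeline** — repeat averaging, S0 normalization, voxelwise
  B0 estimation/correction, APTW maps and ROI MTRasym spectra
  (`aptw.pipeline`);
* **ROI rules** — multiple small lesion ROIs with the lowest-value
  selection rule, mirrored contralateral (CNAWM) reference, APTW contrast,
  whole-lesion mean (`aptw.roi`);
* **cohort statistics** — clinical time bins, Pearson / pooled t /
  ANOVA+LSD, and the grouped treatment-response tables (`aptw.stats`).

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Simulate an acidotic lesion (pH 6.4) in healthy background (pH 7.0) under
a ±0.3 ppm B0 field, then recover the lesion value through the full
pipeline:

```python
from aptw import (
    PhantomSpec, B0FieldSpec, build_phantom, process_series, measure_lesion,
    ground_truth_decomposition, PoolParameterSet, SaturationSpec,
)

spec = PhantomSpec(b0=B0FieldSpec(amplitude_ppm=0.3), seed=7)
phantom = build_phantom(spec)

truth = ground_truth_decomposition(
    PoolParameterSet.brain_tissue(ph=spec.lesion_ph), SaturationSpec()
)
print(f"lesion ground truth: APTW {truth.aptw_pct:+.2f}% "
      f"(APTR {truth.aptr_pct:+.2f}%, MTR'asym {truth.mtr_prime_asym_pct:+.2f}%)")

result = process_series(phantom.series)   # register, average, normalize, B0-correct
meas = measure_lesion(result.aptw, phantom.roiset)
print(f"measured lesion APTW (lowest of {meas.n_rois} ROIs): {meas.lesion_aptw_pct:+.2f}%")
print(f"whole-lesion mean: {meas.lesion_aptw_mean_pct:+.2f}%   "
      f"CNAWM: {meas.cnawm_aptw_pct:+.2f}%   contrast: {meas.contrast_pct:+.2f}%")
```

prints

```
lesion ground truth: APTW -5.29% (APTR +0.27%, MTR'asym -5.55%)
measured lesion APTW (lowest of 3 ROIs): -5.27%
whole-lesion mean: -5.27%   CNAWM: -4.57%   contrast: -0.70%
```

The lesion's ground-truth asymmetry (−5.29%) is recovered to 0.02
percentage points despite the B0 field; the acidic lesion reads below the
contralateral reference (negative contrast), as in acute stroke. At these
defaults the amide term is small and the reading is dominated by the
NOE/MT background — raising lesion pH (or the amide exchange rate
directly) raises APTR and with it the recovered APTW.

A command-line interface wraps the same stages:

```sh
aptw simulate --seed 7 --out phantom/
aptw process --series phantom/series.nii --s0 phantom/s0.nii \
     --offsets phantom/offsets.csv --out maps/
aptw roi --aptw-map maps/ --auto-roi phantom/rois/whole_lesion.nii --out lesion.csv
aptw simulate-cohort --seed 1 --out cohort.csv
aptw cohort --cohort cohort.csv --out tables/
```

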