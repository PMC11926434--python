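# vheetps

Spot-scanning treatment planning for very high-energy electron (VHEE) beams
on synthetic voxel phantoms: analytic beam base data, beam's-eye-view spot
placement, pencil-beam influence-matrix dose calculation, non-negative
fluence-map optimisation, DVH plan-quality metrics, and automated parameter
sweeps over beam number, energy and spot spacing.

## What it does

- **`vheetps.base_data`** — per-energy tables of integrated depth dose and
  multiple-scattering lateral spread in water. Generated analytically
  (build-up x quasi-exponential depth dose; Highland scattering power
  integrated through the Fermi-Eyges second moment) or imported from CSV.
- **`vheetps.phantom`** — deterministic synthetic phantoms with structure
  sets: water box, pelvis (PTV + abutting rectum/bladder) and two thorax
  variants (low-density lungs, heart/oesophagus/spinal-cord, midline or
  chest-wall PTV). Saved/loaded as NRRD volumes.
- **`vheetps.geometry`** — equidistant gantry arrangements (partial arcs and
  full 360 deg), BEV projection of targets, square spot lattices with a
  configurable margin, and exact Siddon-style water-equivalent path length
  maps (numba-accelerated).
- **`vheetps.dose_engine`** — dose per spot as depth-dose lookup at
  radiological depth times a unit-integral lateral Gaussian with
  sigma_tot(z) = sqrt(sigma0^2 + sigma_scatter(z)^2); sparse
  voxels x spots influence matrix (HDF5 round-trip supported).
- **`vheetps.optimizer`** — quadratic-penalty objectives (uniform target,
  max dose, mean dose, DVH-max) minimised over non-negative spot weights
  with L-BFGS-B, then normalised so the mean target dose equals the
  prescription (60 Gy prostate / 55 Gy lung protocols, 20 fractions).
- **`vheetps.evaluate`** — cumulative DVH, Dx%, D at absolute volume
  (e.g. D_1cm3), V_xGy, mean dose and homogeneity index
  HI = (D2% - D98%) / D50%.
- **`vheetps.study_pipeline`** — `run_plan` chains the full workflow;
  `run_sweep` runs factor products into a tidy long-format table;
  `compare_to_reference` joins absolute/relative differences against any
  reference metric table (a 12-beam full-arc pseudo-reference is provided).

## CLI

```sh
vheetps basedata --energy 200 --sigma0 4 --out basedata/e200.csv
vheetps phantom --recipe pelvis --out phantoms/pelvis
vheetps plan --phantom-dir phantoms/pelvis --n-beams 5 --energy 200 \
             --protocol prostate --prescription 60 --out runs/plan01
vheetps sweep --config study.yaml --out runs/sweep01
vheetps dvh --phantom-dir phantoms/pelvis --dose-npy dose.npy --out runs/dvh
vheetps compare --results runs/sweep01/results.csv \
                --reference ref.csv --out runs/diff.csv
```

A sweep config is YAML; see `StudyConfig.from_yaml` for the schema
(phantoms, beam counts, arc span/centre, energies in MeV, sigma0,
spacing multipliers, protocol, prescription).

## Conventions

- Axes: x right->left, y anterior->posterior, z inferior->superior; gantry
  0 deg enters anteriorly travelling +y, angles increase toward
  patient-left entry; parallel-beam (infinite SAD) geometry.
- Dose grid 2 mm default; spot spacing is quoted in multiples of the
  initial spot sigma; spot lattices cover the target BEV projection plus a
  5 mm margin.
- Dx% uses the rank convention ceil(x/100 * n) on descending-sorted voxel
  doses (no interpolation).
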