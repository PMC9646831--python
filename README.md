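# sacflow

Pulsatile, non-Newtonian hemodynamics of an idealized coiled sidewall
aneurysm, in 2-D, at desk scale.

The package builds a parametric curved parent vessel carrying a sidewall
sac, meshes it, solves transient incompressible flow with Casson blood
rheology (haematocrit-dependent) and a Darcy–Forchheimer momentum sink
representing endovascular coil packing, and post-processes wall shear
stress (WSS), time-averaged WSS, the oscillatory shear index (OSI), wall
pressure, sac inflow velocity and iso-velocity areas at the four cardiac
landmarks — maximum acceleration (A), peak systole (B), maximum
deceleration (C) and early diastole (D). A study driver sweeps coil
porosity × haematocrit and tabulates percent changes against a reference
condition.

## Layout

| module | role |
| --- | --- |
| `sacflow.geometry_mesh` | parametric vessel + sac geometry; structured-quad / Delaunay meshing; coil-region mask |
| `sacflow.rheology` | regularized Casson viscosity with haematocrit closures (Newtonian fallback) |
| `sacflow.waveform` | analytic pulsatile inlet signal; automatic A–D landmark detection |
| `sacflow.coil_model` | porosity → permeability (Kozeny–Carman) and inertial loss (Ergun); momentum sink |
| `sacflow.solver` | P1-FEM incremental pressure-projection Navier–Stokes solver with friction-weighted projection in coil cells |
| `sacflow.postprocess` | wall probe, WSS/TAWSS/OSI, windowed per-instant OSI, risk regions, cross-condition comparison |
| `sacflow.pipeline` / `sacflow.cli` | config-driven runs, porosity×HCT study, grid-independence ladder, manifests |
| `sacflow.benchmarks` | closed-form oracles (Poiseuille, oscillatory channel, Darcy) used only by tests |

Notes on modelling choices (all configurable):

- The geometry is a synthetic stand-in: a 2-D channel (width 4 mm,
  centerline radius 20 mm by default) with a circular-segment sac
  (dome radius 3 mm, neck 4 mm) on the outer wall. No patient data are
  used or required.
- Lower coil porosity gives lower Kozeny–Carman permeability and hence a
  stronger momentum sink and less sac inflow (this follows the physics;
  one sentence in the source study's prose inverts the wording).
- OSI saturates at 0.5 wherever tractions are near zero; sac OSI
  statistics therefore exclude samples whose cycle TAWSS is below a
  configurable noise floor (default 1 % of the sac maximum).

## CLI

```sh
sacflow run   --config cfg.yaml --out results/    # one condition
sacflow study --config cfg.yaml --out results/    # porosity x HCT sweep
sacflow grid  --config cfg.yaml --out results/    # grid-independence ladder
sacflow report --out results/                     # rebuild tables from artifacts
```

The YAML config overrides the defaults in `sacflow.config.DEFAULT_CONFIG`;
every resolved value (including untouched defaults) is echoed into each
run's `report.json`, so no silent defaults exist. Flags `--resolution`,
`--cycles` and `--quiet` override the corresponding config entries.

Each run writes VTK (legacy ASCII) snapshots at the four landmarks, the
wall traction/pressure time series and the per-sample indices as CSV, a
JSON report, and a `manifest.json` with SHA-256 checksums of every
artifact. Identical configs produce bit-identical manifests.

Example config:

```yaml
mesh: {resolution: 3.5e-4}
coil: {porosities: [0.79, 0.89]}
hct: [0.35, 0.45]
solver: {dt: 1.0e-3, cycles_to_run: 3, cycles_to_discard: 2}
```

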