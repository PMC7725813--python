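# spinefe

Desk-scale nonlinear finite elements for spine biomechanics: hydrostatic
fluid-cavity elements with a single shared pressure unknown per cavity,
conformal node-merged multi-body meshing, a parametric synthetic torso
anatomy, and a reproducible validation harness (intramuscular pressure,
lumbar bending moment, two-phase intervertebral disc pressure, full-spine
flexion, mesh/model-form sensitivity).

Everything is text-based and deterministic: geometry is generated
programmatically (no external data), and identical configurations produce
byte-identical reports.

## Layout

| module | contents |
| --- | --- |
| `spinefe.mesh` | structured tet/membrane primitives, coincident-node merging, enclosed volume, tet4→tet10 conversion |
| `spinefe.materials` | isotropic elasticity and quasi-incompressible neo-Hookean laws |
| `spinefe.cavity` | closed-surface volume kernel (exact gradient/Hessian), cavity specs, follower pressure loads |
| `spinefe.engine` | total-Lagrangian Newton solver (tet4/tet10 solids, tri3 membranes, bar2 trusses, cavity multipliers), result extractors |
| `spinefe.anatomy` | lumbar and full-spine synthetic assemblies, tissue tables, muscle force cases |
| `spinefe.experiments` | the validation tests and sensitivity studies; `spinefe.cli` exposes them |
| `spinefe.io` | legacy-VTK (ASCII) export/import |

Key numerical choices: near-incompressible solids (ν = 0.499) use a
deviatoric neo-Hookean law with a condensed constant-pressure volumetric
term (an optional nodal-averaged-Jacobian variant is built in); membranes
are plane-stress convective-coordinate elements without bending stiffness;
cavities couple through the exact enclosed-volume gradient and Hessian, with
incompressible cavities enforced by one Lagrange multiplier each (the shared
hydrostatic pressure unknown). Cavity multiplier columns are eliminated by a
small Schur complement so the sparse factorization stays fast.

## CLI

```bash
spinefe build --assembly lumbar --outdir results      # export a model as .vtk
spinefe run imp                                       # one validation test
spinefe run all --outdir results --plots              # everything + plots
spinefe report --outdir results                       # print the JSON summary
```

Configuration is a flat YAML file passed with `--config`; every field of
`spinefe.experiments.ExperimentConfig` can be overridden (mesh edge length,
element order, sweep ranges, thresholds). Literature envelopes are printed
as advisory context; only geometry-independent statistics are pass/fail.

## Units and conventions

Millimetres, newtons, MPa; X = right-lateral, Y = superior, Z = anterior.
Pressures are reported both in MPa and mmHg (1 mmHg = 1.33322e−4 MPa).
Surface sets store outward-oriented facets; enclosed-volume computation
rejects inward orientation instead of silently flipping.
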