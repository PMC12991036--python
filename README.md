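# femursweep

Automated sensitivity analysis of femoral lesion location. The package
generates parametric synthetic femurs, calibrates QCT-style Hounsfield-unit
images against density phantoms, solves a single-legged-stance load case with
linear tetrahedral finite elements, and sweeps a 10 mm spherical osteolytic
lesion in 1 mm steps from the medial to the lateral side of three diaphyseal
stations, reporting per-location elasticity-loss, stiffness-loss, transverse
cortical involvement (TCI), cortical volume loss and probed principal
strains.

## Quick start

```python
from femursweep import FemurParams, RunConfig, run_sweep

config = RunConfig(femur=FemurParams(seed=1))
result = run_sweep(config)

print(result.summary)           # per-femur maxima with station/side
result.records.to_csv("sweep.csv")
```

`run_sweep` generates the femur, derives the anatomical frame (sphere-fitted
hip joint centre at the origin, shaft axis superior, medial +x), selects the
proximal/mid/distal stations by seeded k-means, balances the knee joint
centre so the medial condyle carries 55 ± 0.1% of the stance reaction with
the hip displacing in the coronal plane, and then solves one constrained FE
system per lesion position, reusing cached unit-modulus element matrices so
each lesion case costs a low-rank stiffness update plus one factorisation.

## What is in the box

| Module | Contents |
| --- | --- |
| `femursweep.synthetic` | Parametric implicit-solid femur generator, synthetic HU voxel images with calibration phantom rods (NIfTI I/O) |
| `femursweep.calibration` | Phantom regression ρ=a+b·HU, ash/apparent-density conversions, E=6850·ρ^1.49 MPa, ≤100-set HU partitioning, two-phase (16.7 GPa / 155 MPa) assignment |
| `femursweep.anatomy` | Least-squares sphere fits, anatomical frame + rigid registration, k-means region/station selection |
| `femursweep.fe_core` | Linear tetrahedral elasticity, rigid 6-DOF reference-point ties via master–slave elimination, sparse LU with cheap re-solves, reactions, principal strains, spherical strain probes |
| `femursweep.lesion_sweep` | Spherical 50 kPa lesions, medial–lateral sweep paths, TCI and cortical-volume-loss oracles |
| `femursweep.pipeline` | Knee-centre balancing, elasticity-loss (Eq. 1) and stiffness-loss (Eq. 2), full sweep orchestration, per-femur normalisation, strain profiles |
| `femursweep.mesh` / `femursweep.vtkio` | Tet-mesh container, structured tube/box test meshes, legacy-VTK ASCII I/O |

See `docs/methods.md` for the governing equations and modelling decisions,
and `examples/` for narrative walkthroughs (calibration, generation, stance
balancing, the full sweep, strain profiles).

## Tests and acceptance

```bash
python -m pytest                     # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports the medial condyle reaction share (percent)
after knee balancing on the default synthetic femur. Two acceptance tests
encode literature-derived expectations (mid-shaft stiffness-loss maximum;
non-positive stiffness-loss everywhere) that the default synthetic geometry
does not reproduce under the magnitude-based stiffness definition; they are
kept failing deliberately rather than tuning the generator — see
`docs/methods.md` ("Known deviations") for the mechanical analysis.

## Units

Millimetres, newtons, megapascals (N/mm²); densities in g/cm³; HU for image
intensities. Stiffness-loss is reported in N/mm (numerically equal to kN/m).
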