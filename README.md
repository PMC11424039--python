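# micoconn

Microstructure-informed structural connectomics: from multi-shell
diffusion MRI signals and tractography streamlines to weighted brain
networks and their developmental statistics.

Conventional structural connectomes weight each connection by the number
of reconstructed streamlines — a quantity with weak biological meaning
that is badly biased wherever several fiber bundles cross inside the
same imaging voxel. The alternative implemented here assigns every
streamline its own **intra-axonal signal fraction (IASF)** by
deconvolving the voxel-level diffusion signal over the streamlines that
traverse it (the COMMIT approach): with a stick-zeppelin-ball
compartment model and fixed diffusivities
(d<sub>par</sub> = d<sub>par,zep</sub> = 1.7×10⁻³,
d<sub>perp</sub> = 0.61×10⁻³, d<sub>iso</sub> ∈ [1.7, 3.0]×10⁻³ mm²/s),
the signal in each voxel is a non-negative linear combination of
per-streamline stick kernels plus extra-axonal zeppelin and isotropic
ball compartments, and solving

&nbsp;&nbsp;&nbsp;&nbsp; min<sub>x ≥ 0</sub> ‖A x − y‖²

yields one weight x<sub>k</sub> per streamline, assumed constant along
it. Streamlines that explain no signal get x ≈ 0 and are filtered out as
implausible. Bundles (streamlines joining the same ROI pair i, j) are
aggregated into edge weights by

&nbsp;&nbsp;&nbsp;&nbsp; a<sub>ij</sub> = Σ<sub>k</sub> x<sub>ijk</sub> l<sub>k</sub> / (Σ<sub>k</sub> l<sub>k</sub> / N<sub>ij</sub>)

— the length-weighted total IASF of the bundle divided by its mean
streamline length. On these weighted graphs the package computes
modularity (Newman spectral, resolution γ = 1), global efficiency,
local efficiency, Onnela clustering and mean strength, per canonical
cortical network (visual, somatomotor, dorsal/ventral attention, limbic,
fronto-parietal, default mode, subcortical), and runs the developmental
analysis: linear mixed-effects models of each measure on age, sex and
network with ICV as covariate and AIC model selection over interaction
structures; per-network OLS at α = 0.005 with adjusted R²; a
connection-density-adjusted replication; and elastic-net age prediction
from node-level local efficiencies with an 80:20 split, fivefold CV
over the L1-ratio grid (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1) and
node-importance ranking.

Because real cohort MRI of this kind is not public, every stage is
exercisable end-to-end on synthetic data: crossing-fiber diffusion
phantoms with known ground-truth weights, and cohorts of subjects
(default n = 88, ages 8–19, 46 female) whose connectome edges carry
programmed age, sex and network effects.

## Worked example

```python
import numpy as np
from micoconn import (VoxelGrid, make_crossing_phantom, simulate_signal,
                      make_scheme, StreamlineDeconvolution, build_connectome)

grid = VoxelGrid((8, 8, 8))                      # 2 mm isotropic voxels
scheme = make_scheme([(500, 30), (1200, 30), (2400, 60), (4000, 60), (6000, 60)],
                     n_b0=14, seed=1)            # 254-volume protocol
tractogram, truth, parc = make_crossing_phantom(grid, n_bundles=2,
                                                streamlines_per_bundle=8, seed=11)
signal = simulate_signal(tractogram, truth, grid, scheme)

result = StreamlineDeconvolution(signal, tractogram, grid, scheme).fit()
print(result.summary())
err = np.abs(result.x - truth.x_true) / truth.x_true
print(f"max relative recovery error: {err.max():.2e}")

conn = build_connectome(tractogram, result.weights, parc, weighting="IASF")
print("IASF edge (bundle 0):", round(conn.matrix[0, 1], 4))
```

prints

```
Streamline deconvolution (stick-zeppelin-ball NNLS)
  streamlines: 16 (kept 16, filtered 0)
  compartment columns: 124 zeppelin, 212 ball
  active voxels: 106, rows: 26924
  residual ||Ax - y||: 3.27103e-13
  IASF range (kept): [0.2143, 0.6742]
max relative recovery error: 2.55e-12
IASF edge (bundle 0): 2.8665
```

The two crossing bundles are perfectly unmixed: every streamline's
recovered signal fraction matches its ground-truth value to near
machine precision, and the bundle's connectome entry is its total IASF
(≈ mean weight × 8 streamlines). With Rician noise added
(`add_noise(signal, sigma=0.02, "rician")`) the weights remain accurate
to ≈ 10 % median error.

The same stages run from the shell:

```bash
micoconn run --config cfg.yaml          # full synthetic pipeline + manifest
micoconn simulate-phantom / fit-commit / build-connectome
micoconn simulate-cohort / metrics / stats / feature-importance
```

## Layout

| module | contents |
| --- | --- |
| `micoconn.scheme` | multi-shell gradient tables |
| `micoconn.kernels` | stick / zeppelin / ball compartment signals |
| `micoconn.phantom` | crossing-fiber phantoms, analytic signal synthesis, noise |
| `micoconn.deconvolution` | forward operator, NNLS, streamline filtering |
| `micoconn.parcellation` | label volumes, atlas-merge consensus rule |
| `micoconn.connectome` | bundle grouping, IASF/NOS edge weights, subnetworks |
| `micoconn.metrics` | the five weighted graph measures, metric tables |
| `micoconn.cohort` | synthetic developmental cohorts with programmed effects |
| `micoconn.stats` | mixed models, per-network GLMs, elastic-net importance |
| `micoconn.pipeline` | config-driven end-to-end run with manifest |
| `micoconn.experiments` | the Monte-Carlo validation harnesses |

See `docs/methods.md` for the modelling choices and their rationale.
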