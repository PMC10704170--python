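# springgeo

Latent-geometry analysis of gene/protein interaction networks.

The package models an interaction network as a spring system (node masses =
total degree, edges = springs), derives an all-pairs spring-stiffness matrix
from the nullspace of the mass-weighted oriented incidence matrix, converts it
to a dissimilarity matrix, embeds that matrix into three isotropic model
spaces — Euclidean (classical MDS), hyperbolic (Poincaré ball, strain-based
initialization plus quasi-Newton stress refinement), and spherical (curvature
radius optimized via the smallest eigenvalue of `r² cos(D/r)`) — and selects
the geometry with minimum embedding stress.  When the best geometry is
hyperbolic, the nodes' radial coordinates are clustered with 1-D k-means
(elbow method for k, stability analysis over repeated runs), and the cluster
whose internal stiffness distribution best matches the global one (minimum
two-sample Kolmogorov–Smirnov statistic) is flagged as the candidate driver
cluster.  A spectral-clustering baseline with the eigengap heuristic is
included for comparison.

## Modules

| module | contents |
| --- | --- |
| `springgeo.network_io` | SIF parsing, graph simplification, degrees/masses, oriented incidence |
| `springgeo.spring_model` | vibrational centrality, mass-weighted incidence, equilibrium/non-equilibrium stiffness, rescaling, dissimilarity |
| `springgeo.embedding` | model-space distances, the three embeddings, stress, geometry selection |
| `springgeo.clustering` | radial k-means, elbow, stability, driver report, spectral baseline |
| `springgeo.synthetic` | planted-geometry samplers, threshold graphs, hand-checkable fixtures |
| `springgeo.pipeline` / `springgeo.cli` | configuration-driven orchestration and the `springgeo` command |

## Command line

```sh
# generate a planted hyperbolic network and analyse it end to end
springgeo simulate --model hyperbolic --n 150 --dim 2 --scale 3 \
    --threshold 2 --seed 1 --outdir demo
springgeo stiffness demo/network.sif --outdir demo
springgeo select-geometry demo/dissimilarity.csv --dims 3,4,5 --outdir demo
springgeo embed demo/dissimilarity.csv --model hyperbolic --dim 3 \
    --out demo/coordinates.csv
springgeo cluster demo/coordinates.csv --outdir demo
springgeo drivers demo/stiffness.csv demo/clusters.csv

# or everything at once from a YAML config
springgeo run --config config.yaml --seed 1 --outdir demo
```

A config file mirrors `springgeo.pipeline.PipelineConfig`; exactly one of
`sif_path`, `dissimilarity_path`, or `synthetic` must be given:

```yaml
sif_path: network.sif
dims: [3, 4, 5, 6, 7, 8, 9, 10]
stability_runs: 1000
seed: 1
outdir: results
```

Every run writes CSV/JSON outputs plus `manifest.json` (config hash, seed,
per-stage wall times, SHA-256 of each output); the same config and seed
reproduce all outputs byte-for-byte.

## Notes

- Input SIF files are tab-separated with at least three columns
  (participant A, interaction type, participant B); extended SIF columns are
  ignored, parallel edges collapsed, self-loops dropped.
- Dense all-pairs matrices are capped at 5,000 nodes.
- All randomness flows from explicit seeds; repeated runs are deterministic.
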