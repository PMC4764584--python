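# tissuescope3d

Reconstruction and quantitative analysis of dense-tissue architecture from
multi-channel 3D confocal microscopy, with liver as the reference tissue.
The package turns stacks of stained sections — nuclei (DAPI), bile-canalicular
apical membranes (CD13), sinusoidal endothelium (Flk1), actin cortex
(phalloidin) — into a geometrical model: de-noised images, stitched and
unbent sections, triangle meshes of tubular networks, nuclei and cells,
skeleton graphs, and per-cell morphometric tables, plus a fully synthetic
benchmark for measuring reconstruction accuracy against voxel ground truth.

It is written for microscopists and image-analysis developers who need the
intermediate quantities — noise models, threshold fields, meshes, centreline
graphs — as first-class Python objects rather than an opaque end-to-end
black box.

## What is inside

| Stage | Module | Method |
| --- | --- | --- |
| De-noising | `volumetric_core` | Poisson noise calibration `V(I) = α(z)(I − β)`; Bayesian foreground/background discrimination along z (outlier-tolerant line fit; threshold 1.25 σ) |
| Mosaics | `mosaic_registration` | Tile shifts maximizing the summed neighbour NCC `G`; multi-band blending; pyramid + polar rigid registration |
| Section geometry | `section_surface` | Kapur max-entropy surfaces; Bayesian refinement (Cauchy data terms, Gaussian thickness coupling, Laplace smoothness) by ICM; quadratic B-spline unbending; local max-entropy (LME) threshold fields; vessel segmentation and gap bridging |
| Structures | `mesh_segmentation` | LME masks → marching-cubes meshes → gradient tuning; balloon active meshes; skeleton graphs with radii |
| Nuclei | `nuclei_tools` | Minimum-volume ellipsoid model selection (single vs double), ln MSE mixture multiplicity, LoG scale-space (LoGMP) seeding, active-mesh splitting, DAPI integrals |
| Classification | `cell_classifier` | 74 nuclear parameters; Fisher-ranked LDA cascade; K2-learned Bayesian network |
| Benchmark | `benchmark_sim` | Synthetic 4-channel liver scenes: uneven log-normal staining, confocal PSF, depth-dependent Poisson noise; voxel-level scoring |
| Morphometry | `morphometrics` | Network statistics, cylinder consistency `V_c = π r_s² L_s`, lobule coordinate χ, zonation profiles, ploidy clustering, log-normal mixtures |

The model core in brief: noise obeys `I = αN + β` with depth-dependent α;
surfaces minimize
`E = Σ ln(1 + ((y−y_m)/s)²) + Σ (y₂−y₁−t₀)²/2σ² + λ Σ |Δy|`;
nuclei multiplicity is decided by the mesh–ellipsoid misfit
`MSE = Σ((p−c)ᵀE(p−c) − 1)²/(n − 9)`; blob seeds come from
`LoGMP(x) = max_σ σ²·(−∇²G_σ * I)(x)` with `r = √2 σ`; zonation uses
`χ = 50((|D−d_pv| − |D−d_cv|)/D + 1)`. Details, defaults and the reasoning
behind every open choice are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a degraded benchmark scene, reconstruct the bile-canalicular
network, and compare against the known ground truth:

```python
import numpy as np
from tissuescope3d import (generate_scene, DegradationConfig,
                           degrade_channel, reconstruct_tubular,
                           evaluate_reconstruction)

scene = generate_scene(96, spacing=0.3, seed=1)        # ground truth block
cfg = DegradationConfig(snr=4.0)                       # 4:1 SNR degradation
img = degrade_channel(scene.channels["bc"], "bc", cfg, seed=11, spacing=0.3)

mask, meshes, radius, denoised = reconstruct_tubular(img, tune_search_um=0.5)
score = evaluate_reconstruction({"bc": mask}, scene)
d = score.per_structure["bc"]
print(f"BC voxel F-score : {d['f']:.3f}  (PR {d['pr']:.3f}, SN {d['sn']:.3f})")
print(f"tuned mean radius: {radius:.2f} um  (generated at 0.50 um)")
```

Output from this exact snippet:

```
BC voxel F-score : 0.783  (PR 0.724, SN 0.853)
tuned mean radius: 0.62 um  (generated at 0.50 um)
```

The F-score is the harmonic mean of voxel precision and sensitivity against
the binary ground truth; the tuned radius is the median distance from the
gradient-tuned mesh surface to the skeleton centreline — for a tube thinner
than the PSF it sits slightly outside the generated 0.5 µm radius, because
the strongest intensity gradient of a blurred sub-resolution tube lies a
fraction of the blur width beyond the true edge.

The same stages are available from the command line
(`tissuescope3d --help`): `denoise`, `mosaic`, `surfaces`, `flatten`,
`vessels`, `register`, `segment`, `skeletonize`, `split-nuclei`, `classify`,
`cells`, `benchmark generate|evaluate`, `quantify`.

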