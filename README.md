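# octoprops

Depth-resolved estimation of the optical attenuation coefficient μ(z) and
the backscattering fraction R(z) from OCT intensity, by a constrained
stationary iteration — together with the single-scattering and Monte Carlo
simulators needed to validate it and an attenuation-compensation renderer
for OCT images.

## The problem

The classic depth-resolved attenuation estimator for OCT,

    μ(z) = I(z) / (2 ∫_z^∞ I(u) du),

is exact only if the backscattering fraction R — the portion of locally
attenuated light scattered back into the detection aperture — is constant
with depth. Real layered tissue (retina, stacked phantoms, vessel walls)
violates that: every change of R *below* a depth biases the attenuation
estimate *at* that depth, producing the familiar over- and under-estimation
bands near layer boundaries. The intensity model behind both quantities is

    I(z) = 2 β R(z) μ(z) L(z),      L(z) = L(0) exp(-2 ∫_0^z μ(u) du),

with β the detection conversion factor (only βL is observable). The two
unknown profiles are coupled through one measured curve, so the system is
underdetermined; this package resolves it with a piecewise-constant prior
on R: the profile is fuzzily segmented (only large derivative changes of R
survive; small ones are replaced by segment means), each homogeneous
portion's attenuation is anchored to its own exponential decay, and the
pair {μ_k, R_k} is refined by alternating updates under constraint bands
until the change of μ is negligible. No prior layer segmentation is
required — the segmentation emerges from the data and is re-thresholded
every loop.

Intended users: researchers doing quantitative OCT tissue characterization
(parametric imaging, attenuation compensation) who want depth-resolved μ
and R without manual layer annotation, plus the simulation tooling to
validate such estimators.

## What is in the box

| module             | contents |
| ------------------ | -------- |
| `core`             | depth grids, A-scan/B-scan/optical-profile containers, dB conversion, TIFF/text raster I/O |
| `forward_model`    | closed-form single-scattering A-line simulator, layered phantom specs, the packaged four-layer validation phantom |
| `preprocess`       | B-scan averaging, axial-PSF correction and two-position exhaustive-search calibration, noise-floor fitting and extrapolation |
| `estimators`       | depth-resolved baseline μ, backscattering initialisation, sample-average R, layer-resolved fits, phase-function-derived R and g |
| `iterative_solver` | fuzzy processing of R, the constrained stationary iteration, B-scan-wide solving |
| `compensation`     | attenuation-compensated intensity `2 R μ βL(0)` and 8-bit display rendering with gamma correction |
| `mc_sim`           | weighted-photon Monte Carlo transport through layered media (Henyey–Greenstein scattering, Fresnel boundaries, Russian roulette), next-event detection estimation, coherence-gated A-line synthesis, the packaged 13-layer retinal scene |
| `fixtures`         | seeded synthetic-data generators (PSF/speckle/floor degradations) and the end-to-end pipeline |

A thin CLI (`octoprops simulate|preprocess|calibrate-psf|solve|compensate|mc|run`)
wraps the library.

## Worked example

Recover the optical properties of the packaged four-layer phantom
(backscattering fractions 0.005 / 0.007 / 0.006 / 0.004, 0.5 mm top
layers, surface at 125 µm, 1 µm axial pitch):

```python
import numpy as np
from octoprops import make_phantom2, simulate_aline, solve
from octoprops.forward_model import phantom2_grid

phantom = make_phantom2()
grid = phantom2_grid()
state = solve(simulate_aline(phantom, grid), phantom.beta_L0)
print(f"converged after {state.k} loops ({state.stop_reason})")
edges = list(phantom.interfaces) + [grid.z_end]
for i, layer in enumerate(phantom.layers):
    sl = grid.window(edges[i] + 0.025, edges[i + 1] - 0.025)
    print(i, layer.mu, np.mean(state.mu_k[sl]), layer.R,
          np.nanmean(state.R_k[sl]))
```

prints

```
converged after 3 loops (converged)
layer  mu_true   mu_hat   R_true      R_hat
    0     1.00   0.9993   0.0050   0.005000
    1     2.00   1.9992   0.0070   0.007000
    2     3.00   3.0013   0.0060   0.006000
    3     1.50   1.5000   0.0040   0.004000
```

The baseline estimator alone misses the layer attenuations by up to ~20%
on this phantom (0.81 / 2.14 / 3.36 / 1.50 mm⁻¹) because of the layered
backscattering; the iteration recovers both profiles to a fraction of a
percent in two to three loops.

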