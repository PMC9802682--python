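# psoct

Simulation and reconstruction toolkit for catheter-based polarization-
sensitive optical coherence tomography (PSOCT) of birefringent tissue, built
around the use case of imaging white-matter fiber tracts through a narrow
rotating fiber probe.

Myelinated fiber bundles are birefringent (Δn ≈ 10⁻³): light polarized along
the fiber axis sees a slightly different refractive index than light
polarized across it. PSOCT measures the polarization state of backscattered
light versus depth and can therefore map both the amount of birefringence and
the in-plane optic-axis orientation — a label-free proxy for fiber-tract
direction. Doing this through a rotating endoscopic probe requires undoing,
per A-line, the polarization transmission of the system optics and the
spinning catheter before the tissue's own depth-resolved properties can be
extracted. This package provides the full chain for method development and
validation on synthetic data:

- **Phantoms and scan geometries** — layered slabs and white-matter-tract-like
  volumes with ground-truth Δn(x), θ(x), reflectivity; benchtop raster and
  endoscopic helical (rotation + pullback) scan patterns with per-A-line
  local reference frames.
- **Forward model** — two illumination states orthogonal on the Poincaré
  sphere, per-spectral-bin static system unitaries, a rotating-catheter
  retarder, the ball-lens reference reflection, speckle and detector noise.
- **Reconstruction** — per-bin Stokes rotation estimation, symmetrization to
  the round-trip linear-eigenstate form, spectral-bin fusion, ball-lens
  catheter compensation, iterative layer peeling to local Δn(z) and θ(z),
  degree-of-polarization (DOP) masking, and axis referencing (probe sheath
  or manual).
- **Rendering** — composite hue/brightness maps (axis in hue, Δn in
  brightness over 0–1.3×10⁻³), en-face / cross-sectional / rotational /
  unwrapped / tangential mean-projection views, HDF5 containers, TIFF/PNG
  export, and a `psoct` command-line interface.

The core model: a tissue layer of thickness δz is the linear retarder with
single-pass retardation φ = 2πΔn·δz/λ_c and Stokes axis (cos 2θ, sin 2θ, 0);
the measurement sees the cumulative round trip T_m = (J_m···J_1)ᵀ(J_m···J_1),
and local properties are recovered by peeling layers off T_m after
compensating the system and catheter. See `docs/methods.md` for the model,
estimators, conventions, and limitations.

## Worked example

Simulate a two-layer phantom (Δn = 5×10⁻⁴ at 20° over Δn = 1.2×10⁻³ at −60°)
through a seeded random system and a sinusoidally varying linear-retarder
catheter on a helical scan, then reconstruct:

```python
import numpy as np
from psoct import *

print(f"axial PSF FWHM in tissue: {axial_psf_fwhm(1300.0, 110.0, 'hann', 1.35):.2f} um")

phantom = make_layered_phantom(
    [(250.0, 5e-4, np.deg2rad(20.0), 1.0), (250.0, 1.2e-3, np.deg2rad(-60.0), 2.0)],
    lateral_shape=(40, 40), voxel_pitch=(100.0, 100.0, 4.8),
)
geometry = make_helical_geometry(
    n_revolutions=2, rotation_rate=50.0, pullback_speed=1.0, aline_rate=10_000.0,
    depth_pixels=160, delta_z=4.8, probe_od=870.0,
    cannula_point=(2000.0, 2000.0, -600.0), cannula_axis=(1.0, 0.0, 0.0),
)
print(f"probe gauge: {geometry.meta['french']} Fr, "
      f"{geometry.meta['alines_per_rev']} A-lines/rev, "
      f"pitch {geometry.meta['helical_pitch_um']:.0f} um/rev")

a_mats, b_mats = random_system(2, seed=11, scale=0.4)
config = MeasurementConfig(
    snr_db=None, n_spectral_bins=2, speckle=False, a_mats=a_mats, b_mats=b_mats,
    catheter=CatheterModel(ret_mean=0.3, ret_amp=0.25, axis_amp=0.4),
    sheath=SheathModel(dn=1.0e-3, thickness_px=4, reflectivity=1.0),
)
tomogram = synthesize_tomogram(phantom, geometry, config)
pmap = reconstruct(tomogram, ReconConfig(kernel=(1, 1), dop_kernel=(3, 3),
                                         axis_reference="sheath"))

truth = tomogram.truth
sel = pmap.mask & (truth.dn > 1e-5)
dn_err = np.abs(pmap.dn - truth.dn)[sel].max()
th_err = np.degrees(np.abs(np.angle(np.exp(2j * (pmap.theta - truth.theta_local))[sel])).max() / 2)
print(f"unmasked tissue pixels: {sel.sum()}")
print(f"max |dn error|: {dn_err:.2e}")
print(f"max axis error: {th_err:.2e} deg")
```

Output:

```
axial PSF FWHM in tissue: 8.20 um
probe gauge: 2.6 Fr, 200 A-lines/rev, pitch 20 um/rev
unmasked tissue pixels: 13062
max |dn error|: 2.73e-17
max axis error: 1.13e-11 deg
```

The PSF width says the spectral model resolves ~8 μm in tissue at a 1300 nm /
110 nm Hann-windowed sweep. On noiseless data the pipeline recovers the
ground-truth birefringence and axis at floating-point precision on every
unmasked pixel — the system and catheter corruption is removed exactly, and
the sheath reference pins the axis offset. With noise and speckle enabled
(`snr_db=30.0`, `speckle=True`, default 5×5 kernels) the median Δn error on a
10⁻³ phantom is about 5×10⁻⁵.

The same pipeline runs from the shell:

```sh
psoct simulate  --config examples/demo.yaml --seed 7 --out tomo.h5
psoct reconstruct --in tomo.h5 --out map.h5 --config examples/demo.yaml
psoct render    --in map.h5 --contrast composite --view unwrapped_enface \
                --position 250 --extent 30 --out unwrapped.png
```

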