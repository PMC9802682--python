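# Methods

## The measurement model

Polarization-sensitive OCT (PSOCT) measures the polarization state of light
backscattered from each depth in tissue. Myelinated white-matter tracts are
birefringent: light polarized along the fiber axis propagates with a slightly
different refractive index than light polarized across it (Δn ≈ 10⁻³), so the
round trip through tissue acts as a stack of wave plates. The toolkit models
the whole measurement as SU(2) retarder algebra:

- A tissue layer of one depth pixel δz with birefringence Δn and in-plane
  optic axis θ is the linear retarder J = exp(−i(φ/2) n̂·τ) with single-pass
  retardation φ = 2πΔn·δz/λ_c and Stokes-space axis n̂ = (cos 2θ, sin 2θ, 0).
- The cumulative one-way transmission to pixel m is V_m = ΔJ_m···ΔJ_1 and the
  measured round trip is T_m = V_mᵀ V_m — transpose-symmetric by reciprocity,
  hence a retarder with *linearly polarized eigenstates* (its Stokes rotation
  axis lies in the QU plane). This symmetry is the anchor of the whole
  calibration chain.
- Two illumination states alternate between A-lines, orthogonal on the
  Poincaré sphere (defaults: horizontal and +45° linear, Stokes (1,0,0) and
  (0,1,0)). Their detected Stokes vectors determine the per-pixel Stokes
  rotation up to noise.
- Static system optics are per-spectral-bin unitaries A (detection side) and
  B (illumination side); the rotating catheter is a slowly varying retarder
  C(α) of the probe rotation angle α, with an optional circular component.
  The detected field is A·C(α)ᵀ·T_m·C(α)·B·e_s, scaled by √reflectivity and a
  circular-Gaussian speckle weight (shared between the two states — both
  states see the same scatterers), plus additive circular-Gaussian detector
  noise at the configured SNR. The ball-lens reference reflection at the
  probe tip bypasses the tissue: A·C(α)ᵀ·C(α)·B·e_s.

The simulator emits depth-domain data directly; interferometric fringe
formation and k-space resampling are outside its scope. The one spectral-
domain quantity, the axial point-spread function, is computed analytically:
the FWHM of |FT of the spectral window over wavenumber|², with the round-trip
factor 2 and the tissue index n folded into the depth variable. The spectral
support is the linearized span Δk = 2πΔλ/λ_c², which makes the FWHM scale
exactly inversely with the sweep range; for λ_c = 1300 nm, Δλ = 110 nm, a
Hann window and n = 1.35 this gives 8.2 μm (the exact-endpoint convention
differs by 0.2 %).

Defaults follow the modeled instrument class: λ_c = 1300 nm, Δλ = 110 nm,
Hann window, n = 1.35, A-line rate 103.6 kHz, 50 rev/s rotation, 1 mm/s
pullback (20 μm helical pitch, 2072 A-lines per revolution), probe OD 870 μm
(2.6 Fr). The depth pixel defaults to δz = 4.8 μm, about half the ~9 μm
axial FWHM. The number of spectral bins defaults to 5. Phantom birefringence
uses 0.8–1.3×10⁻³ for white matter and <10⁻⁴ for gray matter, with white
matter also scattering more strongly; these are the contrast levels the
display range 0–1.3×10⁻³ is built around.

## Reconstruction

1. **Rotation estimation.** Per spectral bin and pixel, the (Q,U,V) of each
   state is normalized to a unit direction, averaged over a (depth ×
   A-lines) window, and the rotation mapping the two known input states onto
   the two measured directions (third axis by cross product) is
   re-orthogonalized by nearest-rotation projection (SVD). Normalizing
   *before* the spatial average is deliberate: the speckle intensity weights
   are shared across spectral bins and between neighboring windows, so
   intensity-weighted averaging would skew every bin's window mean toward
   the same random depths, defeating both spectral-bin fusion and the
   window-overlap correlation that the depth differencing in layer peeling
   relies on. With direction averaging the per-bin errors are independent
   and fusion reduces them by √n_bins.

2. **Symmetrization.** A static unitary on either side of the symmetric
   round trip breaks the QU-axis property. The corrected data must satisfy
   D R_pᵀ D = G R_p (D G D) for a single rotation G (D = diag(1,1,−1) is the
   Stokes image of transposition); G is unique for generic data and is
   estimated from pixel-pair products W = R_p R_qᵀ, whose symmetry images
   are G W G⁻¹ — a Wahba problem solved by SVD and polished by
   Levenberg–Marquardt on the symmetry residual. The correction is the
   right-multiplication R → R·(D G D). Identity is kept unless the fitted
   correction at least halves the residual: on degenerate data (a single
   dominant rotation axis) the constraint does not determine G and the
   minimal correction is the only defensible choice.

   The symmetry constraint leaves a three-parameter family of corrected
   solutions S → X·S·(D Xᵀ D). This residual is *not* estimated — it is
   absorbed: the corrected data are exactly a measurement through the
   modified catheter C·W, and the ball-lens compensation below removes any
   unitary catheter. The absorbed residual reappears only as an optic-axis
   offset that can vary with α, which axis referencing removes. The
   birefringence magnitude is exact throughout because every residual acts
   by conjugation, which preserves rotation angles.

3. **Spectral-bin fusion.** Bin b relates to the reference bin by
   R_b = (D Pᵀ D) R_0 P with one rotation P per bin (same estimation
   machinery). Aligned bins are averaged element-wise and re-projected onto
   SO(3) — a chordal mean, equivalent to the rotation-vector mean for nearby
   rotations but stable where cumulative rotation angles cross the π branch.

4. **Catheter compensation.** Per A-line, H = retarder square root of the
   ball-lens round trip, and the sample round trip is H⁻¹·R·H⁻¹. Writing the
   effective catheter C = Q·H with Q a real rotation (polar-type
   factorization in SU(2)), the compensated data are Qᵀ·T_m·Q: the tissue
   retardation is exact and the axis carries the offset angle of Q. The
   square-root branch is resolved by continuity of the ball-lens rotation
   vector along α (first A-line assumed below π). For benchtop raster data
   the operation is the identity.

5. **Layer peeling.** With V₀ = I: N_m = T_m T_{m−1}⁻¹ is un-conjugated by
   the transpose image of V_{m−1}, giving the doubled local retardance
   vector; its circular component is projected out (round-trip symmetry),
   the vector halved, converted to (Δn, θ) via φ = 2πΔn·δz/λ_c, and V is
   updated. Pixels with no detectable signal (e.g. the gap between probe and
   tissue) carry the last valid cumulative matrix forward and contribute
   zero local retardance. A doubled retardation at the π branch limit is
   flagged, not unwrapped; beyond π it aliases and is undetectable per
   pixel, which is why the simulator warns at synthesis time instead.

6. **DOP masking.** DOP = |mean(Q,U,V)|/mean(I) over the DOP kernel
   (intensity-weighted, per state, averaged over states and bins). Pixels
   below the threshold (default 0.7, kernel 5×5) are masked and displayed
   black. Noise-only regions fall to DOP ≈ O(1/√K); fully polarized uniform
   regions stay at 1. Note DOP < 1 even noiselessly where the state varies
   within the kernel — masking thresholds live well below that effect.

7. **Axis referencing.** The pipeline recovers θ up to an offset (constant
   for a purely linear catheter, α-dependent in general). "manual" subtracts
   a global offset. "sheath" uses the probe sheath — simulated as a thin
   birefringent layer at the probe surface with axis along the cannula
   (θ_local = 0) — and removes, per A-line, the circular-mean recovered
   sheath axis. Per-A-line referencing is required because the residual
   offset can legitimately vary with α; an optional smoothing window along α
   stabilizes it in noise.

## Conventions and numerical choices

- Jones matrices are stored det-normalized (SU(2)); global phase is
  unobservable in PSOCT. Reconstruction from a principal-branch retardance
  vector reproduces the matrix up to the SU(2) sign (±J are the same
  retarder).
- Stokes convention: Q = horizontal−vertical, U = +45°−(−45°), V =
  right−left circular. θ is measured from the first local reference
  direction (fast scan direction / cannula longitudinal axis) toward the
  second, stored in [−π/2, π/2). The fast axis of a retarder at θ = 0
  acquires phase e^{−iφ/2}; mirroring this sign convention mirrors all
  recovered axes, which referencing renders unobservable.
- Retardation exactly π has a degenerate axis: the representative with
  v ≥ 0 (else u ≥ 0, else q ≥ 0) is returned. A square root at rotation
  angle 2π is refused (ambiguous branch).
- Phantom sampling: trilinear interpolation for Δn and reflectivity,
  nearest-neighbor for the axis and the label (the axis is circular;
  averaging it across a boundary is meaningless). Depth pixels are half-open
  intervals [m·δz, (m+1)·δz), sampled at centers. Out-of-plane fibers have
  their apparent Δn scaled by cos² of the out-of-plane angle — an
  approximation of the reduced retardance a tilted fiber produces — and the
  out-of-plane axis component is discarded: only the azimuthal (in-plane)
  axis is reconstructed.
- Helical bookkeeping: A-lines per revolution is the exact rational
  aline_rate/rotation_rate, rounded once; pitch = pullback_speed /
  rotation_rate; French gauge = 3 × OD in mm to one decimal.
- Tomogram containers store Stokes data per spectral bin
  (stokes[aline, depth, bin, state, 4]) because the reconstruction is
  per-bin; all containers round-trip arrays bit-exactly.

## What the synthetic data do and do not emulate

The phantoms reproduce the *contrast structure* of fresh brain tissue —
strongly scattering, highly birefringent fiber tracts whose axis follows the
tract direction, embedded in weakly scattering, nearly isotropic gray
matter — and the acquisition geometry of both a benchtop raster scanner and a
rotating/pullback endoscope with ball-lens reference and sheath. Speckle is
i.i.d. circular-Gaussian per pixel (no spatial correlation), attenuation and
multiple scattering are not modeled (low DOP is exercised through
reflectivity-zero regions and additive noise instead), the catheter has no
non-uniform rotational distortion, and tissue does not deform. Passing tests
therefore demonstrate the correctness and noise behavior of the
reconstruction chain under the stated measurement model, not robustness to
every artifact of real endoscopic acquisitions.

Problem sizes in the test suite and acceptance script are chosen to exercise
the full-rate geometry once (2072 A-lines/revolution × 3 revolutions × 256
depth pixels for the noiseless end-to-end check) and scaled-down scenes
elsewhere (64-A-line rasters, 200-A-line revolutions), which the pipeline's
vectorized implementation completes in seconds to about a minute.

## Known limitations

- Absolute (world-frame) 3D axis mapping is out of scope: the recovered axis
  is azimuthal within each A-line's local frame, modulo π, relative to the
  chosen reference.
- Benchtop (raster) data offer no ball-lens reflection, so a residual
  symmetric system component cannot be absorbed there; benchtop use assumes
  calibrated (near-identity) system optics or accepts a small Δn bias from
  the unresolved residual.
- Per-layer retardation must stay below the π round-trip branch; thick
  highly birefringent layers at coarse δz alias.
- DOP thresholding near region boundaries reflects the averaging kernel's
  footprint; masked fractions are meaningful a kernel half-width away from
  boundaries.
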