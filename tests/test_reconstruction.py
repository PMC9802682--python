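import numpy as np
import pytest

from psoct import (
    CatheterModel,
    MeasurementConfig,
    ReconConfig,
    apply_mask,
    compensate_catheter,
    compute_dop,
    estimate_rotations,
    make_helical_geometry,
    make_layered_phantom,
    make_raster_geometry,
    peel_layers,
    random_system,
    reconstruct,
    reference_axis,
    symmetrize_system,
    synthesize_tomogram,
)
from psoct import retarders as rt
from psoct.reconstruction import (
    CumulativeRoundTrip,
    LocalPolarimetryMap,
    apply_symmetrization,
    ball_lens_rotations,
    _sym_residual,
)
from conftest import brute_force_layer_solver, circular_axis_error, random_retarder_stack


def _forward_rotations(tomogram, with_catheter=True):
    """Oracle: Stokes rotations of catheter^T . T_m . catheter from the
    simulator's own ground truth profile."""
    tr = tomogram.truth
    geom = tomogram.geometry
    phi = 2 * np.pi * tr.dn * geom.delta_z / (tomogram.config.lambda_c * 1e-3)
    layers = rt.linear_retarder(phi, tr.theta_local)
    n, m_depth = phi.shape
    if with_catheter and tomogram.config.catheter is not None and geom.mode == "helical":
        cath = tomogram.config.catheter.jones(geom.meta["rotation_angle"])
    else:
        cath = np.broadcast_to(np.eye(2, dtype=complex), (n, 2, 2))
    out = np.empty((n, m_depth, 3, 3))
    tissue_only = np.empty((n, m_depth, 3, 3))
    j = np.broadcast_to(np.eye(2, dtype=complex), (n, 2, 2)).copy()
    cath_t = np.swapaxes(cath, -1, -2)
    for m in range(m_depth):
        j = layers[:, m] @ j
        t_rt = rt.roundtrip(j)
        tissue_only[:, m] = rt.su2_to_so3(t_rt)
        out[:, m] = rt.su2_to_so3(cath_t @ t_rt @ cath)
    return out, tissue_only


# ---------------------------------------------------------------------------
# rotation estimation
# ---------------------------------------------------------------------------


def test_estimate_rotations_identity_channel():
    ph = make_layered_phantom([(96.0, 0.0, 0.0, 1.0)], lateral_shape=(4, 4), voxel_pitch=(50, 50, 4.8))
    geom = make_raster_geometry(4, 4, pitch_fast=50, pitch_slow=50, depth_pixels=20, delta_z=4.8)
    tomo = synthesize_tomogram(ph, geom, MeasurementConfig(snr_db=None, n_spectral_bins=1, speckle=False))
    rot, valid = estimate_rotations(tomo, ReconConfig(kernel=(1, 1)))
    assert valid.all()
    assert np.abs(rot - np.eye(3)).max() < 1e-12


def test_estimate_rotations_matches_forward_model(noiseless_helical_tomogram):
    rot, valid = estimate_rotations(noiseless_helical_tomogram, ReconConfig(kernel=(1, 1)), 0)
    # undo the known per-bin system matrices to compare with the
    # catheter+tissue-only rotations
    a = rt.su2_to_so3(noiseless_helical_tomogram.config.a_mats[0])
    b = rt.su2_to_so3(noiseless_helical_tomogram.config.b_mats[0])
    oracle, _ = _forward_rotations(noiseless_helical_tomogram)
    expected = a @ oracle @ b
    assert np.abs(rot[valid] - expected[valid]).max() < 1e-8


def test_rotation_error_decreases_with_kernel(uniform_raster_tomogram_30db):
    tomo = uniform_raster_tomogram_30db
    oracle, _ = _forward_rotations(tomo)
    valid = tomo.truth.dn > 1e-5
    medians = []
    for k in (1, 3, 5, 7, 9):
        rot, v = estimate_rotations(tomo, ReconConfig(kernel=(k, k)), 0)
        err = np.linalg.norm((rot - oracle)[valid & v], axis=(-2, -1))
        medians.append(np.median(err))
    assert all(a > b for a, b in zip(medians, medians[1:]))


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------


def test_symmetrize_identity_system_keeps_identity(noiseless_helical_tomogram):
    # simulate the same scene without system matrices: already symmetric
    tomo = noiseless_helical_tomogram
    cfg = MeasurementConfig(
        snr_db=None, n_spectral_bins=1, speckle=False,
        catheter=tomo.config.catheter, sheath=tomo.config.sheath,
    )
    phantom = make_layered_phantom(
        [(250.0, 5e-4, np.deg2rad(20.0), 1.0), (250.0, 1.2e-3, np.deg2rad(-60.0), 2.0)],
        lateral_shape=(40, 40), voxel_pitch=(100.0, 100.0, 4.8),
    )
    clean = synthesize_tomogram(phantom, tomo.geometry, cfg)
    rot, valid = estimate_rotations(clean, ReconConfig(kernel=(1, 1)), 0)
    corrected, g = symmetrize_system(rot, ReconConfig(kernel=(1, 1)), valid=valid)
    assert np.abs(g - np.eye(3)).max() < 1e-9
    assert np.array_equal(corrected[valid], rot[valid])


def test_symmetrize_restores_roundtrip_symmetry(noiseless_helical_tomogram):
    tomo = noiseless_helical_tomogram
    cfg = ReconConfig(kernel=(1, 1))
    rot, valid = estimate_rotations(tomo, cfg, 0)
    bl = ball_lens_rotations(tomo, cfg, 0)
    corrected, g = symmetrize_system(rot, cfg, valid=valid, extra=bl)
    res = np.abs(_sym_residual(corrected[valid]))
    assert res.mean() < 1e-6
    assert np.abs(_sym_residual(rot[valid])).mean() > 1e-2  # was genuinely asymmetric


def test_symmetrize_reduces_asymmetry_over_random_systems(two_layer_phantom, small_helical_geometry):
    cfg = ReconConfig(kernel=(1, 1), sym_sample=1500)
    improved = 0
    for seed in range(20):
        a, b = random_system(1, seed=100 + seed, scale=0.5)
        mcfg = MeasurementConfig(
            snr_db=None, n_spectral_bins=1, speckle=False, a_mats=a, b_mats=b,
            catheter=CatheterModel(ret_mean=0.3, ret_amp=0.2, axis_amp=0.5),
        )
        tomo = synthesize_tomogram(two_layer_phantom, small_helical_geometry, mcfg)
        rot, valid = estimate_rotations(tomo, cfg, 0)
        corrected, _ = symmetrize_system(rot, cfg, valid=valid, extra=ball_lens_rotations(tomo, cfg, 0))
        before = np.abs(_sym_residual(rot[valid])).mean()
        after = np.abs(_sym_residual(corrected[valid])).mean()
        improved += after < before
    assert improved == 20


def test_symmetrize_insufficient_pixels_raises():
    rot = np.broadcast_to(np.eye(3), (4, 4, 3, 3)).copy()
    with pytest.raises(ValueError):
        symmetrize_system(rot, ReconConfig(min_valid_pixels=32), valid=np.zeros((4, 4), dtype=bool))


# ---------------------------------------------------------------------------
# catheter compensation
# ---------------------------------------------------------------------------


def test_compensate_without_catheter_is_identity():
    rot = rt.vector_to_so3(np.random.default_rng(0).normal(size=(6, 9, 3)))
    cum = compensate_catheter(rot, None)
    assert np.array_equal(cum.rotations, rot)


def test_compensate_known_catheter(two_layer_phantom, small_helical_geometry):
    mcfg = MeasurementConfig(
        snr_db=None, n_spectral_bins=1, speckle=False,
        catheter=CatheterModel(ret_mean=0.3, ret_amp=0.25, axis_amp=0.4),
    )
    tomo = synthesize_tomogram(two_layer_phantom, small_helical_geometry, mcfg)
    cfg = ReconConfig(kernel=(1, 1))
    rot, valid = estimate_rotations(tomo, cfg, 0)
    bl = ball_lens_rotations(tomo, cfg, 0)
    cum = compensate_catheter(rot, bl, valid=valid)
    _, tissue_only = _forward_rotations(tomo, with_catheter=False)
    assert np.abs(cum.rotations[valid] - tissue_only[valid]).max() < 1e-8


def test_compensated_maps_independent_of_rotation_angle():
    """A catheter whose retardation varies sinusoidally with alpha must leave
    no alpha dependence in the compensated maps of a uniform phantom."""
    ph = make_layered_phantom([(2000.0, 1e-3, 0.0, 1.0)], lateral_shape=(50, 50), voxel_pitch=(100, 100, 50))
    geom = make_helical_geometry(
        n_revolutions=1, rotation_rate=50.0, pullback_speed=0.0, aline_rate=5000.0,
        depth_pixels=24, delta_z=10.0, cannula_point=(2500.0, 2500.0, 1000.0), cannula_axis=(1, 0, 0),
    )
    mcfg = MeasurementConfig(
        snr_db=None, n_spectral_bins=1, speckle=False,
        catheter=CatheterModel(ret_mean=0.4, ret_amp=0.3, axis_amp=0.6),
    )
    tomo = synthesize_tomogram(ph, geom, mcfg)
    pm = reconstruct(tomo, ReconConfig(kernel=(1, 1), dop_kernel=(3, 3)))
    sel = pm.mask & (tomo.truth.dn > 1e-5)
    cols = sel.all(axis=0)
    assert np.var(pm.dn[:, cols], axis=0).max() < 1e-12


# ---------------------------------------------------------------------------
# layer peeling
# ---------------------------------------------------------------------------


def test_peel_identity_gives_zero():
    t = np.broadcast_to(np.eye(3), (4, 16, 3, 3)).copy()
    dn, theta, wrap = peel_layers(CumulativeRoundTrip(t, np.ones((4, 16), bool)), 4.8, 1300.0)
    assert np.all(dn == 0) and not wrap.any()


def test_peel_matches_brute_force_solver():
    rng = np.random.default_rng(2024)
    delta_z, lambda_c = 4.8, 1300.0
    for _ in range(20):
        phis, thetas, t_su2 = random_retarder_stack(rng, 20)
        cum = CumulativeRoundTrip(rt.su2_to_so3(t_su2)[None], np.ones((1, 20), bool))
        dn, theta, wrap = peel_layers(cum, delta_z, lambda_c)
        phi_o, theta_o = brute_force_layer_solver(t_su2)
        assert np.abs(phi_o - phis).max() < 1e-8  # oracle solves the stack
        dn_o = phi_o * (lambda_c * 1e-3) / (2 * np.pi * delta_z)
        assert np.abs(dn[0] - dn_o).max() < 1e-8
        assert circular_axis_error(theta[0], theta_o).max() < 1e-8
        assert not wrap.any()


def test_peel_two_layer_noiseless(noiseless_helical_tomogram):
    tomo = noiseless_helical_tomogram
    cfg = ReconConfig(kernel=(1, 1))
    rot, valid = estimate_rotations(tomo, cfg, 0)
    bl = ball_lens_rotations(tomo, cfg, 0)
    rot_c, g = symmetrize_system(rot, cfg, valid=valid, extra=bl)
    cum = compensate_catheter(rot_c, apply_symmetrization(bl, g), valid=valid)
    dn, theta, _ = peel_layers(cum, tomo.geometry.delta_z, tomo.config.lambda_c)
    tr = tomo.truth
    sel = valid & (tr.dn > 1e-5)
    assert np.abs(dn - tr.dn)[sel].max() < 1e-8


def test_peel_wrap_flag():
    # a single layer whose doubled retardation reaches the pi branch limit
    j = rt.linear_retarder(np.pi / 2 * 0.9999, 0.3)  # doubled: ~pi
    t = rt.su2_to_so3(rt.roundtrip(j))[None, None]
    _, _, wrap = peel_layers(CumulativeRoundTrip(t, np.ones((1, 1), bool)), 4.8, 1300.0)
    assert wrap[0, 0]


# ---------------------------------------------------------------------------
# DOP and masking
# ---------------------------------------------------------------------------


def test_dop_noiseless_is_one():
    ph = make_layered_phantom([(96.0, 0.0, 0.0, 1.0)], lateral_shape=(8, 8), voxel_pitch=(50, 50, 4.8))
    geom = make_raster_geometry(8, 8, pitch_fast=50, pitch_slow=50, depth_pixels=20, delta_z=4.8)
    tomo = synthesize_tomogram(ph, geom, MeasurementConfig(snr_db=None, n_spectral_bins=1, speckle=True, seed=2))
    dop = compute_dop(tomo, ReconConfig(dop_kernel=(3, 3)))
    assert np.abs(dop - 1.0).max() < 1e-12


def test_dop_pure_noise_small():
    ph = make_layered_phantom([(96.0, 0.0, 0.0, 0.0)], lateral_shape=(32, 1), voxel_pitch=(25, 25, 4.8))
    geom = make_raster_geometry(32, 1, depth_pixels=20, delta_z=4.8)
    tomo = synthesize_tomogram(ph, geom, MeasurementConfig(snr_db=20.0, n_spectral_bins=1, seed=5, speckle=True))
    dop = compute_dop(tomo, ReconConfig(dop_kernel=(5, 5)))  # K = 25 samples
    assert np.median(dop) < 0.3


def test_dop_invariant_under_global_unitary(two_layer_phantom, small_helical_geometry):
    """Rotating the detected Stokes data by a constant unitary's SO(3) image
    leaves the DOP unchanged (unitarity preserves Stokes norms)."""
    import dataclasses

    base = MeasurementConfig(snr_db=25.0, n_spectral_bins=1, speckle=True, seed=8)
    t1 = synthesize_tomogram(two_layer_phantom, small_helical_geometry, base)
    u = rt.su2_to_so3(rt.retarder_from_vector([0.7, -0.4, 1.1]))
    stokes = t1.stokes.copy()
    stokes[..., 1:] = stokes[..., 1:] @ u.T
    t2 = dataclasses.replace(t1, stokes=stokes)
    cfg = ReconConfig(dop_kernel=(5, 5))
    assert np.abs(compute_dop(t1, cfg) - compute_dop(t2, cfg)).max() < 1e-10


def test_dop_kernel_too_large():
    ph = make_layered_phantom([(48.0, 0.0, 0.0, 1.0)], lateral_shape=(2, 2), voxel_pitch=(50, 50, 4.8))
    geom = make_raster_geometry(2, 2, depth_pixels=10, delta_z=4.8)
    tomo = synthesize_tomogram(ph, geom, MeasurementConfig(snr_db=None, n_spectral_bins=1, speckle=False))
    with pytest.raises(ValueError):
        compute_dop(tomo, ReconConfig(dop_kernel=(50, 50)))


def test_apply_mask_thresholds():
    dop = np.array([[0.0, 0.5, 0.9, 1.0]])
    pmap = LocalPolarimetryMap(
        dn=np.full((1, 4), 1e-3), theta=np.zeros((1, 4)), dop=dop, mask=np.ones((1, 4), bool), meta={}
    )
    all_valid = apply_mask(pmap, ReconConfig(dop_threshold=0.0))
    assert all_valid.mask.all()
    all_masked = apply_mask(pmap, ReconConfig(dop_threshold=1.0))
    assert all_masked.mask.sum() == 1  # only the dop = 1.0 pixel survives
    assert np.all(all_masked.dn[~all_masked.mask] == 0)
    with pytest.raises(ValueError):
        ReconConfig(dop_threshold=1.5)


def test_masked_fraction_nonincreasing_in_snr(two_layer_phantom, small_helical_geometry):
    fractions = []
    for snr in (5.0, 15.0, 25.0, 35.0):
        cfg = MeasurementConfig(snr_db=snr, n_spectral_bins=1, seed=13, speckle=True)
        tomo = synthesize_tomogram(two_layer_phantom, small_helical_geometry, cfg)
        dop = compute_dop(tomo, ReconConfig())
        lit = tomo.truth.reflectivity > 0
        fractions.append((dop[lit] < 0.7).mean())
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


# ---------------------------------------------------------------------------
# axis referencing
# ---------------------------------------------------------------------------


def test_reference_axis_manual():
    theta = np.linspace(-1.0, 1.0, 12).reshape(3, 4)
    pmap = LocalPolarimetryMap(
        dn=np.ones((3, 4)), theta=theta, dop=np.ones((3, 4)), mask=np.ones((3, 4), bool), meta={}
    )
    same = reference_axis(pmap, ReconConfig(axis_reference="manual", manual_theta=0.0))
    assert circular_axis_error(same.theta, theta).max() < 1e-12
    shifted = reference_axis(pmap, ReconConfig(axis_reference="manual", manual_theta=0.25))
    assert circular_axis_error(shifted.theta, theta - 0.25).max() < 1e-12
    twice = reference_axis(shifted, ReconConfig(axis_reference="manual", manual_theta=0.0))
    assert circular_axis_error(twice.theta, shifted.theta).max() < 1e-12


def test_reference_axis_sheath_requires_sheath():
    pmap = LocalPolarimetryMap(
        dn=np.ones((3, 4)), theta=np.zeros((3, 4)), dop=np.ones((3, 4)), mask=np.ones((3, 4), bool),
        meta={"sheath_px": 0},
    )
    with pytest.raises(ValueError):
        reference_axis(pmap, ReconConfig(axis_reference="sheath"))


def test_reference_axis_sheath_removes_offset():
    # a sheath recovered at a constant offset c shifts all axes by -c
    n, m = 6, 10
    rng = np.random.default_rng(0)
    theta_true = rng.uniform(-0.5, 0.5, size=(n, m))
    offset = 0.3
    pmap = LocalPolarimetryMap(
        dn=np.full((n, m), 1e-3),
        theta=np.clip(theta_true + offset, -np.pi / 2, np.pi / 2 - 1e-9),
        dop=np.ones((n, m)),
        mask=np.ones((n, m), bool),
        meta={"sheath_px": 3},
    )
    pmap.theta[:, :3] = offset  # sheath truly at 0, observed at c = offset
    out = reference_axis(pmap, ReconConfig(axis_reference="sheath"))
    assert circular_axis_error(out.theta[:, 3:], theta_true[:, 3:]).max() < 1e-10
    # idempotent: the re-referenced sheath now sits at 0
    again = reference_axis(out, ReconConfig(axis_reference="sheath"))
    assert circular_axis_error(again.theta, out.theta).max() < 1e-10


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def test_end_to_end_noiseless_recovery(noiseless_helical_tomogram):
    """Full pipeline on a random system + sinusoidal catheter + sheath:
    birefringence within 1e-6 and axis within 0.1 degree everywhere unmasked."""
    pm = reconstruct(
        noiseless_helical_tomogram,
        ReconConfig(kernel=(1, 1), dop_kernel=(3, 3), axis_reference="sheath"),
    )
    tr = noiseless_helical_tomogram.truth
    sel = pm.mask & (tr.dn > 1e-4)
    assert sel.sum() > 10_000
    assert np.abs(pm.dn - tr.dn)[sel].max() < 1e-6
    assert np.degrees(circular_axis_error(pm.theta, tr.theta_local)[sel].max()) < 0.1
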