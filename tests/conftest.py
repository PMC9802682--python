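import numpy as np
import pytest

from psoct import (
    CatheterModel,
    MeasurementConfig,
    SheathModel,
    make_helical_geometry,
    make_layered_phantom,
    make_raster_geometry,
    random_system,
    synthesize_tomogram,
)

TWO_LAYERS = [
    (250.0, 5e-4, np.deg2rad(20.0), 1.0),
    (250.0, 1.2e-3, np.deg2rad(-60.0), 2.0),
]


@pytest.fixture(scope="session")
def two_layer_phantom():
    return make_layered_phantom(TWO_LAYERS, lateral_shape=(40, 40), voxel_pitch=(100.0, 100.0, 4.8))


@pytest.fixture(scope="session")
def small_helical_geometry():
    # 200 A-lines per revolution keeps the suite fast; the acceptance test
    # runs the full 2072 A-lines/rev case
    return make_helical_geometry(
        n_revolutions=2,
        rotation_rate=50.0,
        pullback_speed=1.0,
        aline_rate=10_000.0,
        depth_pixels=160,
        delta_z=4.8,
        probe_od=870.0,
        cannula_point=(2000.0, 2000.0, -600.0),
        cannula_axis=(1.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def noiseless_helical_tomogram(two_layer_phantom, small_helical_geometry):
    """Two-layer phantom through a random system and a sinusoidal
    linear-retarder catheter, with a probe sheath; noiseless."""
    a_mats, b_mats = random_system(2, seed=11, scale=0.4)
    config = MeasurementConfig(
        snr_db=None,
        n_spectral_bins=2,
        seed=3,
        speckle=False,
        a_mats=a_mats,
        b_mats=b_mats,
        catheter=CatheterModel(ret_mean=0.3, ret_amp=0.25, axis_amp=0.4),
        sheath=SheathModel(dn=1.0e-3, thickness_px=4, reflectivity=1.0),
    )
    return synthesize_tomogram(two_layer_phantom, small_helical_geometry, config)


@pytest.fixture(scope="session")
def uniform_raster_tomogram_30db():
    """Uniform dn = 1e-3 slab at SNR 30 dB on a benchtop raster scan."""
    phantom = make_layered_phantom(
        [(400.0, 1e-3, np.deg2rad(30.0), 1.0)], lateral_shape=(64, 1), voxel_pitch=(25.0, 25.0, 4.8)
    )
    geometry = make_raster_geometry(64, 1, depth_pixels=80, delta_z=4.8)
    config = MeasurementConfig(snr_db=30.0, n_spectral_bins=5, seed=42, speckle=True)
    return synthesize_tomogram(phantom, geometry, config)


def circular_axis_error(theta_a, theta_b):
    """Distance between axis angles defined modulo pi, in radians."""
    return np.abs(np.angle(np.exp(2j * (theta_a - theta_b)))) / 2.0


def random_retarder_stack(rng, n_layers):
    """Per-layer (phi, theta) and the cumulative SU(2) round trips T_m."""
    from psoct import retarders as rt

    phis = rng.uniform(0.05, 0.6, size=n_layers)
    thetas = rng.uniform(-np.pi / 2, np.pi / 2, size=n_layers)
    layers = rt.linear_retarder(phis, thetas)
    t = np.empty((n_layers, 2, 2), dtype=complex)
    j = np.eye(2, dtype=complex)
    for m in range(n_layers):
        j = layers[m] @ j
        t[m] = rt.roundtrip(j)
    return phis, thetas, t


def brute_force_layer_solver(t_su2):
    """Independent per-layer direct solver on cumulative SU(2) round trips.

    Works in the Jones domain with scipy's general-purpose matrix square
    root and logarithm (no Rodrigues/SO(3) algebra): solves each layer's
    doubled retarder by un-conjugating the depth difference with the
    accumulated single-pass transmission, then reads (phi, theta) off the
    matrix logarithm.
    """
    from scipy.linalg import logm, sqrtm

    from psoct.retarders import TAU

    m_depth = t_su2.shape[0]
    phis = np.zeros(m_depth)
    thetas = np.zeros(m_depth)
    v = np.eye(2, dtype=complex)
    prev = np.eye(2, dtype=complex)
    for m in range(m_depth):
        n_m = t_su2[m] @ np.linalg.inv(prev)
        dj2 = np.linalg.inv(v.T) @ n_m @ v.T
        dj = sqrtm(dj2)
        dj = dj / np.sqrt(np.linalg.det(dj))
        ell = logm(dj)
        r = np.real(np.array([1j * np.trace(ell @ TAU[k]) for k in range(3)]))
        if np.linalg.norm(r) > np.pi:  # logm branch sign
            r = -r
        phis[m] = np.hypot(r[0], r[1])
        thetas[m] = 0.5 * np.arctan2(r[1], r[0])
        v = dj @ v
        prev = t_su2[m]
    return phis, thetas
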