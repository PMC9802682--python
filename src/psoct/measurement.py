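"""Forward simulation of polarization-modulated OCT measurements.

The simulator emits depth-domain data directly: per A-line and depth pixel it
propagates the two alternating illumination states (orthogonal on the Poincare
sphere) through static per-spectral-bin system optics, the rotating catheter,
and the cumulative round trip of the tissue layers, then adds speckle and
additive detector noise.  Only :func:`axial_psf_fwhm` touches the spectral
domain; interferometric fringe formation is outside the model.

The tissue round trip at depth pixel m is

    T_m = transpose(J_m ... J_1) (J_m ... J_1),
    J_k = linear_retarder(2 pi dn_k delta_z / lambda_c, theta_k)

and the detected field for input state s in spectral bin b is

    E = A_b C(alpha)^T T_m C(alpha) B_b e_s * sqrt(reflectivity) * g + noise

with g a circular-Gaussian speckle weight shared between the two states.  The
ball-lens reference reflection at the probe tip skips the tissue:
E_bl = A_b C^T C B_b e_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantoms import Phantom
from .retarders import (
    linear_retarder,
    retarder_from_vector,
    stokes_from_jones,
    su2_to_so3,
)
from .scanning import GroundTruthProfile, ScanGeometry, sample_ground_truth

#: default illumination Jones vectors: horizontal and +45 deg linear.
#: Their Stokes vectors (1,0,0) and (0,1,0) are orthogonal, not antipodal.
DEFAULT_INPUT_STATES = np.array([[1.0, 0.0], [1.0 / np.sqrt(2), 1.0 / np.sqrt(2)]], dtype=complex)


@dataclass
class CatheterModel:
    """Rotating-probe polarization transmission vs rotation angle alpha.

    A slowly varying retarder with sinusoidal retardation and axis drift,
    plus an optional small circular component that breaks transpose symmetry.
    """

    ret_mean: float = 0.3  # rad
    ret_amp: float = 0.2
    ret_phase: float = 0.0
    axis_mean: float = 0.0  # rad
    axis_amp: float = 0.3
    axis_phase: float = 1.0
    circ_mean: float = 0.0  # rad, circular (V) retardance component
    circ_amp: float = 0.0
    circ_phase: float = 0.0

    def retardance_vectors(self, alpha: np.ndarray) -> np.ndarray:
        phi = self.ret_mean + self.ret_amp * np.sin(alpha + self.ret_phase)
        th = self.axis_mean + self.axis_amp * np.sin(alpha + self.axis_phase)
        v = self.circ_mean + self.circ_amp * np.sin(alpha + self.circ_phase)
        return np.stack([phi * np.cos(2 * th), phi * np.sin(2 * th), v], axis=-1)

    def jones(self, alpha: np.ndarray) -> np.ndarray:
        return retarder_from_vector(self.retardance_vectors(alpha))


@dataclass
class SheathModel:
    """Probe sheath: thin birefringent layer at the probe surface.

    Its optic axis lies along the cannula's longitudinal direction
    (theta_local = 0), making it a per-A-line axis reference.
    """

    dn: float = 1.0e-3
    thickness_px: int = 4
    reflectivity: float = 1.0


@dataclass
class MeasurementConfig:
    lambda_c: float = 1300.0  # nm
    sweep_range: float = 110.0  # nm
    spectral_window: str = "hann"
    n_tissue: float = 1.35
    snr_db: Optional[float] = None  # None = noiseless
    n_spectral_bins: int = 5
    seed: int = 0
    speckle: bool = True
    input_states: np.ndarray = field(default_factory=lambda: DEFAULT_INPUT_STATES.copy())
    a_mats: Optional[np.ndarray] = None  # (n_bins, 2, 2) detection-side unitaries
    b_mats: Optional[np.ndarray] = None  # (n_bins, 2, 2) illumination-side unitaries
    catheter: Optional[CatheterModel] = None
    sheath: Optional[SheathModel] = None

    def __post_init__(self):
        self.input_states = np.asarray(self.input_states, dtype=complex)
        if self.input_states.shape != (2, 2):
            raise ValueError("input_states must be two Jones vectors (2, 2)")
        s = self.input_stokes()
        if abs(np.dot(s[0], s[1])) > 1e-10:
            raise ValueError("the two input states must be orthogonal on the Poincare sphere")
        for name in ("a_mats", "b_mats"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=complex)
                if m.shape != (self.n_spectral_bins, 2, 2):
                    raise ValueError(f"{name} must have shape (n_spectral_bins, 2, 2)")
                setattr(self, name, m)

    def input_stokes(self) -> np.ndarray:
        """Unit (Q, U, V) Stokes vectors of the two illumination states."""
        s = stokes_from_jones(self.input_states)
        return s[:, 1:] / s[:, :1]

    def system_jones(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin (A, B) Jones matrices, identity when unset."""
        eye = np.broadcast_to(np.eye(2, dtype=complex), (self.n_spectral_bins, 2, 2))
        a = self.a_mats if self.a_mats is not None else eye
        b = self.b_mats if self.b_mats is not None else eye
        return np.asarray(a), np.asarray(b)


def random_system(n_bins: int, seed: int, scale: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-bin random small unitaries emulating wavelength-dependent
    polarization effects of the static system components."""
    rng = np.random.default_rng(seed)
    vecs = rng.normal(scale=scale, size=(2, n_bins, 3))
    return retarder_from_vector(vecs[0]), retarder_from_vector(vecs[1])


@dataclass
class MeasuredTomogram:
    """Detected polarimetric tomogram.

    stokes: (n_alines, depth, n_bins, 2 states, 4) detected Stokes data.
    intensity_db: (n_alines, depth) log-scaled backscatter intensity.
    ball_lens: (n_alines, n_bins, 2 states, 4) probe-tip reference reflection
        (helical mode only; None for raster).
    """

    stokes: np.ndarray
    intensity_db: np.ndarray
    ball_lens: Optional[np.ndarray]
    geometry: ScanGeometry
    config: MeasurementConfig
    truth: Optional[GroundTruthProfile] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.stokes.shape[2]


def axial_psf_fwhm(
    lambda_c: float = 1300.0,
    sweep_range: float = 110.0,
    window: str = "hann",
    n_tissue: float = 1.35,
    n_k: int = 2048,
    pad: int = 512,
) -> float:
    """FWHM (um, in tissue) of the intensity point spread function.

    The PSF is the squared magnitude of the Fourier transform of the spectral
    window expressed over wavenumber, with the round-trip factor 2 and the
    tissue refractive index folded into the conjugate depth variable.  The
    spectral support is the linearized wavenumber span
    delta_k = 2 pi sweep_range / lambda_c^2 centered on 2 pi / lambda_c, so
    the FWHM scales exactly inversely with the sweep range.
    """
    if sweep_range <= 0:
        raise ValueError("sweep_range must be > 0")
    delta_k = 2 * np.pi * sweep_range / lambda_c**2  # nm^-1
    x = np.arange(n_k) / (n_k - 1)
    if window == "hann":
        spec = np.sin(np.pi * x) ** 2
    elif window == "rect":
        spec = np.ones_like(x)
    elif window == "gaussian":
        # FWHM of the spectral envelope = half the sweep span
        sigma = 0.25 / np.sqrt(2 * np.log(2))
        spec = np.exp(-0.5 * ((x - 0.5) / sigma) ** 2)
    else:
        raise ValueError(f"unknown spectral window: {window!r}")
    n_fft = n_k * pad
    amp = np.fft.fft(spec, n_fft)
    intensity = np.abs(amp) ** 2
    dk = delta_k / (n_k - 1)
    # conjugate variable of k under exp(i 2 n k z): depth z in nm
    dz = 2 * np.pi / (n_fft * dk * 2 * n_tissue)
    intensity = np.fft.fftshift(intensity)
    z = (np.arange(n_fft) - n_fft // 2) * dz
    half = intensity.max() / 2.0
    above = np.nonzero(intensity >= half)[0]
    i0, i1 = above[0], above[-1]

    def edge(ia, ib):
        return z[ia] + (half - intensity[ia]) * (z[ib] - z[ia]) / (intensity[ib] - intensity[ia])

    return (edge(i1 + 1, i1) - edge(i0 - 1, i0)) / 1000.0  # nm -> um


def effective_profile(
    phantom: Phantom, geometry: ScanGeometry, config: MeasurementConfig
) -> GroundTruthProfile:
    """Per-A-line ground truth as seen by the probe, including the sheath.

    For a helical scan with a sheath model, the first ``thickness_px`` depth
    pixels hold the sheath (axis 0 in the local frame) and the tissue profile
    is shifted deeper accordingly.
    """
    truth = sample_ground_truth(phantom, geometry)
    if config.sheath is None or geometry.mode != "helical":
        return truth
    s = int(config.sheath.thickness_px)
    out = GroundTruthProfile(
        dn=np.zeros_like(truth.dn),
        theta_local=np.zeros_like(truth.theta_local),
        reflectivity=np.zeros_like(truth.reflectivity),
        label=np.zeros_like(truth.label),
    )
    out.dn[:, :s] = config.sheath.dn
    out.reflectivity[:, :s] = config.sheath.reflectivity
    out.dn[:, s:] = truth.dn[:, : truth.dn.shape[1] - s]
    out.theta_local[:, s:] = truth.theta_local[:, : truth.dn.shape[1] - s]
    out.reflectivity[:, s:] = truth.reflectivity[:, : truth.dn.shape[1] - s]
    out.label[:, s:] = truth.label[:, : truth.dn.shape[1] - s]
    return out


def synthesize_tomogram(
    phantom: Phantom, geometry: ScanGeometry, config: MeasurementConfig
) -> MeasuredTomogram:
    """Simulate the detected polarimetric tomogram; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    truth = effective_profile(phantom, geometry, config)
    n, m_depth = truth.dn.shape
    lambda_um = config.lambda_c * 1e-3

    phi = 2 * np.pi * truth.dn * geometry.delta_z / lambda_um  # single-pass per layer
    if np.any(2 * phi >= np.pi):
        warnings.warn(
            "per-layer round-trip retardation reaches pi: phase wrapping likely",
            RuntimeWarning,
            stacklevel=2,
        )
    layer_j = linear_retarder(phi, truth.theta_local)  # (n, depth, 2, 2)

    # cumulative round-trip matrices T_m
    t_rt = np.empty_like(layer_j)
    j_cum = np.broadcast_to(np.eye(2, dtype=complex), (n, 2, 2)).copy()
    for m in range(m_depth):
        j_cum = layer_j[:, m] @ j_cum
        t_rt[:, m] = np.swapaxes(j_cum, -1, -2) @ j_cum

    # rotating catheter
    if config.catheter is not None and geometry.mode == "helical":
        alpha = geometry.meta["rotation_angle"]
        cath = config.catheter.jones(alpha)  # (n, 2, 2)
    else:
        cath = np.broadcast_to(np.eye(2, dtype=complex), (n, 2, 2))
    cath_t = np.swapaxes(cath, -1, -2)
    mid = cath_t[:, None] @ t_rt @ cath[:, None]  # (n, depth, 2, 2)
    bl_mid = cath_t @ cath  # (n, 2, 2)

    a_mats, b_mats = config.system_jones()
    n_bins = config.n_spectral_bins
    e_in = config.input_states  # (2 states, 2)

    if config.speckle:
        g = (rng.standard_normal((n, m_depth)) + 1j * rng.standard_normal((n, m_depth))) / np.sqrt(2)
    else:
        g = np.ones((n, m_depth), dtype=complex)
    amp = np.sqrt(truth.reflectivity) * g  # (n, depth)
    sigma = 0.5 * 10 ** (-config.snr_db / 20.0) if config.snr_db is not None else 0.0

    stokes = np.empty((n, m_depth, n_bins, 2, 4))
    ball = np.empty((n, n_bins, 2, 4))
    for b in range(n_bins):
        chan = a_mats[b] @ mid @ b_mats[b]  # (n, depth, 2, 2)
        bl_chan = a_mats[b] @ bl_mid @ b_mats[b]
        for s in range(2):
            field_ = np.einsum("ndij,j->ndi", chan, e_in[s]) * amp[..., None]
            if sigma > 0:
                field_ = field_ + sigma * (
                    rng.standard_normal(field_.shape) + 1j * rng.standard_normal(field_.shape)
                )
            stokes[:, :, b, s] = stokes_from_jones(field_)
            ball[:, b, s] = stokes_from_jones(np.einsum("nij,j->ni", bl_chan, e_in[s]))

    intensity_db = _intensity_db(stokes)
    meta = {
        "sheath_px": int(config.sheath.thickness_px)
        if (config.sheath is not None and geometry.mode == "helical")
        else 0,
        "input_stokes": config.input_stokes(),
    }
    return MeasuredTomogram(
        stokes=stokes,
        intensity_db=intensity_db,
        ball_lens=ball if geometry.mode == "helical" else None,
        geometry=geometry,
        config=config,
        truth=truth,
        meta=meta,
    )


def _intensity_db(stokes: np.ndarray) -> np.ndarray:
    power = stokes[..., 0].mean(axis=(-2, -1))  # mean over bins and states
    return 10.0 * np.log10(np.maximum(power, 1e-30))


def intensity_image(tomogram: MeasuredTomogram, floor_db: Optional[float] = None) -> np.ndarray:
    """Log-scaled scattering intensity (dB; 0 dB at unit reflectivity).

    ``floor_db`` optionally floors the map at a display minimum.
    """
    db = _intensity_db(tomogram.stokes)
    if floor_db is not None:
        db = np.maximum(db, floor_db)
    return db


def catheter_so3(config: MeasurementConfig, alpha: np.ndarray) -> np.ndarray:
    """Stokes rotation matrices of the configured catheter (testing aid)."""
    if config.catheter is None:
        return np.broadcast_to(np.eye(3), (len(alpha), 3, 3)).copy()
    return su2_to_so3(config.catheter.jones(alpha))
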