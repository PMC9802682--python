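"""Ground-truth birefringent tissue phantoms.

A :class:`Phantom` holds voxel grids of local birefringence ``dn``
(dimensionless), in-plane optic-axis angle ``theta`` (radians, world frame,
measured in the world x-y plane from +x), linear backscatter ``reflectivity``
and a tissue ``label`` grid (0 = background, 1 = gray, 2 = white).  Grids are
indexed ``[ix, iy, iz]``; voxel ``i`` along an axis covers the half-open
interval ``[i*pitch, (i+1)*pitch)`` micrometers in a right-handed world frame.

White-matter-tract phantoms emulate the contrast of myelinated fiber bundles:
ribbon-like structures that scatter more strongly and carry ~10x higher
birefringence than the surrounding gray matter, with the optic axis following
the tract centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .retarders import wrap_axis_angle

LABEL_BACKGROUND, LABEL_GRAY, LABEL_WHITE = 0, 1, 2

#: sanity ceiling on birefringence; generously above the 1.3e-3 display maximum
DN_MAX = 5e-3


@dataclass
class Phantom:
    """Voxelized ground-truth tissue volume."""

    voxel_pitch: np.ndarray  # (3,) micrometers per axis
    dn: np.ndarray
    theta: np.ndarray
    reflectivity: np.ndarray
    label: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxel_pitch = np.asarray(self.voxel_pitch, dtype=float)
        if self.voxel_pitch.shape != (3,) or np.any(self.voxel_pitch <= 0):
            raise ValueError("voxel_pitch must be 3 positive pitches (um)")
        shapes = {self.dn.shape, self.theta.shape, self.reflectivity.shape, self.label.shape}
        if len(shapes) != 1:
            raise ValueError("phantom grids must share one shape")
        if np.any(self.dn < 0) or np.any(self.dn > DN_MAX):
            raise ValueError(f"dn must lie in [0, {DN_MAX}]")
        if np.any(self.reflectivity < 0):
            raise ValueError("reflectivity must be >= 0")

    @property
    def shape(self):
        return self.dn.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical size (um) along each axis."""
        return self.voxel_pitch * np.array(self.shape)


def make_layered_phantom(
    layers,
    *,
    lateral_shape=(16, 16),
    voxel_pitch=(25.0, 25.0, 4.8),
) -> Phantom:
    """Axial stack of uniform slabs.

    ``layers`` is a list of ``(thickness_um, dn, theta, reflectivity)``; slabs
    are stacked along the world z axis.  Layer thicknesses are realized to the
    nearest whole number of voxels.
    """
    if not layers:
        raise ValueError("layer list must not be empty")
    voxel_pitch = np.asarray(voxel_pitch, dtype=float)
    nz_per = [max(1, int(round(t / voxel_pitch[2]))) for t, *_ in layers]
    nz = int(np.sum(nz_per))
    nx, ny = lateral_shape
    dn = np.zeros((nx, ny, nz))
    theta = np.zeros((nx, ny, nz))
    refl = np.zeros((nx, ny, nz))
    label = np.zeros((nx, ny, nz), dtype=np.uint8)
    z0 = 0
    for (t, layer_dn, layer_theta, layer_refl), n in zip(layers, nz_per):
        if t <= 0:
            raise ValueError("layer thicknesses must be > 0")
        sl = slice(z0, z0 + n)
        dn[:, :, sl] = layer_dn
        theta[:, :, sl] = wrap_axis_angle(layer_theta)
        refl[:, :, sl] = layer_refl
        if layer_refl > 0:
            label[:, :, sl] = LABEL_WHITE if layer_dn >= 1e-4 else LABEL_GRAY
        z0 += n
    return Phantom(voxel_pitch, dn, theta, refl, label, meta={"layers": list(layers)})


def make_wmt_phantom(
    seed: int,
    *,
    size=(64, 64, 64),
    n_tracts: int = 4,
    voxel_pitch=(10.0, 10.0, 10.0),
    tract_radius_um: float = 30.0,
    gray_dn: float = 5e-5,
    gray_reflectivity: float = 0.3,
    white_reflectivity: float = 1.0,
) -> Phantom:
    """White-matter-tract phantom: high-dn ribbons in a low-dn gray bed.

    Deterministic given ``seed``.  Each tract is a gently curved tube whose
    optic axis equals the in-plane angle of the local centerline tangent and
    whose birefringence is drawn from [0.8e-3, 1.3e-3].  ``n_tracts = 0``
    yields a pure gray-matter phantom.
    """
    size = tuple(int(s) for s in size)
    if min(size) < 32:
        raise ValueError("phantom size must be at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    voxel_pitch = np.asarray(voxel_pitch, dtype=float)
    dn = np.full(size, gray_dn)
    theta = np.zeros(size)
    refl = np.full(size, gray_reflectivity)
    label = np.full(size, LABEL_GRAY, dtype=np.uint8)

    extent = voxel_pitch * np.array(size)
    radius_vox = tract_radius_um / voxel_pitch  # per-axis radius in voxels
    ix, iy, iz = np.indices(size)
    centers = np.stack([(ix + 0.5), (iy + 0.5), (iz + 0.5)], axis=-1) * voxel_pitch

    tracts = []
    for _ in range(int(n_tracts)):
        tract_dn = rng.uniform(0.8e-3, 1.3e-3)
        p0 = extent * rng.uniform(0.25, 0.75, size=3)
        azim = rng.uniform(-np.pi, np.pi)
        d = np.array([np.cos(azim), np.sin(azim), rng.uniform(-0.15, 0.15)])
        d /= np.linalg.norm(d)
        # in-plane curvature, perpendicular to the heading
        curv = rng.uniform(-1.0, 1.0) / max(extent[:2])
        perp = np.array([-d[1], d[0], 0.0])
        half_len = 0.6 * max(extent[:2])
        t = np.linspace(-half_len, half_len, 257)
        points = p0 + t[:, None] * d + 0.5 * curv * (t**2)[:, None] * perp
        tangents = d + curv * t[:, None] * perp
        tangents /= np.linalg.norm(tangents, axis=-1, keepdims=True)
        theta_t = wrap_axis_angle(np.arctan2(tangents[:, 1], tangents[:, 0]))

        # distance of every voxel center to the nearest centerline sample,
        # measured in voxel-radius units so anisotropic pitches keep a round bore
        scaled_pts = points / (radius_vox * voxel_pitch)
        scaled_cen = centers / (radius_vox * voxel_pitch)
        best = np.full(size, np.inf)
        best_idx = np.zeros(size, dtype=np.intp)
        for k in range(points.shape[0]):
            d2 = np.sum((scaled_cen - scaled_pts[k]) ** 2, axis=-1)
            closer = d2 < best
            best = np.where(closer, d2, best)
            best_idx = np.where(closer, k, best_idx)
        inside = best <= 1.0
        dn[inside] = tract_dn
        theta[inside] = theta_t[best_idx[inside]]
        refl[inside] = white_reflectivity
        label[inside] = LABEL_WHITE
        tracts.append({"points": points, "tangents": tangents, "theta": theta_t, "dn": tract_dn})

    return Phantom(voxel_pitch, dn, theta, refl, label, meta={"tracts": tracts, "seed": seed})
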