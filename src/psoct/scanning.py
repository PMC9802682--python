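"""Scan geometries (benchtop raster, endoscopic helical) and ground-truth sampling.

Each A-line has a pose: an origin (um, world frame), a unit beam direction,
and a local frame basis (e1, e2) orthogonal to the beam that defines the
optic-axis reference: the recovered axis angle is measured from e1 toward e2.
For raster scans e1/e2 are the fast/slow scan directions; for helical scans
e1 is the longitudinal (cannula axis) direction and e2 the circumferential
direction, i.e. a plane tangential to the cannula surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .phantoms import Phantom
from .retarders import wrap_axis_angle


@dataclass
class ScanGeometry:
    mode: str  # "raster" | "helical"
    n_alines: int
    depth_pixels: int
    delta_z: float  # um
    origins: np.ndarray  # (n_alines, 3) um
    directions: np.ndarray  # (n_alines, 3) unit
    e1: np.ndarray  # (n_alines, 3) unit, first in-plane reference
    e2: np.ndarray  # (n_alines, 3) unit, second in-plane reference
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("origins", "directions", "e1", "e2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_alines, 3):
                raise ValueError(f"{name} must have shape (n_alines, 3)")
            setattr(self, name, arr)
        if self.delta_z <= 0:
            raise ValueError("delta_z must be > 0")
        dots = np.abs(np.einsum("ij,ij->i", self.directions, self.e1))
        dots2 = np.abs(np.einsum("ij,ij->i", self.directions, self.e2))
        if dots.max(initial=0) > 1e-9 or dots2.max(initial=0) > 1e-9:
            raise ValueError("beam direction must be orthogonal to the local frame basis")


@dataclass
class GroundTruthProfile:
    """Per-A-line ground truth in the local (beam) frame."""

    dn: np.ndarray  # (n_alines, depth_pixels)
    theta_local: np.ndarray
    reflectivity: np.ndarray
    label: np.ndarray


def french_gauge(od_um: float) -> float:
    """Catheter gauge: French = 3 x outer diameter in mm, to one decimal."""
    return round(3.0 * od_um / 1000.0, 1)


def make_raster_geometry(
    n_fast: int,
    n_slow: int,
    *,
    pitch_fast: float = 25.0,
    pitch_slow: float = 25.0,
    depth_pixels: int = 128,
    delta_z: float = 4.8,
    origin=(0.0, 0.0, 0.0),
) -> ScanGeometry:
    """Benchtop raster: beams along +z on a regular (fast x, slow y) grid."""
    origin = np.asarray(origin, dtype=float)
    fx = (np.arange(n_fast) + 0.5) * pitch_fast
    sy = (np.arange(n_slow) + 0.5) * pitch_slow
    gx, gy = np.meshgrid(fx, sy, indexing="ij")
    n = n_fast * n_slow
    origins = origin + np.stack([gx.ravel(), gy.ravel(), np.zeros(n)], axis=-1)
    directions = np.tile([0.0, 0.0, 1.0], (n, 1))
    e1 = np.tile([1.0, 0.0, 0.0], (n, 1))
    e2 = np.tile([0.0, 1.0, 0.0], (n, 1))
    return ScanGeometry(
        "raster", n, depth_pixels, delta_z, origins, directions, e1, e2,
        meta={"n_fast": n_fast, "n_slow": n_slow, "pitch_fast": pitch_fast, "pitch_slow": pitch_slow},
    )


def make_helical_geometry(
    *,
    n_revolutions: int = 3,
    rotation_rate: float = 50.0,  # rev/s
    pullback_speed: float = 1.0,  # mm/s
    aline_rate: float = 103_600.0,  # A-lines/s
    depth_pixels: int = 256,
    delta_z: float = 4.8,
    probe_od: float = 870.0,  # um
    cannula_point=(0.0, 0.0, 0.0),
    cannula_axis=(1.0, 0.0, 0.0),
    ball_lens_depth_index: int = 0,
) -> ScanGeometry:
    """Endoscopic helical scan: rotation + pullback along a rigid cannula.

    A-lines per revolution is kept as an exact rational aline_rate /
    rotation_rate and rounded once to the nearest integer; the helical pitch
    (pullback advance per revolution) is pullback_speed / rotation_rate.
    """
    if rotation_rate <= 0 or aline_rate <= 0 or pullback_speed < 0:
        raise ValueError("rates must be positive")
    alines_per_rev = int(round(Fraction(aline_rate) / Fraction(rotation_rate)))
    n = alines_per_rev * int(n_revolutions)
    pitch_um = pullback_speed * 1000.0 / rotation_rate  # um per revolution

    axis = np.asarray(cannula_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # radial basis perpendicular to the cannula axis
    helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, axis)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)

    i = np.arange(n)
    alpha = 2 * np.pi * i / alines_per_rev
    pullback = pitch_um * i / alines_per_rev
    directions = np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * w
    origins = (
        np.asarray(cannula_point, dtype=float)
        + pullback[:, None] * axis
        + (probe_od / 2.0) * directions
    )
    e1 = np.tile(axis, (n, 1))  # longitudinal
    e2 = -np.sin(alpha)[:, None] * u + np.cos(alpha)[:, None] * w  # circumferential
    return ScanGeometry(
        "helical", n, depth_pixels, delta_z, origins, directions, e1, e2,
        meta={
            "rotation_rate": rotation_rate,
            "pullback_speed": pullback_speed,
            "aline_rate": aline_rate,
            "alines_per_rev": alines_per_rev,
            "n_revolutions": int(n_revolutions),
            "helical_pitch_um": pitch_um,
            "probe_od": probe_od,
            "french": french_gauge(probe_od),
            "ball_lens_depth_index": int(ball_lens_depth_index),
            "rotation_angle": alpha,
            "pullback_um": pullback,
            "cannula_point": np.asarray(cannula_point, dtype=float),
            "cannula_axis": axis,
        },
    )


def make_scan_geometry(mode: str, **params) -> ScanGeometry:
    """Dispatch to :func:`make_raster_geometry` or :func:`make_helical_geometry`."""
    if mode == "raster":
        n_fast = params.pop("n_fast")
        n_slow = params.pop("n_slow")
        return make_raster_geometry(n_fast, n_slow, **params)
    if mode == "helical":
        return make_helical_geometry(**params)
    raise ValueError(f"unknown scan mode: {mode!r}")


def sample_ground_truth(phantom: Phantom, geometry: ScanGeometry) -> GroundTruthProfile:
    """Sample per-A-line ground truth profiles in each A-line's local frame.

    Samples at depth-pixel centers (m + 1/2) * delta_z along each beam.
    dn and reflectivity are interpolated trilinearly; the axis angle and the
    label use nearest-neighbor lookup (the axis is circular, so averaging it
    across a boundary is meaningless).  The world axis is re-expressed as the
    azimuthal angle within the local (e1, e2) frame; the out-of-plane
    component is discarded, and the sampled dn is scaled by cos^2 of the
    out-of-plane angle to emulate the reduced apparent birefringence of
    out-of-plane fibers.  Beams leaving the volume return background (0).
    """
    m = np.arange(geometry.depth_pixels)
    # (n_alines, depth, 3) world positions of pixel centers
    pos = geometry.origins[:, None, :] + geometry.directions[:, None, :] * (
        (m[None, :, None] + 0.5) * geometry.delta_z
    )
    coords = (pos / phantom.voxel_pitch) - 0.5  # voxel-center convention
    coords = np.moveaxis(coords, -1, 0)

    dn = ndimage.map_coordinates(phantom.dn, coords, order=1, mode="grid-constant", cval=0.0)
    refl = ndimage.map_coordinates(phantom.reflectivity, coords, order=1, mode="grid-constant", cval=0.0)
    theta_w = ndimage.map_coordinates(phantom.theta, coords, order=0, mode="grid-constant", cval=0.0)
    label = ndimage.map_coordinates(phantom.label, coords, order=0, mode="grid-constant", cval=0)

    # world-frame in-plane axis vector
    ax = np.stack([np.cos(theta_w), np.sin(theta_w), np.zeros_like(theta_w)], axis=-1)
    a1 = np.einsum("adk,ak->ad", ax, geometry.e1)
    a2 = np.einsum("adk,ak->ad", ax, geometry.e2)
    a_beam = np.einsum("adk,ak->ad", ax, geometry.directions)
    theta_local = wrap_axis_angle(np.arctan2(a2, a1))
    in_plane = np.hypot(a1, a2)
    theta_local = np.where(in_plane > 1e-12, theta_local, 0.0)
    dn_eff = dn * (1.0 - a_beam**2)  # cos^2 of the out-of-plane angle
    return GroundTruthProfile(dn_eff, theta_local, refl, label.astype(np.uint8))
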