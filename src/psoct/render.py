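"""Display products: composite hue/brightness maps and projection views.

The composite map encodes the optic-axis orientation as color hue (cyclic HSV
wheel over the axis period pi) and birefringence as brightness over a fixed
display range (default 0 to 1.3e-3); masked pixels are black.  Intensity
tomograms are displayed as 0-40 dB grayscale.

Views are mean projections over a stated extent along the out-of-plane
direction of the requested slice.  Circular quantities (the axis angle) are
averaged as doubled-angle phasors.  Masked pixels are excluded from the
means; a window that is masked everywhere yields NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .scanning import ScanGeometry

#: display ranges and projection extents used by the standard figures
DEFAULT_DN_RANGE = 1.3e-3
DEFAULT_INTENSITY_RANGE = (0.0, 40.0)  # dB
BENCHTOP_ENFACE_EXTENT_UM = 30.0
BENCHTOP_CROSS_EXTENT_UM = 70.0
ENDO_ENFACE_EXTENT_UM = 30.0
ENDO_PULLBACK_CROSS_EXTENT_DEG = 2.5
ENDO_ROT_CROSS_EXTENT_UM = 140.0
DEEP_ROT_CROSS_EXTENT_UM = 60.0

VIEW_KINDS = (
    "enface",
    "cross_fast",
    "cross_slow",
    "rot_cross",
    "pullback_cross",
    "unwrapped_enface",
    "tangential",
)


@dataclass
class ViewSpec:
    kind: str
    position: float  # um, or degrees for pullback_cross
    extent: float  # um, or degrees for pullback_cross

    def __post_init__(self):
        if self.kind not in VIEW_KINDS:
            raise ValueError(f"unknown view kind: {self.kind!r}")
        if self.extent <= 0:
            raise ValueError("projection extent must be > 0")


@dataclass
class CompositeImage:
    rgb: np.ndarray  # (..., 3) in [0, 1]
    colorbar: dict = field(default_factory=dict)


def composite_map(pmap, dn_max: float = DEFAULT_DN_RANGE) -> CompositeImage:
    """Hue = axis orientation (period pi), brightness = dn / dn_max, masked black."""
    if dn_max <= 0:
        raise ValueError("dn_max must be > 0")
    hue = np.mod((pmap.theta + np.pi / 2) / np.pi, 1.0)
    val = np.clip(pmap.dn / dn_max, 0.0, 1.0) * pmap.mask
    hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
    return CompositeImage(
        rgb=hsv_to_rgb(hsv),
        colorbar={
            "hue_period_rad": np.pi,
            "hue_zero": "axis -90 deg at hue 0, +90 deg wraps to the same hue",
            "brightness_range": (0.0, dn_max),
        },
    )


def intensity_grayscale(db: np.ndarray, drange=DEFAULT_INTENSITY_RANGE) -> np.ndarray:
    """Map a dB image onto [0, 1] over the display range (default 0-40 dB)."""
    lo, hi = drange
    return np.clip((db - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# volumes in the geometry's native coordinates
# ---------------------------------------------------------------------------


@dataclass
class RasterVolume:
    """(fast, slow, depth) volume; pitches in um."""

    data: np.ndarray
    pitch: tuple  # (fast, slow, depth) um
    mask: Optional[np.ndarray] = None
    circular: bool = False


@dataclass
class CylindricalVolume:
    """(pullback revolution, rotation angle, depth) volume from a helical scan."""

    data: np.ndarray
    pitch_rev_um: float  # pullback advance per revolution
    deg_per_aline: float
    delta_z: float
    r0: float  # radius of the first depth pixel (probe surface), um
    mask: Optional[np.ndarray] = None
    circular: bool = False


def as_volume(values: np.ndarray, geometry: ScanGeometry, mask=None, circular=False):
    """Reshape per-A-line data (n_alines, depth) into the native volume."""
    if geometry.mode == "raster":
        nf, ns = geometry.meta["n_fast"], geometry.meta["n_slow"]
        shape = (nf, ns, geometry.depth_pixels)
        return RasterVolume(
            values.reshape(shape),
            (geometry.meta["pitch_fast"], geometry.meta["pitch_slow"], geometry.delta_z),
            mask=None if mask is None else mask.reshape(shape),
            circular=circular,
        )
    apr = geometry.meta["alines_per_rev"]
    nrev = geometry.meta["n_revolutions"]
    shape = (nrev, apr, geometry.depth_pixels)
    return CylindricalVolume(
        values.reshape(shape),
        pitch_rev_um=geometry.meta["helical_pitch_um"],
        deg_per_aline=360.0 / apr,
        delta_z=geometry.delta_z,
        r0=geometry.meta["probe_od"] / 2.0,
        mask=None if mask is None else mask.reshape(shape),
        circular=circular,
    )


def _window(center_idx: float, half_idx: float, size: int, wrap: bool):
    # pixels whose centers fall in the half-open window [center-half, center+half)
    lo = int(np.floor(center_idx - half_idx + 0.5))
    hi = max(int(np.floor(center_idx + half_idx + 0.5)) - 1, lo)
    idx = np.arange(lo, hi + 1)
    if wrap:
        return np.mod(idx, size)
    idx = idx[(idx >= 0) & (idx < size)]
    if idx.size == 0:
        raise ValueError("projection window lies outside the volume")
    return idx


def _project(data, mask, axis, idx, circular):
    sub = np.take(data, idx, axis=axis)
    w = np.ones_like(sub) if mask is None else np.take(mask, idx, axis=axis).astype(float)
    wsum = w.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        if circular:
            z = (w * np.exp(2j * sub)).sum(axis=axis) / np.where(wsum == 0, 1.0, wsum)
            out = 0.5 * np.angle(z)
        else:
            out = (w * sub).sum(axis=axis) / np.where(wsum == 0, 1.0, wsum)
    return np.where(wsum > 0, out, np.nan)


def extract_view(volume, spec: ViewSpec) -> np.ndarray:
    """Mean projection over the spec extent centered at the spec position.

    Raster kinds: enface -> (fast, slow); cross_fast (slice along the fast
    direction at a slow position) -> (fast, depth); cross_slow -> (slow,
    depth); positions/extents in um.

    Helical kinds: rot_cross (at a pullback position, projected along the
    pullback) -> (angle, depth); pullback_cross (at a rotation angle in
    degrees, projected over degrees) -> (pullback, depth); unwrapped_enface
    (at a constant distance from the probe surface) -> (pullback, angle);
    tangential (plane parallel to the cannula at a perpendicular distance
    from its axis) -> (pullback, lateral).
    """
    if isinstance(volume, RasterVolume):
        pf, ps, dz = volume.pitch
        if spec.kind == "enface":
            axis, pitch = 2, dz
        elif spec.kind == "cross_fast":
            axis, pitch = 1, ps
        elif spec.kind == "cross_slow":
            axis, pitch = 0, pf
        else:
            raise ValueError(f"view kind {spec.kind!r} needs a helical volume")
        n = volume.data.shape[axis]
        center = spec.position / pitch - 0.5
        if not -0.5 <= center <= n - 0.5:
            raise ValueError("view position outside the volume")
        idx = _window(center, spec.extent / (2 * pitch), n, wrap=False)
        out = _project(volume.data, volume.mask, axis, idx, volume.circular)
        return np.swapaxes(out, 0, 1) if spec.kind == "cross_slow" else out

    if not isinstance(volume, CylindricalVolume):
        raise TypeError("volume must be a RasterVolume or CylindricalVolume")
    v = volume
    if spec.kind == "rot_cross":
        n = v.data.shape[0]
        center = spec.position / v.pitch_rev_um
        if not -0.5 <= center <= n - 0.5:
            raise ValueError("view position outside the volume")
        idx = _window(center, spec.extent / (2 * v.pitch_rev_um), n, wrap=False)
        return _project(v.data, v.mask, 0, idx, v.circular)
    if spec.kind == "pullback_cross":
        n = v.data.shape[1]
        center = np.mod(spec.position, 360.0) / v.deg_per_aline
        idx = _window(center, spec.extent / (2 * v.deg_per_aline), n, wrap=True)
        return _project(v.data, v.mask, 1, idx, v.circular)
    if spec.kind == "unwrapped_enface":
        n = v.data.shape[2]
        center = spec.position / v.delta_z - 0.5
        if not -0.5 <= center <= n - 0.5:
            raise ValueError("view position outside the volume")
        idx = _window(center, spec.extent / (2 * v.delta_z), n, wrap=False)
        return _project(v.data, v.mask, 2, idx, v.circular)
    if spec.kind == "tangential":
        return _tangential(v, spec.position, spec.extent)
    raise ValueError(f"view kind {spec.kind!r} needs a raster volume")


def _tangential(v: CylindricalVolume, distance: float, extent: float) -> np.ndarray:
    """Plane parallel to the cannula axis at a perpendicular distance (um)."""
    nrev, napr, ndepth = v.data.shape
    rmax = v.r0 + ndepth * v.delta_z
    if not v.r0 <= distance < rmax:
        raise ValueError("tangential plane distance outside the imaged annulus")
    smax = np.sqrt(max(rmax**2 - distance**2, 0.0))
    ns = 2 * int(smax / v.delta_z) + 1
    s = (np.arange(ns) - ns // 2) * v.delta_z
    nx = max(1, int(round(extent / v.delta_z)))
    x = distance + (np.arange(nx) - (nx - 1) / 2.0) * v.delta_z
    r = np.hypot(x[:, None], s[None, :])
    phi = np.degrees(np.arctan2(s[None, :], x[:, None]))
    aidx = np.mod(np.rint(phi / v.deg_per_aline).astype(int), napr)
    didx = np.rint((r - v.r0) / v.delta_z - 0.5).astype(int)
    inside = (didx >= 0) & (didx < ndepth)
    didx = np.clip(didx, 0, ndepth - 1)

    sub = v.data[:, aidx, didx]  # (nrev, nx, ns)
    w = inside.astype(float)[None, :, :]
    if v.mask is not None:
        w = w * v.mask[:, aidx, didx]
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if v.circular:
            z = (w * np.exp(2j * sub)).sum(axis=1) / np.where(wsum == 0, 1.0, wsum)
            out = 0.5 * np.angle(z)
        else:
            out = (w * sub).sum(axis=1) / np.where(wsum == 0, 1.0, wsum)
    return np.where(wsum > 0, out, np.nan)
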