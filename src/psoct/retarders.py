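"""SU(2)/SO(3) polarimetry algebra for retarders.

Jones matrices are plain complex ndarrays of shape ``(..., 2, 2)``, kept as
det = 1 (SU(2)) representatives: PSOCT is insensitive to common phase, and the
normalization makes the SU(2) <-> SO(3) correspondence unambiguous up to sign.
Retardance vectors are real ndarrays ``(..., 3)`` holding the Stokes-space
rotation-vector components (Q, U, V) in radians; a linear retarder has zero V
component.

Conventions
-----------
Pauli basis (tau1, tau2, tau3) is ordered to match Stokes (Q, U, V) with
Q = horizontal - vertical, U = +45 - (-45), V = right - left circular.  A
retarder with retardance vector ``r`` (|r| = phi) is

    J = exp(-i (phi/2) (rhat . tau)) = cos(phi/2) I - i sin(phi/2) (rhat . tau)

and its Stokes-space image rotates (Q, U, V) by the angle phi about rhat.  The
optic-axis angle theta is measured from the first in-plane reference direction,
counterclockwise, stored in [-pi/2, pi/2); a linear retarder with axis theta
has retardance vector phi * (cos 2theta, sin 2theta, 0).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TAU",
    "linear_retarder",
    "retarder_from_vector",
    "retardance_vector",
    "roundtrip",
    "retarder_sqrt",
    "project_linear",
    "axis_and_birefringence",
    "wrap_axis_angle",
    "su2_to_so3",
    "so3_to_vector",
    "vector_to_so3",
    "nearest_rotation",
    "transpose_image",
    "stokes_from_jones",
    "is_unitary",
]

# Pauli-like basis matching the (Q, U, V) Stokes ordering.
TAU = np.array(
    [
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# Stokes-space image of matrix transposition: J -> J^T maps R -> D R^T D.
_D = np.diag([1.0, 1.0, -1.0])

_EYE2 = np.eye(2, dtype=complex)


def is_unitary(j: np.ndarray, tol: float = 1e-12) -> bool:
    """True if every matrix in the stack is unitary with det 1 within tol."""
    j = np.asarray(j, dtype=complex)
    jh = np.conj(np.swapaxes(j, -1, -2))
    gram = np.einsum("...ij,...jk->...ik", j, jh)
    if not np.allclose(gram, _EYE2, atol=10 * tol):
        return False
    det = j[..., 0, 0] * j[..., 1, 1] - j[..., 0, 1] * j[..., 1, 0]
    return bool(np.allclose(det, 1.0, atol=10 * tol))


def retarder_from_vector(r: np.ndarray) -> np.ndarray:
    """SU(2) retarder with Stokes rotation vector ``r`` (radians), shape (...,3)."""
    r = np.asarray(r, dtype=float)
    phi = np.linalg.norm(r, axis=-1)
    # unit axis; arbitrary for phi == 0 where sin(phi/2)/phi -> handled by sinc
    half = phi / 2.0
    # sin(phi/2)/phi, finite at 0
    scale = 0.5 * np.sinc(half / np.pi)
    ntau = np.einsum("...k,kij->...ij", r * scale[..., None], TAU)
    return np.cos(half)[..., None, None] * _EYE2 - 1j * ntau


def linear_retarder(phi, theta) -> np.ndarray:
    """Linear retarder: single-pass retardation ``phi`` >= 0, axis ``theta``.

    theta is interpreted modulo pi.  The result is transpose-symmetric and has
    retardance vector phi * (cos 2theta, sin 2theta, 0) for phi <= pi.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(phi < 0):
        raise ValueError("retardation phi must be >= 0")
    r = np.stack(
        [phi * np.cos(2 * theta), phi * np.sin(2 * theta), np.zeros_like(phi * theta)],
        axis=-1,
    )
    return retarder_from_vector(r)


def _su2_angle_axis(j: np.ndarray):
    """Raw rotation angle in [0, 2pi) and unit axis of an SU(2) element."""
    j = np.asarray(j, dtype=complex)
    c = 0.5 * np.real(j[..., 0, 0] + j[..., 1, 1])
    # s_k = Re[(i/2) tr(J tau_k)] = sin(phi/2) * n_k
    svec = np.stack(
        [
            np.real(0.5j * (j[..., 0, 0] - j[..., 1, 1])),
            np.real(0.5j * (j[..., 0, 1] + j[..., 1, 0])),
            0.5 * np.real(j[..., 1, 0] - j[..., 0, 1]),
        ],
        axis=-1,
    )
    s = np.linalg.norm(svec, axis=-1)
    phi = 2.0 * np.arctan2(s, np.clip(c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(s[..., None] > 0, svec / np.where(s == 0, 1.0, s)[..., None], 0.0)
    return phi, axis


def retardance_vector(j: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Principal-branch Stokes rotation vector of an SU(2) retarder.

    The returned norm lies in [0, pi].  For retardation within ``tol`` of pi
    the axis sign is degenerate; the representative with v >= 0 (else u >= 0,
    else q >= 0) is returned.
    """
    phi, axis = _su2_angle_axis(j)
    # reduce to principal branch: phi in [0, pi]
    flip = phi > np.pi
    phi = np.where(flip, 2 * np.pi - phi, phi)
    axis = np.where(flip[..., None], -axis, axis)
    r = phi[..., None] * axis
    # tie-break the sign at phi == pi
    at_pi = np.abs(phi - np.pi) < tol
    if np.any(at_pi):
        v, u, q = r[..., 2], r[..., 1], r[..., 0]
        want_flip = (v < -tol) | ((np.abs(v) <= tol) & ((u < -tol) | ((np.abs(u) <= tol) & (q < 0))))
        r = np.where((at_pi & want_flip)[..., None], -r, r)
    return r


def roundtrip(j_cum: np.ndarray) -> np.ndarray:
    """Round-trip retarder transpose(J) @ J of a cumulative one-way J.

    The result is transpose-symmetric, hence has linearly polarized
    eigenstates (Stokes rotation axis in the QU plane).
    """
    j_cum = np.asarray(j_cum, dtype=complex)
    return np.swapaxes(j_cum, -1, -2) @ j_cum


def retarder_sqrt(j2: np.ndarray, branch_tol: float = 1e-6) -> np.ndarray:
    """Retarder square root: halves the Stokes rotation vector of ``j2``.

    The square root is taken on the raw branch (rotation angle in [0, 2pi)),
    so the result squared reproduces ``j2`` exactly.  A rotation angle within
    ``branch_tol`` of 2pi (j2 close to -I) has no well-defined principal root
    and raises ValueError.
    """
    phi, axis = _su2_angle_axis(j2)
    if np.any(np.abs(phi - 2 * np.pi) < branch_tol):
        raise ValueError("retardation within tolerance of 2*pi: ambiguous square-root branch")
    return retarder_from_vector(0.5 * phi[..., None] * axis)


def project_linear(r: np.ndarray) -> np.ndarray:
    """Zero the circular (V) component of a retardance vector; idempotent."""
    r = np.array(r, dtype=float, copy=True)
    r[..., 2] = 0.0
    return r


def wrap_axis_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap an optic-axis angle (defined modulo pi) into [-pi/2, pi/2)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi / 2, np.pi) - np.pi / 2


def axis_and_birefringence(r: np.ndarray, delta_z: float, lambda_c: float):
    """Optic-axis angle and birefringence from a local single-pass retardance.

    Parameters
    ----------
    r : (..., 3) linear retardance vector (V component ignored after
        projection), radians.
    delta_z : depth-pixel thickness in micrometers.
    lambda_c : center wavelength in nanometers.

    Returns
    -------
    theta : axis angle in [-pi/2, pi/2); 0 by convention where |r| = 0.
    dn : birefringence, dn = |r| * lambda_c / (2 pi delta_z).
    """
    if delta_z <= 0:
        raise ValueError("delta_z must be > 0")
    r = np.asarray(r, dtype=float)
    norm = np.hypot(r[..., 0], r[..., 1])
    theta = wrap_axis_angle(0.5 * np.arctan2(r[..., 1], r[..., 0]))
    theta = np.where(norm > 0, theta, 0.0)
    dn = norm * (lambda_c * 1e-3) / (2 * np.pi * delta_z)
    return theta, dn


# ---------------------------------------------------------------------------
# SO(3) counterparts
# ---------------------------------------------------------------------------


def su2_to_so3(j: np.ndarray) -> np.ndarray:
    """Stokes-space rotation matrix of an SU(2) element: R_ij = tr(tau_i J tau_j J†)/2."""
    j = np.asarray(j, dtype=complex)
    jh = np.conj(np.swapaxes(j, -1, -2))
    # tau_i J tau_j J† traced over the 2x2 indices
    m = np.einsum("iab,...bc,jcd,...da->...ij", TAU, j, TAU, jh)
    return 0.5 * np.real(m)


def vector_to_so3(r: np.ndarray) -> np.ndarray:
    """Rodrigues map: rotation matrix for rotation vector ``r`` (radians)."""
    r = np.asarray(r, dtype=float)
    phi = np.linalg.norm(r, axis=-1)
    # sin(phi)/phi and (1-cos(phi))/phi^2, both finite at 0
    a = np.sinc(phi / np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(phi > 1e-6, (1 - np.cos(phi)) / np.where(phi == 0, 1.0, phi) ** 2, 0.5 - phi**2 / 24)
    zeros = np.zeros_like(phi)
    k = np.stack(
        [
            np.stack([zeros, -r[..., 2], r[..., 1]], axis=-1),
            np.stack([r[..., 2], zeros, -r[..., 0]], axis=-1),
            np.stack([-r[..., 1], r[..., 0], zeros], axis=-1),
        ],
        axis=-2,
    )
    k2 = k @ k
    return np.eye(3) + a[..., None, None] * k + b[..., None, None] * k2


def so3_to_vector(rot: np.ndarray) -> np.ndarray:
    """Principal rotation vector (norm in [0, pi]) of a rotation matrix stack."""
    rot = np.asarray(rot, dtype=float)
    tr = rot[..., 0, 0] + rot[..., 1, 1] + rot[..., 2, 2]
    cos = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos)
    a = 0.5 * np.stack(
        [
            rot[..., 2, 1] - rot[..., 1, 2],
            rot[..., 0, 2] - rot[..., 2, 0],
            rot[..., 1, 0] - rot[..., 0, 1],
        ],
        axis=-1,
    )  # = sin(angle) * axis
    sin = np.sin(angle)
    out = np.zeros_like(a)
    small = angle < 1e-6
    near_pi = angle > np.pi - 1e-6
    mid = ~small & ~near_pi
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mid[..., None], a * (angle / np.where(sin == 0, 1.0, sin))[..., None], out)
    out = np.where(small[..., None], a, out)  # angle/sin -> 1
    if np.any(near_pi):
        # axis from the symmetric part: R + I = 2 (axis axis^T) at angle pi
        sym = 0.5 * (rot + np.swapaxes(rot, -1, -2))
        diag = np.stack([sym[..., 0, 0], sym[..., 1, 1], sym[..., 2, 2]], axis=-1)
        axis = np.sqrt(np.clip((diag + 1.0) / 2.0, 0.0, 1.0))
        # fix relative signs from the off-diagonals, anchored on the largest component
        i = np.argmax(axis, axis=-1)
        ax = np.array(axis)
        idx = np.ndindex(*rot.shape[:-2]) if rot.ndim > 2 else [()]
        for ind in idx:
            k = int(i[ind]) if rot.ndim > 2 else int(i)
            s = sym[ind] if rot.ndim > 2 else sym
            v = ax[ind] if rot.ndim > 2 else ax
            for jj in range(3):
                if jj != k and v[jj] > 0:
                    v[jj] *= np.sign(s[k, jj]) if s[k, jj] != 0 else 1.0
            # tie-break: v >= 0, else u >= 0, else q >= 0
            if v[2] < 0 or (v[2] == 0 and (v[1] < 0 or (v[1] == 0 and v[0] < 0))):
                v *= -1
            if rot.ndim > 2:
                ax[ind] = v
        out = np.where(near_pi[..., None], ax * angle[..., None], out)
    return out


def nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project a stack of 3x3 matrices onto SO(3) (Frobenius-nearest)."""
    u, _, vt = np.linalg.svd(np.asarray(m, dtype=float))
    det = np.linalg.det(u @ vt)
    d = np.ones(m.shape[:-2] + (3,))
    d[..., 2] = det
    return (u * d[..., None, :]) @ vt


def transpose_image(rot: np.ndarray) -> np.ndarray:
    """Stokes-space image of Jones transposition: R -> D R^T D, D = diag(1,1,-1)."""
    return _D @ np.swapaxes(np.asarray(rot, dtype=float), -1, -2) @ _D


def stokes_from_jones(e: np.ndarray) -> np.ndarray:
    """Detected Stokes parameters (I, Q, U, V) of Jones fields ``(..., 2)``."""
    e = np.asarray(e, dtype=complex)
    ex, ey = e[..., 0], e[..., 1]
    i = np.abs(ex) ** 2 + np.abs(ey) ** 2
    q = np.abs(ex) ** 2 - np.abs(ey) ** 2
    cross = np.conj(ex) * ey
    return np.stack([i, q, 2 * np.real(cross), 2 * np.imag(cross)], axis=-1)
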