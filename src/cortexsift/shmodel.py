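"""Real symmetric spherical-harmonic basis, least-squares fitting, rotation.

The basis is the real, antipodally symmetric ("descoteaux-style") one used
throughout HARDI modelling: only even orders l appear, and for each l the
m-index runs -l..l with sin-type terms for m < 0, the zonal harmonic at
m = 0 and cos-type terms for m > 0.  Order 6 gives
(6+1)(6+2)/2 = 28 coefficients.

Rotation of a coefficient set is performed by evaluating the band-limited
function on a fixed quadrature set rotated by the inverse rotation and
refitting, which is exact for band-limited functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .gradients import GradientScheme, generate_even_directions

__all__ = [
    "SHCoefficients",
    "n_coeffs",
    "sh_index_list",
    "sh_basis",
    "fit_sh",
    "rotate_coeffs",
    "rotation_matrix_to_normal",
    "per_order_power",
]

DEFAULT_ORDER = 6
_QUAD_N = 64  # quadrature directions used for rotate-and-refit
_QUAD_SEED = 42


def n_coeffs(order: int) -> int:
    """Number of real even-order SH coefficients up to ``order``."""
    if order < 0 or order % 2:
        raise ValueError("SH order must be even and non-negative")
    return (order + 1) * (order + 2) // 2


def sh_index_list(order: int) -> list[tuple[int, int]]:
    """(l, m) pairs in basis order: l in 0,2,...,order; m = -l..l."""
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def _cart_to_sph(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(u[:, 1], u[:, 0])  # azimuth
    return theta, phi


def sh_basis(directions: np.ndarray, order: int = DEFAULT_ORDER) -> np.ndarray:
    """Design matrix of the real symmetric SH basis at the given directions.

    Returns an (n_directions, n_coeffs) matrix; antipodally symmetric since
    only even l enter.
    """
    nc = n_coeffs(order)
    theta, phi = _cart_to_sph(directions)
    B = np.empty((theta.size, nc))
    j = 0
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                B[:, j] = y.real
            else:
                B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
            j += 1
    return B


@dataclass
class SHCoefficients:
    """Real even-order SH coefficients of a normalized diffusion signal."""

    coeffs: np.ndarray
    order: int = DEFAULT_ORDER
    shell_b: float | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        if self.coeffs.size != n_coeffs(self.order):
            raise ValueError(
                f"expected {n_coeffs(self.order)} coefficients for order "
                f"{self.order}, got {self.coeffs.size}"
            )

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        return sh_basis(directions, self.order) @ self.coeffs


def _laplace_beltrami(order: int) -> np.ndarray:
    """diag(l(l+1)) smoothness penalty in basis order."""
    return np.array([l * (l + 1) for l, _ in sh_index_list(order)], dtype=float)


def _resolve_directions(scheme) -> tuple[np.ndarray, float | None]:
    if isinstance(scheme, GradientScheme):
        dwi = ~scheme.b0_mask
        sids = np.unique(scheme.shell_ids[dwi])
        if sids.size != 1:
            raise ValueError(
                "fit_sh needs a single-shell scheme; select one shell first"
            )
        return scheme.directions[dwi], scheme.shells[int(sids[0])]
    return np.atleast_2d(np.asarray(scheme, dtype=float)), None


def fit_sh(
    signal: np.ndarray,
    scheme,
    order: int = DEFAULT_ORDER,
    regularization: float = 0.0,
) -> SHCoefficients:
    """Least-squares SH fit of a normalized single-shell signal.

    Minimizes ``|B c - s|^2 + lambda |L c|^2`` with the Laplace-Beltrami
    penalty ``L = diag(l(l+1))``.  ``scheme`` is either a single-shell
    :class:`GradientScheme` (its DWI directions are used) or an (n, 3)
    direction array.  With ``regularization=0`` the system must be
    over-determined.
    """
    dirs, shell_b = _resolve_directions(scheme)
    s = np.asarray(signal, dtype=float).ravel()
    if s.size != len(dirs):
        raise ValueError(f"{s.size} samples but {len(dirs)} directions")
    nc = n_coeffs(order)
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if regularization == 0 and s.size < nc:
        raise np.linalg.LinAlgError(
            f"under-determined fit: {s.size} samples < {nc} coefficients; "
            "use regularization > 0"
        )
    B = sh_basis(dirs, order)
    if regularization == 0:
        c, *_ = np.linalg.lstsq(B, s, rcond=None)
    else:
        L2 = np.diag(_laplace_beltrami(order) ** 2)
        c = np.linalg.solve(B.T @ B + regularization * L2, B.T @ s)
    return SHCoefficients(c, order=order, shell_b=shell_b)


def fit_sh_many(
    signals: np.ndarray,
    scheme,
    order: int = DEFAULT_ORDER,
    regularization: float = 0.0,
) -> np.ndarray:
    """Vectorized fit: (n_samples, n_dirs) signals -> (n_samples, n_coeffs)."""
    dirs, _ = _resolve_directions(scheme)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    if S.shape[1] != len(dirs):
        raise ValueError("signal/direction count mismatch")
    B = sh_basis(dirs, order)
    nc = B.shape[1]
    if regularization == 0:
        if S.shape[1] < nc:
            raise np.linalg.LinAlgError("under-determined fit")
        sol = np.linalg.pinv(B)
    else:
        L2 = np.diag(_laplace_beltrami(order) ** 2)
        sol = np.linalg.solve(B.T @ B + regularization * L2, B.T)
    return S @ sol.T


@lru_cache(maxsize=8)
def _quadrature(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed quadrature directions and pseudo-inverse basis for refitting."""
    q = generate_even_directions(_QUAD_N, seed=_QUAD_SEED)
    B = sh_basis(q, order)
    return q, np.linalg.pinv(B)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("matrix is not a proper rotation")
    return R


def rotation_design_matrix(R: np.ndarray, order: int = DEFAULT_ORDER) -> np.ndarray:
    """Matrix M with (M c) the coefficients of ``f o R^{-1}``."""
    R = _check_rotation(R)
    q, pinvB = _quadrature(order)
    B_rot = sh_basis(q @ R, order)  # evaluates basis at R^{-1} q (row-vector form)
    return pinvB @ B_rot


def rotate_coeffs(coeffs: SHCoefficients, R: np.ndarray) -> SHCoefficients:
    """Rotate a band-limited spherical function: returns coeffs of f o R^{-1}.

    Implemented by evaluating the function on a fixed quadrature set rotated
    by R^{-1} and refitting; exact for band-limited input.
    """
    M = rotation_design_matrix(R, coeffs.order)
    return SHCoefficients(M @ coeffs.coeffs, order=coeffs.order, shell_b=coeffs.shell_b)


def rotation_matrix_to_normal(normal: np.ndarray) -> np.ndarray:
    """Proper rotation R with R @ normal = +z.

    Rotates about ``normal x z`` by the angle between them; when the normal is
    (anti-)parallel to z the identity (or a pi flip about x) is returned.
    """
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if not np.isclose(nn, 1.0, atol=1e-6):
        raise ValueError("normal must be unit length")
    n = n / nn
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    c = float(n @ z)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # pi rotation about x
    axis = axis / s
    angle = np.arctan2(s, c)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def per_order_power(coeffs: SHCoefficients) -> dict[int, float]:
    """sqrt(sum_m c_lm^2) per order l — the rotation-invariant power."""
    out = {}
    idx = sh_index_list(coeffs.order)
    for l in range(0, coeffs.order + 1, 2):
        mask = [i for i, (ll, _) in enumerate(idx) if ll == l]
        out[l] = float(np.sqrt(np.sum(coeffs.coeffs[mask] ** 2)))
    return out
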