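"""Rotational-invariant feature vectors and per-vertex correlation maps.

Each b-shell's order-6 SH coefficient set is reduced to 9 scalars per vertex:

* ``p_0, p_2, p_4, p_6`` — per-order power ``sqrt(sum_m c_lm^2)``, invariant
  under any 3D rotation of the diffusion profile;
* ``c'_20, c'_40, c'_60`` — the m = 0 (zonal) coefficients after rotating the
  profile so the local cortical surface normal points along +z;
* ``t_2, t_4`` — transverse power ``sqrt(sum_{m != 0} c'_lm^2)`` in that
  normal-aligned frame.

The last five are invariant under rotations about the surface normal, the
natural reference axis of cortical microstructure.  Feature vectors from
several acquisitions are concatenated (9, 18 or 27 values per vertex), and a
per-vertex Pearson correlation between two acquisitions' 9-vectors serves as
a repeatability / information-overlap map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shmodel import (
    SHCoefficients,
    per_order_power,
    rotation_design_matrix,
    rotation_matrix_to_normal,
    sh_index_list,
)

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "invariants",
    "invariants_many",
    "concat_features",
    "correlation_map",
]

FEATURE_NAMES = ("p0", "p2", "p4", "p6", "cz2", "cz4", "cz6", "t2", "t4")
N_FEATURES = 9


@dataclass
class FeatureVector:
    """Per-vertex features concatenated across acquisitions."""

    values: np.ndarray
    acquisition_tags: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size % N_FEATURES:
            raise ValueError(f"feature length {self.values.size} not a multiple of {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    @property
    def n_acquisitions(self) -> int:
        return self.values.size // N_FEATURES


def _zonal_and_transverse(coeffs: np.ndarray, order: int) -> tuple[dict, dict]:
    idx = sh_index_list(order)
    zonal = {}
    transverse = {}
    for l in range(2, order + 1, 2):
        z = [i for i, (ll, m) in enumerate(idx) if ll == l and m == 0]
        t = [i for i, (ll, m) in enumerate(idx) if ll == l and m != 0]
        zonal[l] = float(coeffs[z[0]])
        transverse[l] = float(np.sqrt(np.sum(coeffs[t] ** 2)))
    return zonal, transverse


def invariants(coeffs: SHCoefficients, normal: np.ndarray) -> np.ndarray:
    """The 9 rotational-invariant features for one vertex and one shell."""
    n = np.asarray(normal, dtype=float)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
        raise ValueError("normal must be a unit vector")
    power = per_order_power(coeffs)
    Rn = rotation_matrix_to_normal(n)
    M = rotation_design_matrix(Rn, coeffs.order)
    c_aligned = M @ coeffs.coeffs
    zonal, trans = _zonal_and_transverse(c_aligned, coeffs.order)
    return np.array(
        [
            power[0],
            power[2],
            power[4],
            power[6],
            zonal[2],
            zonal[4],
            zonal[6],
            trans[2],
            trans[4],
        ]
    )


def invariants_many(
    coeff_table: np.ndarray, normals: np.ndarray, order: int = 6
) -> np.ndarray:
    """Vectorized invariants: (n_vertices, n_coeffs) -> (n_vertices, 9).

    The alignment rotation depends on the vertex normal, so the rotation
    design matrix is built per vertex; the per-order powers are batched.
    """
    C = np.atleast_2d(np.asarray(coeff_table, dtype=float))
    N = np.atleast_2d(np.asarray(normals, dtype=float))
    if len(C) != len(N):
        raise ValueError("coefficient/normal count mismatch")
    idx = sh_index_list(order)
    out = np.empty((len(C), N_FEATURES))
    order_masks = {
        l: np.array([i for i, (ll, _) in enumerate(idx) if ll == l])
        for l in range(0, order + 1, 2)
    }
    for l, col in zip((0, 2, 4, 6), range(4)):
        out[:, col] = np.sqrt((C[:, order_masks[l]] ** 2).sum(axis=1))
    zon = {l: [i for i, (ll, m) in enumerate(idx) if ll == l and m == 0][0] for l in (2, 4, 6)}
    trans = {l: [i for i, (ll, m) in enumerate(idx) if ll == l and m != 0] for l in (2, 4)}
    for v in range(len(C)):
        M = rotation_design_matrix(rotation_matrix_to_normal(N[v]), order)
        ca = M @ C[v]
        out[v, 4] = ca[zon[2]]
        out[v, 5] = ca[zon[4]]
        out[v, 6] = ca[zon[6]]
        out[v, 7] = np.sqrt(np.sum(ca[trans[2]] ** 2))
        out[v, 8] = np.sqrt(np.sum(ca[trans[4]] ** 2))
    return out


def concat_features(per_acquisition: list[np.ndarray], tags=None) -> FeatureVector:
    """Concatenate 9-feature vectors across acquisitions (length 9/18/27)."""
    if not per_acquisition:
        raise ValueError("need at least one acquisition")
    arrs = [np.asarray(a, dtype=float).ravel() for a in per_acquisition]
    for a in arrs:
        if a.size != N_FEATURES:
            raise ValueError(f"each acquisition must contribute {N_FEATURES} features")
    return FeatureVector(np.concatenate(arrs), acquisition_tags=list(tags or []))


def correlation_map(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-vertex Pearson correlation between two acquisitions' features.

    ``A`` and ``B`` are (n_vertices, 9) tables over the same vertex set.
    Vertices where either vector is constant (zero variance) get NaN — they
    are flagged, never silently zero, and excluded from map summaries.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=1) / (na * nb)
    r[(na < 1e-300) | (nb < 1e-300)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)
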