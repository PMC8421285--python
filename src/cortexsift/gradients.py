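"""Gradient tables, even direction sets and electrostatic-repulsion splitting.

Diffusion gradient directions are axial (a DWI measured along ``u`` equals the
one measured along ``-u``), so every energy here uses the antipodally
symmetrized Coulomb objective

    E = sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|

which is the conventional criterion for evenly covering the half-sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "read_gradient_table",
    "write_gradient_table",
    "generate_even_directions",
    "coulomb_energy",
    "partition_energy",
    "split_electrostatic",
]

B0_THRESHOLD = 50.0  # s/mm^2, below which a volume counts as b=0
SHELL_TOL = 50.0  # s/mm^2, clustering tolerance when inferring shells


class GradientTableError(ValueError):
    """Malformed bval/bvec input."""


@dataclass
class GradientScheme:
    """B-values plus unit directions defining one or more shells.

    Attributes
    ----------
    directions : (n, 3) float array
        Unit direction per volume (b0 volumes keep whatever vector was given,
        conventionally zero -> stored as +z placeholder, masked out anyway).
    bvalues : (n,) float array
        Diffusion weighting per volume in s/mm^2.
    shell_ids : (n,) int array
        Shell assignment; -1 for b0 volumes.
    b0_mask : (n,) bool array
        True where bvalue < the b0 threshold.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    shell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    b0_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if self.directions.shape != (self.bvalues.size, 3):
            raise GradientTableError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvalues.size} b-values"
            )
        if np.any(self.bvalues < 0):
            raise GradientTableError("negative b-value")
        if self.b0_mask is None:
            self.b0_mask = self.bvalues < B0_THRESHOLD
        # normalize DWI directions; b0 rows get a +z placeholder
        dirs = self.directions.copy()
        norms = np.linalg.norm(dirs, axis=1)
        dwi = ~self.b0_mask
        bad = dwi & (norms < 1e-12)
        if np.any(bad):
            raise GradientTableError("zero direction vector on a diffusion-weighted volume")
        dirs[dwi] /= norms[dwi, None]
        dirs[self.b0_mask] = (0.0, 0.0, 1.0)
        self.directions = dirs
        if self.shell_ids is None:
            self.shell_ids = _infer_shells(self.bvalues, self.b0_mask)
        self.shell_ids = np.asarray(self.shell_ids, dtype=int).ravel()

    @property
    def n_volumes(self) -> int:
        return self.bvalues.size

    @property
    def shells(self) -> dict[int, float]:
        """Mapping shell id -> nominal (mean) b-value, b0 excluded."""
        out = {}
        for sid in np.unique(self.shell_ids):
            if sid < 0:
                continue
            out[int(sid)] = float(self.bvalues[self.shell_ids == sid].mean())
        return out

    def shell_indices(self, shell_id: int) -> np.ndarray:
        return np.flatnonzero(self.shell_ids == shell_id)


def _infer_shells(bvalues: np.ndarray, b0_mask: np.ndarray) -> np.ndarray:
    """Cluster non-b0 b-values into shells within +/- SHELL_TOL."""
    shell_ids = np.full(bvalues.size, -1, dtype=int)
    centers: list[float] = []
    for i in np.argsort(bvalues):
        if b0_mask[i]:
            continue
        b = bvalues[i]
        for sid, c in enumerate(centers):
            if abs(b - c) <= SHELL_TOL:
                shell_ids[i] = sid
                break
        else:
            centers.append(b)
            shell_ids[i] = len(centers) - 1
    return shell_ids


def _parse_numeric(path: Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GradientTableError(f"non-numeric token in {path}: {exc}") from exc
    if not rows:
        raise GradientTableError(f"empty gradient file {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GradientTableError(f"ragged rows in {path}")
    return np.array(rows, dtype=float)


def read_gradient_table(
    bval_path: str | Path,
    bvec_path: str | Path,
    orientation: str = "auto",
) -> GradientScheme:
    """Read FSL-style bval/bvec text files.

    ``bvec`` may be 3 x N (FSL convention) or N x 3; the shape decides unless
    it is 3 x 3, in which case ``orientation`` must be ``"rows"`` (3 x N) or
    ``"columns"`` (N x 3).
    """
    bvals = _parse_numeric(Path(bval_path)).ravel()
    bvecs = _parse_numeric(Path(bvec_path))
    if bvecs.ndim == 1:
        bvecs = bvecs[None, :]
    if bvecs.shape == (3, 3) and orientation == "auto":
        raise GradientTableError(
            "ambiguous 3x3 bvec: pass orientation='rows' or 'columns'"
        )
    if orientation == "rows" or (orientation == "auto" and bvecs.shape[0] == 3):
        bvecs = bvecs.T
    elif orientation not in ("auto", "columns"):
        raise GradientTableError(f"unknown orientation {orientation!r}")
    if bvecs.shape[1] != 3:
        raise GradientTableError(f"bvec is not 3xN or Nx3: shape {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise GradientTableError(
            f"{bvals.size} b-values but {bvecs.shape[0]} direction vectors"
        )
    return GradientScheme(directions=bvecs, bvalues=bvals)


def write_gradient_table(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL bval (one row) and bvec (three rows) files."""
    dirs = scheme.directions.copy()
    dirs[scheme.b0_mask] = 0.0
    Path(bval_path).write_text(
        " ".join(f"{b:.6g}" for b in scheme.bvalues) + "\n"
    )
    lines = [" ".join(f"{v:.8f}" for v in dirs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Electrostatic repulsion
# ---------------------------------------------------------------------------

def _antipodal_potentials(directions: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Pairwise antipodal Coulomb potential matrix, zero diagonal."""
    u = np.asarray(directions, dtype=float)
    d_minus = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
    d_plus = np.linalg.norm(u[:, None, :] + u[None, :, :], axis=-1)
    n = len(u)
    pot = 1.0 / np.maximum(d_minus, eps) + 1.0 / np.maximum(d_plus, eps)
    pot[np.arange(n), np.arange(n)] = 0.0
    return pot


def coulomb_energy(directions: np.ndarray) -> float:
    """Antipodally symmetrized Coulomb energy of a direction set."""
    u = np.atleast_2d(directions)
    if len(u) < 2:
        return 0.0
    return float(_antipodal_potentials(u).sum() / 2.0)


def _energy_gradient(u: np.ndarray) -> np.ndarray:
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    d_m = np.linalg.norm(diff, axis=-1)
    d_p = np.linalg.norm(summ, axis=-1)
    n = len(u)
    idx = np.arange(n)
    d_m[idx, idx] = np.inf
    d_p[idx, idx] = np.inf
    grad = -(diff / d_m[..., None] ** 3).sum(axis=1) - (summ / d_p[..., None] ** 3).sum(axis=1)
    return grad


def generate_even_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """Evenly spaced axial directions by projected-gradient repulsion descent.

    Starts from a seeded random configuration and descends the antipodal
    Coulomb energy on the product of spheres with a backtracking step size.
    Deterministic per ``(n, seed)``.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if n == 1:
        return u
    lr = 0.1
    e = coulomb_energy(u)
    for _ in range(n_iter):
        g = _energy_gradient(u)
        # project onto tangent plane of each sphere
        g -= (g * u).sum(axis=1, keepdims=True) * u
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-12:
            break
        step = u - lr * g / max(gnorm, 1e-12)
        step /= np.linalg.norm(step, axis=1, keepdims=True)
        e_new = coulomb_energy(step)
        if e_new < e:
            converged = e - e_new < 1e-12 * max(abs(e), 1.0)
            u, e = step, e_new
            lr *= 1.1
            if converged:
                break
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    return u


def partition_energy(directions: np.ndarray, subsets: list[np.ndarray]) -> float:
    """Sum of intra-subset antipodal Coulomb energies."""
    return float(sum(coulomb_energy(np.asarray(directions)[np.asarray(s)]) for s in subsets))


def split_electrostatic(
    directions: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[np.ndarray]:
    """Split a direction set into ``k`` balanced, evenly covering subsets.

    Seeded random balanced initialization followed by best-improvement
    pairwise swaps across subsets until no swap lowers the summed
    intra-subset antipodal Coulomb energy; ``n_restarts`` restarts, best kept.
    """
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(u)
    if k < 1 or n % k != 0:
        raise ValueError(f"{n} directions not divisible into {k} subsets")
    m = n // k
    pot = _antipodal_potentials(u)
    rng = np.random.default_rng(seed)

    best_assign = None
    best_e = np.inf
    for _ in range(n_restarts):
        assign = np.repeat(np.arange(k), m)
        rng.shuffle(assign)
        # w[i, s] = sum of potentials from i to members of subset s
        onehot = np.eye(k)[assign]
        w = pot @ onehot
        e = 0.5 * (w[np.arange(n), assign]).sum()
        while True:
            # delta(i, j) for swapping i and j across their subsets
            ai = assign[:, None]
            aj = assign[None, :]
            wi_new = w[np.arange(n)[:, None], aj] - pot  # i joins j's subset, j leaves
            wi_old = w[np.arange(n), assign][:, None]
            wj_new = w[np.arange(n)[None, :], ai] - pot  # j joins i's subset, i leaves

            wj_old = w[np.arange(n), assign][None, :]
            delta = (wi_new - wi_old) + (wj_new - wj_old)
            delta[ai == aj] = np.inf
            i, j = np.unravel_index(np.argmin(delta), delta.shape)
            if delta[i, j] >= -1e-12:
                break
            e += delta[i, j]
            si, sj = assign[i], assign[j]
            assign[i], assign[j] = sj, si
            # rank-1 updates of w
            w[:, si] += pot[:, j] - pot[:, i]
            w[:, sj] += pot[:, i] - pot[:, j]
        e = 0.5 * (w[np.arange(n), assign]).sum()
        if e < best_e - 1e-12:
            best_e, best_assign = e, assign.copy()
    return [np.flatnonzero(best_assign == s) for s in range(k)]
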