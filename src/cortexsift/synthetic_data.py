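"""Synthetic cortical patches and multi-shell diffusion signals.

The generator emulates the ingredients of a surface-based HARDI study of
cortical gray matter:

* a folded cortical sheet (``z = a sin(2 pi x / wavelength)``) sampled on a
  vertex grid finer than the DWI voxel grid, with analytic outward normals,
  per-vertex cortical thickness and contiguous ROI label bands;
* per-ROI microstructure as a mixture of axially symmetric diffusion
  tensors whose axes are referenced to the local surface normal ("radial"
  across the cortical ribbon, "tangential" within it) and dispersed with a
  Watson distribution, plus a non-mono-exponential (kurtosis-like)
  b-dependence — so that different b-values genuinely probe different tissue
  properties;
* magnitude (Rician) noise at a configurable b0 SNR.

The benchmark ROI factories produce regions whose direction-averaged signal
is calibrated to be equal at the middle b-value, so repeated mid-b
acquisitions see only the angular contrast while mixed b-values also see
the difference in b-dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gradients import GradientScheme, generate_even_directions, write_gradient_table
from .shmodel import rotation_matrix_to_normal

__all__ = [
    "Compartment",
    "MicrostructureSpec",
    "PatchConfig",
    "SyntheticDataset",
    "make_patch",
    "simulate_signal",
    "make_dataset",
    "write_dataset",
    "benchmark_rois",
    "benchmark_config",
    "spherical_mean_signal",
]


@dataclass(frozen=True)
class Compartment:
    """One axially symmetric tensor compartment.

    ``orientation`` is "radial" (axis along the surface normal),
    "tangential" (axis in the tangent plane, azimuth drawn per vertex) or a
    fixed unit 3-vector.  Eigenvalues are in mm^2/s.
    """

    fraction: float
    lambda_par: float
    lambda_perp: float
    orientation: object = "radial"


@dataclass(frozen=True)
class MicrostructureSpec:
    """Mixture of dispersed tensor compartments with a kurtosis term.

    The noise-free normalized signal is

        S(b, u) / s0 = sum_k f_k exp(-b adc_k(u)) exp((b adc_k(u))^2 K / 6)

    with ``adc_k(u) = u^T D_k u``; compartment axes are drawn per vertex
    from a Watson distribution (concentration ``dispersion_kappa``) about
    the orientation stated in the compartment.
    """

    compartments: tuple[Compartment, ...]
    dispersion_kappa: float = 6.0
    kurtosis_k: float = 0.5
    s0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        fs = sum(c.fraction for c in self.compartments)
        if abs(fs - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions sum to {fs}, not 1")
        for c in self.compartments:
            if c.lambda_par <= 0 or c.lambda_perp <= 0:
                raise ValueError("tensor eigenvalues must be positive")
        if self.kurtosis_k < 0:
            raise ValueError("kurtosis term must be >= 0")

    def scaled(self, s: float) -> "MicrostructureSpec":
        """Uniformly scale all eigenvalues by ``s``."""
        comps = tuple(
            replace(c, lambda_par=c.lambda_par * s, lambda_perp=c.lambda_perp * s)
            for c in self.compartments
        )
        return replace(self, compartments=comps)


@dataclass
class PatchConfig:
    """Geometry, microstructure, acquisition and noise of one dataset."""

    rois: dict  # label -> MicrostructureSpec
    nx: int = 30
    ny: int = 20
    spacing: float = 1.0  # mm between surface vertices
    amplitude: float = 3.0  # mm, folding amplitude
    wavelength: float = 20.0  # mm, folding period
    voxel_size: float = 1.7  # mm isotropic DWI voxel
    thickness_mean: float = 2.5  # mm
    thickness_sd: float = 0.3
    snr: float = 20.0  # b0 SNR; Rician sigma = s0 / snr
    bvalues: tuple = (800.0, 1400.0, 2000.0)  # s/mm^2 shells
    n_repeats_mid: int = 3  # repeats of the middle shell
    acquisition_order: tuple | None = None  # explicit b-value sequence
    n_directions: int = 30
    n_b0: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("degenerate grid")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if len(self.rois) < 1:
            raise ValueError("need at least one ROI")

    @property
    def acquisitions(self) -> list[tuple[float, int]]:
        """(b-value, repeat-index) per acquisition, ascending-b by default."""
        if self.acquisition_order is not None:
            seen: dict[float, int] = {}
            out = []
            for b in self.acquisition_order:
                rep = seen.get(b, 0)
                out.append((float(b), rep))
                seen[b] = rep + 1
            return out
        bs = sorted(self.bvalues)
        mid = bs[len(bs) // 2]
        out = []
        for b in bs:
            reps = self.n_repeats_mid if b == mid else 1
            out.extend((float(b), r) for r in range(reps))
        return out

    @property
    def sigma(self) -> float:
        return 1.0 / self.snr  # s0 is unit-normalized


# ---------------------------------------------------------------------------
# Surface patch
# ---------------------------------------------------------------------------

def make_patch(config: PatchConfig, seed: int | None = None) -> pd.DataFrame:
    """Vertex table of a sinusoidally folded cortical sheet.

    Columns ``x y z nx ny nz thickness label``; normals are analytic unit
    normals of the sheet, thickness is truncated-normal (> 0.5 mm) and ROI
    labels form contiguous bands along x.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    xs = np.arange(config.nx) * config.spacing
    ys = np.arange(config.ny) * config.spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    x = X.ravel()
    y = Y.ravel()
    k = 2.0 * np.pi / config.wavelength
    z = config.amplitude * np.sin(k * x)
    dzdx = config.amplitude * k * np.cos(k * x)
    normals = np.stack([-dzdx, np.zeros_like(x), np.ones_like(x)], axis=1)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    n = x.size
    thick = rng.normal(config.thickness_mean, config.thickness_sd, size=n)
    while np.any(thick <= 0.5):
        bad = thick <= 0.5
        thick[bad] = rng.normal(config.thickness_mean, config.thickness_sd, size=bad.sum())

    labels = list(config.rois)
    band = np.floor(
        np.repeat(np.arange(config.nx), config.ny) * len(labels) / config.nx
    ).astype(int)
    lab = np.array(labels, dtype=object)[band]

    return pd.DataFrame(
        {
            "vertex_id": np.arange(n),
            "x": x,
            "y": y,
            "z": z,
            "nx": normals[:, 0],
            "ny": normals[:, 1],
            "nz": normals[:, 2],
            "thickness": thick,
            "label": lab,
        }
    )


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def _watson_cos(kappa: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample cos(theta) from the bipolar Watson density ~ exp(kappa t^2)."""
    if np.isinf(kappa):
        return np.where(rng.random(size) < 0.5, -1.0, 1.0)
    t = np.linspace(-1.0, 1.0, 4097)
    pdf = np.exp(kappa * (t**2 - 1.0))  # scaled to avoid overflow
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(t))])
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, t)


def _watson_axes(mean_axis: np.ndarray, kappa: float, size: int, rng) -> np.ndarray:
    """Draw ``size`` axes Watson-dispersed about ``mean_axis``."""
    t = _watson_cos(kappa, size, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    s = np.sqrt(np.maximum(0.0, 1.0 - t**2))
    v = np.stack([s * np.cos(phi), s * np.sin(phi), t], axis=1)
    R = rotation_matrix_to_normal(mean_axis)  # maps mean_axis -> z
    return v @ R  # = R^T v, maps z -> mean_axis


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def _compartment_axes(
    spec: MicrostructureSpec, normal: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """One dispersed axis per compartment for one vertex."""
    axes = []
    for comp in spec.compartments:
        if isinstance(comp.orientation, str):
            if comp.orientation == "radial":
                mean = normal
            elif comp.orientation == "tangential":
                t1, t2 = _tangent_basis(normal)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                mean = np.cos(phi) * t1 + np.sin(phi) * t2
            else:
                raise ValueError(f"unknown orientation {comp.orientation!r}")
        else:
            mean = np.asarray(comp.orientation, dtype=float)
            mean = mean / np.linalg.norm(mean)
        axes.append(_watson_axes(mean, spec.dispersion_kappa, 1, rng)[0])
    return axes


def noise_free_signal(
    spec: MicrostructureSpec,
    axes: list[np.ndarray],
    bvalues: np.ndarray,
    directions: np.ndarray,
) -> np.ndarray:
    """Multi-compartment kurtosis signal given fixed compartment axes."""
    b = np.asarray(bvalues, dtype=float)
    u = np.atleast_2d(directions)
    S = np.zeros(b.size)
    for comp, d in zip(spec.compartments, axes):
        adc = comp.lambda_perp + (comp.lambda_par - comp.lambda_perp) * (u @ d) ** 2
        badc = b * adc
        S += comp.fraction * np.exp(-badc + badc**2 * spec.kurtosis_k / 6.0)
    return spec.s0 * S


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MR noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma)."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    e1 = rng.normal(0.0, sigma, np.shape(signal))
    e2 = rng.normal(0.0, sigma, np.shape(signal))
    return np.sqrt((signal + e1) ** 2 + e2**2)


def simulate_signal(
    spec: MicrostructureSpec,
    normal: np.ndarray,
    scheme: GradientScheme,
    sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-volume amplitudes for one vertex (axes and noise drawn from seed)."""
    if scheme.n_volumes == 0:
        raise ValueError("empty gradient scheme")
    if sigma < 0:
        raise ValueError("noise level must be >= 0")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rng = np.random.default_rng(seed)
    axes = _compartment_axes(spec, n, rng)
    S = noise_free_signal(spec, axes, scheme.bvalues, scheme.directions)
    return add_rician_noise(S, sigma, rng)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_CAL_DIRS = None


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform direction set (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    t = 1.0 - 2.0 * i / n
    s = np.sqrt(1.0 - t**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), t], axis=1)


def spherical_mean_signal(spec: MicrostructureSpec, b: float) -> float:
    """Direction-averaged noise-free signal at b (dispersion-independent)."""
    global _CAL_DIRS
    if _CAL_DIRS is None:
        _CAL_DIRS = _fibonacci_sphere(512)
    axes = []
    for comp in spec.compartments:
        axes.append(np.array([0.0, 0.0, 1.0]))  # spherical mean is axis-free
    S = noise_free_signal(spec, axes, np.full(len(_CAL_DIRS), b), _CAL_DIRS)
    return float(S.mean())


def match_mean_signal(
    spec: MicrostructureSpec, target: float, b: float
) -> MicrostructureSpec:
    """Scale eigenvalues so the direction-averaged signal at ``b`` hits target."""

    def f(s):
        return spherical_mean_signal(spec.scaled(s), b) - target

    # the mean signal is not monotone in the scale (the kurtosis term grows
    # quadratically), so bracket a sign change on a log grid first
    grid = np.logspace(-1.5, 1.0, 120)
    vals = np.array([f(s) for s in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        raise ValueError("cannot match the target mean signal by eigenvalue scaling")
    i = sign_change[0]
    s = brentq(f, grid[i], grid[i + 1], xtol=1e-12)
    return spec.scaled(s)


# ---------------------------------------------------------------------------
# Benchmark ROI families
# ---------------------------------------------------------------------------

def _roi_spec(radial_fraction: float, kurtosis_k: float, kappa: float = 6.0) -> MicrostructureSpec:
    return MicrostructureSpec(
        compartments=(
            Compartment(radial_fraction, 1.2e-3, 0.5e-3, "radial"),
            Compartment(1.0 - radial_fraction, 1.2e-3, 0.5e-3, "tangential"),
        ),
        dispersion_kappa=kappa,
        kurtosis_k=kurtosis_k,
    )


def benchmark_rois(n_rois: int = 2, mid_b: float = 1400.0) -> dict:
    """ROIs differing in radial-vs-tangential fraction and kurtosis.

    All ROIs are calibrated to the same direction-averaged signal at the
    middle b-value, so a single shell at mid-b sees only the angular
    contrast while the b-dependence contrast needs multiple b-values.
    """
    # (radial fraction, kurtosis) pairs spanning plausible cortical contrast
    params = [
        (0.50, 0.40),
        (0.65, 1.00),
        (0.40, 0.70),
        (0.60, 0.25),
        (0.45, 1.10),
        (0.70, 0.55),
        (0.35, 0.90),
        (0.55, 1.30),
    ]
    if not 2 <= n_rois <= len(params):
        raise ValueError(f"n_rois must be in [2, {len(params)}]")
    specs = {}
    ref = _roi_spec(*params[0])
    target = spherical_mean_signal(ref, mid_b)
    for i in range(n_rois):
        name = f"roi{i}"
        spec = _roi_spec(*params[i])
        specs[name] = match_mean_signal(spec, target, mid_b) if i else ref
    return specs


def benchmark_config(
    n_rois: int = 2,
    vertices_per_roi: int = 300,
    seed: int = 0,
    snr: float = 20.0,
    bvalues: tuple = (800.0, 1400.0, 2000.0),
    n_directions: int = 30,
) -> PatchConfig:
    """The standard synthetic benchmark configuration."""
    ny = 10 if vertices_per_roi % 20 else 20
    nx, rem = divmod(n_rois * vertices_per_roi, ny)
    if rem:
        raise ValueError("vertices_per_roi must be a multiple of 10")
    return PatchConfig(
        rois=benchmark_rois(n_rois, mid_b=sorted(bvalues)[len(bvalues) // 2]),
        nx=nx,
        ny=ny,
        snr=snr,
        bvalues=tuple(float(b) for b in bvalues),
        n_directions=n_directions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Pipeline-ready bundle: surface, per-acquisition schemes and signals."""

    config: PatchConfig
    surface: pd.DataFrame
    schemes: dict  # (b, repeat) -> GradientScheme
    signals: dict  # (b, repeat) -> (n_vertices, n_volumes) raw amplitudes
    manifest: dict

    @property
    def acquisitions(self) -> list[tuple[float, int]]:
        return list(self.signals)

    @property
    def labels(self) -> np.ndarray:
        return self.surface["label"].to_numpy()

    @property
    def normals(self) -> np.ndarray:
        return self.surface[["nx", "ny", "nz"]].to_numpy()


def _acquisition_scheme(config: PatchConfig, b: float, directions: np.ndarray) -> GradientScheme:
    nb0, nd = config.n_b0, config.n_directions
    bvals = np.concatenate([np.zeros(nb0), np.full(nd, b)])
    dirs = np.concatenate([np.tile([0.0, 0.0, 1.0], (nb0, 1)), directions])
    return GradientScheme(directions=dirs, bvalues=bvals)


def make_dataset(config: PatchConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset, deterministic per master seed.

    Per-vertex microstructure axes are drawn once (the tissue is the same in
    every acquisition); each acquisition then gets independent Rician noise.
    The repeated acquisitions share their diffusion direction set, matching
    the repeated-shell protocol the generator emulates.
    """
    seed = config.seed if seed is None else seed
    surface = make_patch(config, seed=seed)
    directions = generate_even_directions(config.n_directions, seed=seed % (2**31))
    normals = surface[["nx", "ny", "nz"]].to_numpy()
    labels = surface["label"].to_numpy()
    n_vert = len(surface)

    # one axis draw per vertex, shared by all acquisitions
    axes_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    vertex_axes = [
        _compartment_axes(config.rois[labels[v]], normals[v], axes_rng)
        for v in range(n_vert)
    ]

    schemes: dict = {}
    signals: dict = {}
    for a_idx, (b, rep) in enumerate(config.acquisitions):
        scheme = _acquisition_scheme(config, b, directions)
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 303, a_idx]))
        S = np.empty((n_vert, scheme.n_volumes))
        for v in range(n_vert):
            clean = noise_free_signal(
                config.rois[labels[v]], vertex_axes[v], scheme.bvalues, scheme.directions
            )
            S[v] = add_rician_noise(clean, config.sigma, noise_rng)
        schemes[(b, rep)] = scheme
        signals[(b, rep)] = S

    manifest = {
        "seed": int(seed),
        "acquisitions": [[float(b), int(r)] for b, r in config.acquisitions],
        "n_vertices": int(n_vert),
        "rois": {lab: asdict(spec) for lab, spec in config.rois.items()},
        "snr": float(config.snr),
        "n_directions": int(config.n_directions),
        "n_b0": int(config.n_b0),
        "voxel_size": float(config.voxel_size),
        "grid": [int(config.nx), int(config.ny)],
    }
    return SyntheticDataset(
        config=config, surface=surface, schemes=schemes, signals=signals, manifest=manifest
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path, volumetric: bool = False) -> dict:
    """Write bval/bvec, signal tables (or NIfTI volumes), surface and manifest.

    Returns the file map.  In volumetric mode each acquisition becomes a 4D
    NIfTI on a voxel grid enclosing the patch; the voxel containing each
    vertex's mid-thickness point holds that group's representative signal,
    so the volume round-trips through the surface-sampling stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    ds.surface.to_csv(outdir / "surface.tsv", sep="\t", index=False)
    files["surface"] = "surface.tsv"
    for (b, rep), scheme in ds.schemes.items():
        stem = f"acq_b{int(b)}_r{rep}"
        write_gradient_table(scheme, outdir / f"{stem}.bval", outdir / f"{stem}.bvec")
        if volumetric:
            import nibabel as nib

            img = _to_volume(ds, (b, rep))
            nib.save(img, outdir / f"{stem}.nii")
            files[stem] = f"{stem}.nii"
        else:
            np.savetxt(outdir / f"{stem}.tsv", ds.signals[(b, rep)], delimiter="\t")
            files[stem] = f"{stem}.tsv"
    (outdir / "manifest.json").write_text(json.dumps(ds.manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = "manifest.json"
    return files


def _to_volume(ds: SyntheticDataset, acq: tuple[float, int]):
    """Rasterize one acquisition's per-vertex signals into a 4D NIfTI."""
    import nibabel as nib

    cfg = ds.config
    surf = ds.surface
    pos = surf[["x", "y", "z"]].to_numpy()
    nrm = surf[["nx", "ny", "nz"]].to_numpy()
    thick = surf["thickness"].to_numpy()
    pts = pos + 0.5 * thick[:, None] * nrm
    margin = 2.0 * cfg.voxel_size
    origin = pts.min(axis=0) - margin
    extent = pts.max(axis=0) + margin - origin
    shape = np.ceil(extent / cfg.voxel_size).astype(int) + 1
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    affine[:3, 3] = origin
    # the NIfTI header stores the affine in float32; rasterize with the
    # rounded values the reader will see, so voxel lookups round-trip
    affine = np.float32(affine).astype(float)
    origin = affine[:3, 3]
    voxel = affine[0, 0]

    sig = ds.signals[acq]
    data = np.zeros((*shape, sig.shape[1]))
    ijk = np.floor((pts - origin) / voxel).astype(int)
    # per voxel, store the signal of the vertex nearest the group centroid
    # (the same representative the dedup stage keeps)
    df = pd.DataFrame({"i": ijk[:, 0], "j": ijk[:, 1], "k": ijk[:, 2]})
    for (i, j, k), grp in df.groupby(["i", "j", "k"], sort=False):
        rows = grp.index.to_numpy()
        centroid = pos[rows].mean(axis=0)
        d = np.linalg.norm(pos[rows] - centroid, axis=1)
        keep = rows[np.lexsort((rows, d))[0]]
        data[i, j, k, :] = sig[keep]
    return nib.Nifti1Image(data, affine)
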