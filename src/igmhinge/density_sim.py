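"""Pseudo-atom density rendering and rigid pivot-ensemble simulation.

A reconstructed density map of a flexible domain is, to first order, the
density of the rigid body blurred by the distribution of its orientations.
This module renders atomic models into voxel grids (one isotropic Gaussian of
unit integral per atom) and averages renders over a grid of in-plane /
out-of-plane pivot angles about a :class:`~igmhinge.model_geometry.PivotFrame`
to produce that motion-blurred "probability cloud".

Maps are stored with isotropic voxels, values indexed ``[ix, iy, iz]``, and a
real-space origin at the center of voxel (0, 0, 0); MRC/CCP4 I/O goes through
gemmi (mode-2 float, origin in the MRC2014 header origin words).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, GridBoundsError, GridMismatchError
from .model_geometry import AtomicModel, DomainSelection, PivotFrame

DEFAULT_ATOM_SIGMA = 2.0  # Angstrom
DEFAULT_VOXEL_SIZE = 2.0  # Angstrom


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid: origin (A), shape (nx, ny, nz), voxel (A)."""

    origin: tuple
    shape: tuple
    voxel_size: float

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ConfigError("voxel size must be positive")

    @classmethod
    def cube_around(cls, center, half_extent: float,
                    voxel_size: float = DEFAULT_VOXEL_SIZE) -> "GridSpec":
        n = int(np.ceil(2 * half_extent / voxel_size)) + 1
        center = np.asarray(center, float)
        origin = center - voxel_size * (n - 1) / 2.0
        return cls(tuple(origin), (n, n, n), voxel_size)

    @classmethod
    def around_model(cls, model: AtomicModel, margin: float = 10.0,
                     voxel_size: float = DEFAULT_VOXEL_SIZE) -> "GridSpec":
        lo = model.coords.min(axis=0) - margin
        hi = model.coords.max(axis=0) + margin
        shape = tuple(int(np.ceil(d / voxel_size)) + 1 for d in (hi - lo))
        return cls(tuple(lo), shape, voxel_size)


@dataclass
class DensityMap:
    """A scalar voxel grid with isotropic spacing.

    ``values[ix, iy, iz]`` sits at ``origin + voxel_size * (ix, iy, iz)``.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray
    axis_order: str = "xyz"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.origin = np.asarray(self.origin, float)
        if self.voxel_size <= 0:
            raise ConfigError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("map contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def integral(self) -> float:
        """Integral of the density over the volume (value * A^3)."""
        return float(self.values.sum()) * self.voxel_size ** 3

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size, self.origin.copy(),
                          self.axis_order)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.voxel_size

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.voxel_size - other.voxel_size) < tol
                and bool(np.all(np.abs(self.origin - other.origin) < tol)))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_into(values: np.ndarray, grid: GridSpec, coords: np.ndarray,
                 sigma: float, weight: float = 1.0) -> None:
    """Accumulate unit-integral Gaussians into ``values`` (separable kernels)."""
    vox = grid.voxel_size
    origin = np.asarray(grid.origin, float)
    half = int(np.ceil(5.0 * sigma / vox))  # 5 sigma: truncation ~1e-6
    amp = weight * vox ** 3 / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    shape = values.shape
    vc = (coords - origin) / vox
    for p in vc:
        idx = np.round(p).astype(int)
        g1d = []
        slices = []
        for ax in range(3):
            lo = max(idx[ax] - half, 0)
            hi = min(idx[ax] + half + 1, shape[ax])
            x = np.arange(lo, hi, dtype=float)
            g1d.append(np.exp(-0.5 * ((x - p[ax]) * vox / sigma) ** 2))
            slices.append(slice(lo, hi))
        values[tuple(slices)] += amp * np.einsum("i,j,k->ijk", *g1d)


def render_density(model: AtomicModel, grid: GridSpec,
                   atom_sigma: float = DEFAULT_ATOM_SIGMA) -> DensityMap:
    """Render a model as a sum of isotropic 3-D Gaussians of unit integral.

    Requires the grid to enclose every atom with at least a 3*sigma margin so
    that the numerical integral per atom is ~1.
    """
    if atom_sigma <= 0:
        raise ConfigError("atom_sigma must be positive")
    origin = np.asarray(grid.origin, float)
    top = origin + grid.voxel_size * (np.asarray(grid.shape) - 1)
    margin = 3.0 * atom_sigma
    outside = ((model.coords < origin + margin - 1e-9)
               | (model.coords > top - margin + 1e-9)).any(axis=1)
    if outside.any():
        raise GridBoundsError(
            f"{int(outside.sum())} atoms outside grid (with 3*sigma margin)")
    values = np.zeros(grid.shape, float)
    _render_into(values, grid, model.coords, atom_sigma)
    return DensityMap(values, grid.voxel_size, origin)


# ---------------------------------------------------------------------------
# pivoting
# ---------------------------------------------------------------------------


def pivot_rotation(frame: PivotFrame, alpha: float, beta: float) -> Rotation:
    """Rotation realizing an (alpha, beta) arm displacement about the frame.

    In-plane rotation by ``alpha`` about the platform normal is applied
    first, then the arm is lifted out of the plane by ``beta`` about the
    (rotated) in-plane perpendicular, so the measured projection/elevation
    angles of the displaced arm equal (alpha, beta) exactly.
    """
    n = frame.plane_normal
    r_in = Rotation.from_rotvec(np.radians(alpha) * n)
    # out-of-plane axis: the rotated in-plane perpendicular; rotating the
    # arm direction u about (u x n) by beta raises its elevation by beta
    m = r_in.apply(frame.in_plane_ortho)
    r_out = Rotation.from_rotvec(-np.radians(frame.beta_sign * beta) * m)
    return r_out * r_in


def rotate_about_pivot(model: AtomicModel, frame: PivotFrame,
                       alpha: float, beta: float,
                       mobile: DomainSelection | None = None) -> AtomicModel:
    """Rigidly rotate a model (or its mobile selection) about the pivot point."""
    rot = pivot_rotation(frame, alpha, beta)
    out = model.copy()
    if mobile is None:
        mask = np.ones(len(model), bool)
    else:
        mask = mobile.mask(model)
    rel = model.coords[mask] - frame.pivot
    out.coords[mask] = rot.apply(rel) + frame.pivot
    return out


@dataclass
class OrientationGrid:
    """Weighted grid of (alpha, beta) pivot orientations.

    Weights are normalized to sum to 1; the ensemble map is the weighted
    average of per-orientation renders.
    """

    alphas: np.ndarray
    betas: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.alphas = np.atleast_1d(np.asarray(self.alphas, float))
        self.betas = np.atleast_1d(np.asarray(self.betas, float))
        w = np.asarray(self.weights, float)
        if w.shape != (self.alphas.size, self.betas.size):
            raise ConfigError("weights shape must be (n_alpha, n_beta)")
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigError("weights must be non-negative with positive sum")
        self.weights = w / w.sum()

    def __len__(self) -> int:
        return self.alphas.size * self.betas.size

    def pairs(self):
        for i, a in enumerate(self.alphas):
            for j, b in enumerate(self.betas):
                yield float(a), float(b), float(self.weights[i, j])

    @classmethod
    def regular(cls, alpha_range: float, beta_range: float, step: float = 10.0,
                taper: str = "uniform") -> "OrientationGrid":
        """Symmetric +-range grids at fixed step (degrees) on both axes.

        ``taper`` is ``"uniform"`` (default) or ``"cosine"`` (raised-cosine
        weight falling to ~0 at the range edges on each axis).
        """
        def axis(rng):
            if rng <= 0:
                return np.array([0.0])
            n = int(round(rng / step))
            return np.arange(-n, n + 1) * step

        alphas = axis(alpha_range)
        betas = axis(beta_range)
        if taper == "uniform":
            w = np.ones((alphas.size, betas.size))
        elif taper == "cosine":
            wa = np.cos(np.pi / 2 * alphas / max(alpha_range, step)) ** 2 \
                if alphas.size > 1 else np.ones(1)
            wb = np.cos(np.pi / 2 * betas / max(beta_range, step)) ** 2 \
                if betas.size > 1 else np.ones(1)
            w = np.outer(wa, wb)
        else:
            raise ConfigError(f"unknown taper {taper!r}")
        return cls(alphas, betas, w)


def simulate_pivot_ensemble(model: AtomicModel, frame: PivotFrame,
                            orientations: OrientationGrid, grid: GridSpec,
                            atom_sigma: float = DEFAULT_ATOM_SIGMA,
                            mobile: DomainSelection | None = None) -> DensityMap:
    """Weighted average of rigid-body renders over the orientation grid.

    The output models a reconstructed map of the flexible body: the density
    of the molecule convolved with its orientation distribution (mass is
    conserved relative to a single render).
    """
    if len(orientations) == 0:
        raise ConfigError("orientation grid is empty")
    values = np.zeros(grid.shape, float)
    mask = np.ones(len(model), bool) if mobile is None else mobile.mask(model)
    origin = np.asarray(grid.origin, float)
    top = origin + grid.voxel_size * (np.asarray(grid.shape) - 1)
    margin = 3.0 * atom_sigma
    static = model.coords[~mask]
    for alpha, beta, w in orientations.pairs():
        rot = pivot_rotation(frame, alpha, beta)
        coords = rot.apply(model.coords[mask] - frame.pivot) + frame.pivot
        bad = ((coords < origin + margin - 1e-9)
               | (coords > top - margin + 1e-9)).any(axis=1)
        if bad.any():
            raise GridBoundsError(
                f"{int(bad.sum())} atoms outside grid at orientation "
                f"({alpha:g}, {beta:g})")
        _render_into(values, grid, coords, atom_sigma, weight=w)
    if static.size:
        _render_into(values, grid, static, atom_sigma, weight=1.0)
    return DensityMap(values, grid.voxel_size, origin)


def map_overlap(a: DensityMap, b: DensityMap, threshold: float) -> float:
    """Jaccard overlap of the two maps' voxel sets above a common threshold."""
    if not a.same_grid(b):
        raise GridMismatchError("maps are not on the same grid")
    sa = a.values > threshold
    sb = b.values > threshold
    union = int(np.logical_or(sa, sb).sum())
    if union == 0:
        return 1.0  # both empty above threshold: identical
    return float(np.logical_and(sa, sb).sum()) / union


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O
# ---------------------------------------------------------------------------


def write_mrc(density: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 mode-2 float with the origin in the header."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(density.values, dtype=np.float32))
    nx, ny, nz = density.shape
    v = density.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), density.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 volume (isotropic voxels required)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    spacing = np.asarray(m.grid.spacing, float)
    if not np.allclose(spacing, spacing[0], atol=1e-4):
        raise ConfigError(f"anisotropic voxels {spacing} not supported")
    values = np.array(m.grid, copy=True).astype(float)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], float)
    return DensityMap(values, float(spacing[0]), origin)
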