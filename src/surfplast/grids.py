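"""Gaussian atom-density grids and surface-plasticity fields.

The central quantity: for every frame a smooth density is built by placing
a unit-amplitude Gaussian of width ``kernel_sigma`` on each atom center,

    rho_t(x) = sum_i exp(-|x - r_i(t)|^2 / (2 sigma^2)).

The temporal mean of these grids describes the typical protein surface (an
isovalue of it can be rendered as such), while the temporal standard
deviation highlights regions alternately occupied by protein and solvent.
A further Gaussian smoothing of the SD grid emphasizes large regions of
high flexibility; that smoothed SD field is the *surface plasticity* map.
Sampling it at each atom's time-averaged position localizes plasticity on
atoms and residues.

Unit amplitude (rather than a normalized density) keeps isovalues
independent of atom count; the amplitude convention and all kernel
parameters are echoed into run manifests because plasticity magnitudes
depend on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ensemble import ResidueKey, StructureEnsemble
from .errors import BoundaryError, GeometryError, InsufficientFramesError

#: Default Gaussian kernel width per atom (Angstrom, heavy-atom scale).
DEFAULT_KERNEL_SIGMA = 1.5
#: Default grid spacing (Angstrom).
DEFAULT_SPACING = 0.5
#: Default bounding-box padding (Angstrom).
DEFAULT_PADDING = 6.0
#: Default width of the post-hoc smoothing of the SD grid (Angstrom).
DEFAULT_SMOOTH_SIGMA = 1.5
#: Default isovalue for "typical surface" extraction (unit-amplitude kernels).
DEFAULT_ISOVALUE = 0.5


@dataclass
class ScalarGrid:
    """Regular 3-D scalar field: origin (A), isotropic spacing (A), values."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise GeometryError(f"grid spacing must be > 0, got {self.spacing}")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GeometryError(f"grid values must be 3-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite grid values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        """World coordinate of the last grid node on each axis."""
        return self.origin + (np.asarray(self.dims) - 1) * self.spacing

    def same_geometry(self, other: "ScalarGrid", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def to_fractional(self, points: np.ndarray) -> np.ndarray:
        """World Angstrom -> fractional voxel indices."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world-coordinate points.

        Raises :class:`BoundaryError` (naming the first offending point) if
        any point falls outside the grid.
        """
        frac = self.to_fractional(points)
        hi = np.asarray(self.dims) - 1
        bad = np.any((frac < 0) | (frac > hi), axis=1)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise BoundaryError(
                f"point {i} at {np.atleast_2d(points)[i]} lies outside the grid"
            )
        return ndimage.map_coordinates(self.values, frac.T, order=1, mode="nearest")


@dataclass
class GridStats:
    """Temporal mean and standard-deviation grids on a shared geometry."""

    mean: ScalarGrid
    sd: ScalarGrid

    def __post_init__(self):
        if not self.mean.same_geometry(self.sd):
            raise GeometryError("mean and sd grids differ in geometry")
        if np.any(self.sd.values < 0):
            raise ValueError("sd grid has negative values")


@dataclass
class PlasticityResult:
    """Smoothed SD field plus plasticity localized on atoms and residues."""

    smoothed_sd: ScalarGrid
    per_atom: np.ndarray
    per_residue: dict[ResidueKey, float]
    isovalue_used: float
    parameters: dict = field(default_factory=dict)


def grid_geometry(
    coords: np.ndarray | list[np.ndarray],
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Origin and dims of the axis-aligned box enclosing coords plus padding.

    Accepts one coordinate array or a list of arrays (e.g. all frames of
    several ensembles that must share a geometry for comparison).
    """
    if isinstance(coords, (list, tuple)):
        pts = np.concatenate([np.asarray(c, dtype=float).reshape(-1, 3) for c in coords])
    else:
        pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if pts.size == 0:
        raise GeometryError("no coordinates to build a grid around")
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    origin = pts.min(axis=0) - padding
    extent = pts.max(axis=0) + padding - origin
    dims = tuple(int(np.ceil(e / spacing)) + 1 for e in extent)
    return origin, dims


def frame_density_grid(
    coords: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    dims: tuple[int, int, int],
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    cutoff_sigmas: float = 4.0,
    out: np.ndarray | None = None,
    check_padding: bool = True,
) -> ScalarGrid:
    """Gaussian atom-density grid for a single frame.

    Each atom contributes a unit-amplitude isotropic Gaussian of s.d.
    ``kernel_sigma``; contributions are truncated beyond
    ``cutoff_sigmas * kernel_sigma`` along each axis (the separable kernel
    makes the truncation region a box; it fully contains the sphere of the
    same radius).  If the grid does not enclose the atoms with at least the
    truncation distance of padding, mass leaks off-grid and a warning is
    emitted.
    """
    if kernel_sigma <= 0:
        raise ValueError(f"kernel_sigma must be > 0, got {kernel_sigma}")
    origin = np.asarray(origin, dtype=float).reshape(3)
    dims = tuple(int(d) for d in dims)
    if min(dims) < 1:
        raise GeometryError(f"grid dims must all be >= 1, got {dims}")
    if out is None:
        values = np.zeros(dims)
    else:
        values = out

    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        return ScalarGrid(origin, spacing, values)

    cut = cutoff_sigmas * kernel_sigma
    upper = origin + (np.asarray(dims) - 1) * spacing
    if check_padding and (
        np.any(pts.min(axis=0) - origin < cut) or np.any(upper - pts.max(axis=0) < cut)
    ):
        warnings.warn(
            "grid padding is smaller than the kernel truncation distance; "
            "density near the boundary will be clipped",
            stacklevel=2,
        )

    inv_2s2 = 1.0 / (2.0 * kernel_sigma * kernel_sigma)
    ndims = np.asarray(dims)
    for r in pts:
        lo = np.ceil((r - cut - origin) / spacing).astype(int)
        hi = np.floor((r + cut - origin) / spacing).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, ndims - 1)
        if np.any(hi < lo):
            continue
        g = [
            np.exp(
                -((origin[d] + np.arange(lo[d], hi[d] + 1) * spacing - r[d]) ** 2)
                * inv_2s2
            )
            for d in range(3)
        ]
        values[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] += (
            g[0][:, None, None] * (g[1][:, None] * g[2][None, :])[None, :, :]
        )
    return ScalarGrid(origin, spacing, values)


def ensemble_grid_stats(
    ensemble: StructureEnsemble,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    cutoff_sigmas: float = 4.0,
    geometry: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> GridStats:
    """Temporal mean and SD of the per-frame density grids.

    All frames share one geometry (the bounding box of the whole ensemble
    plus ``padding``, or an explicit ``geometry`` when several systems must
    be compared on a common grid).  Accumulation is Welford's one-pass
    algorithm, so the SD is numerically stable even when fluctuations are
    tiny relative to the mean.  Population (1/T) normalization.

    A single-frame ensemble yields a zero SD grid with a warning.
    """
    t_frames = ensemble.n_frames
    if geometry is None:
        origin, dims = grid_geometry(
            ensemble.coords.reshape(-1, 3), spacing=spacing, padding=padding
        )
    else:
        origin, dims = geometry
        origin = np.asarray(origin, dtype=float).reshape(3)
        dims = tuple(int(d) for d in dims)
    if t_frames < 2:
        warnings.warn("single-frame ensemble: SD grid is identically zero", stacklevel=2)

    mean = np.zeros(dims)
    m2 = np.zeros(dims)
    buf = np.empty(dims)
    for t in range(t_frames):
        buf.fill(0.0)
        frame_density_grid(
            ensemble.coords[t],
            origin,
            spacing,
            dims,
            kernel_sigma=kernel_sigma,
            cutoff_sigmas=cutoff_sigmas,
            out=buf,
            check_padding=(t == 0),
        )
        delta = buf - mean
        mean += delta / (t + 1)
        m2 += delta * (buf - mean)
    sd = np.sqrt(np.maximum(m2 / t_frames, 0.0))
    return GridStats(
        mean=ScalarGrid(origin, spacing, mean),
        sd=ScalarGrid(origin, spacing, sd),
    )


def smooth_grid(grid: ScalarGrid, smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> ScalarGrid:
    """Convolve with a normalized Gaussian of s.d. ``smooth_sigma`` (Angstrom).

    Zero-padded boundaries (values beyond the grid are treated as zero), so
    totals can only shrink near edges.  ``smooth_sigma = 0`` is the identity.
    """
    if smooth_sigma < 0:
        raise ValueError(f"smooth_sigma must be >= 0, got {smooth_sigma}")
    if smooth_sigma == 0:
        return ScalarGrid(grid.origin.copy(), grid.spacing, grid.values.copy())
    sigma_vox = smooth_sigma / grid.spacing
    smoothed = ndimage.gaussian_filter(grid.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return ScalarGrid(grid.origin.copy(), grid.spacing, smoothed)


def localize_plasticity(
    stats: GridStats,
    smoothed_sd: ScalarGrid,
    ensemble: StructureEnsemble,
    isovalue: float = DEFAULT_ISOVALUE,
) -> PlasticityResult:
    """Sample the smoothed SD field at time-averaged atom positions.

    per_atom[i] is the trilinear interpolation of the smoothed SD grid at
    atom i's mean position over the (aligned) ensemble; per-residue values
    are means over each residue's atoms.  The isovalue recorded is the one
    to use when exporting the mean-density surface the values are meant to
    color.
    """
    if not stats.mean.same_geometry(smoothed_sd):
        raise GeometryError("smoothed SD grid geometry differs from stats grids")
    mean_pos = ensemble.coords.mean(axis=0)
    per_atom = smoothed_sd.interpolate(mean_pos)
    per_residue = {
        key: float(per_atom[idx].mean()) for key, idx in ensemble.residue_groups().items()
    }
    return PlasticityResult(
        smoothed_sd=smoothed_sd,
        per_atom=per_atom,
        per_residue=per_residue,
        isovalue_used=float(isovalue),
    )


def extract_isosurface(grid: ScalarGrid, isovalue: float) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes isosurface of the grid in world coordinates (Angstrom).

    Returns (vertices, triangle faces).  The isovalue must lie strictly
    between the grid's min and max.
    """
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if not (vmin < isovalue < vmax):
        raise ValueError(
            f"isovalue {isovalue} outside the open value range ({vmin}, {vmax})"
        )
    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(grid.values, level=isovalue)
    return verts * grid.spacing + grid.origin, faces


def compute_plasticity(
    ensemble: StructureEnsemble,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    isovalue: float = DEFAULT_ISOVALUE,
    geometry: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> tuple[GridStats, PlasticityResult]:
    """Convenience pipeline: density stats -> smoothed SD -> localization.

    The ensemble is expected to be superposed already (see
    :func:`surfplast.superpose.align_ensemble`); gridding an unaligned
    trajectory conflates global tumbling with surface plasticity.
    """
    if ensemble.n_frames < 1:
        raise InsufficientFramesError("need at least one frame")
    stats = ensemble_grid_stats(
        ensemble,
        kernel_sigma=kernel_sigma,
        spacing=spacing,
        padding=padding,
        geometry=geometry,
    )
    smoothed = smooth_grid(stats.sd, smooth_sigma)
    result = localize_plasticity(stats, smoothed, ensemble, isovalue=isovalue)
    result.parameters = {
        "kernel_sigma_A": kernel_sigma,
        "spacing_A": spacing,
        "padding_A": padding,
        "smooth_sigma_A": smooth_sigma,
        "isovalue": isovalue,
        "amplitude_convention": "unit per atom",
    }
    return stats, result
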