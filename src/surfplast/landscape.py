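"""Cartesian PCA, gaMD Boltzmann reweighting, free-energy surfaces and
conformational-selection statistics.

The collective coordinates are principal components of the Cartesian
C-alpha coordinate covariance of an aligned ensemble.  Histogramming the
projections gives populations p(bin); for gaMD data each frame is weighted
to undo the boost potential, with exp(beta DeltaV) approximated by its
truncated Maclaurin series

    w_t = sum_{k=0}^{order} (beta DeltaV_t)^k / k!,

the standard stabilization of gaMD energetic reweighting (the raw
exponential amplifies the noisiest frames).  Free energies are
F = -ln p in units of k_B T, gauged so the lowest occupied bin is zero;
empty bins stay flagged as empty rather than being assigned a large
constant, which keeps minima counting well-defined.

Conformational selection is quantified two ways: the fraction of free
ensemble frames within an RMSD cutoff of the bound (binding-competent)
reference, and the free-vs-bound population shift on a shared PCA basis
(occupied-range ratios per PC and the change in the number of local
free-energy minima).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import BoostSeries, StructureEnsemble
from .errors import CorrespondenceError, GeometryError, InsufficientFramesError
from .superpose import kabsch_superpose


@dataclass
class PCAModel:
    """PCA of flattened (3N) Cartesian coordinates, population covariance."""

    mean_coords: np.ndarray          # (N, 3)
    components: np.ndarray           # (K, 3N), orthonormal rows
    eigenvalues: np.ndarray          # (K,), Angstrom^2, descending
    projections: np.ndarray          # (T, K), centered
    total_variance: float            # trace of the coordinate covariance

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Project (T, N, 3) coordinates onto the model's components."""
        flat = np.asarray(coords, dtype=float).reshape(coords.shape[0], -1)
        return (flat - self.mean_coords.ravel()) @ self.components.T


@dataclass
class FESResult:
    """Reweighted histogram and free energies over 1-2 PC coordinates."""

    bin_edges: list[np.ndarray]
    probabilities: np.ndarray        # normalized over all bins
    free_energy: np.ndarray          # k_B T units, min over occupied bins = 0
    empty: np.ndarray                # True where no sample fell
    maclaurin_order: int | None      # None = exact exponential weights
    empty_bin_policy: str = "nan"

    def bin_centers(self, dim: int = 0) -> np.ndarray:
        e = self.bin_edges[dim]
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class SelectionReport:
    """Binding-competent-state occupancy of a free ensemble."""

    rmsd_to_reference: np.ndarray    # (T,), Angstrom
    competent_fraction: float
    cutoff: float


@dataclass
class PopulationShift:
    """Free-vs-bound landscape comparison on identical bins."""

    range_ratio: list[float]         # per PC: occupied-range bound / free
    minima_free: int
    minima_bound: int
    minima_difference: int           # free - bound
    f_cut: float
    occupied_bins_free: list[int] = field(default_factory=list)
    occupied_bins_bound: list[int] = field(default_factory=list)


def fit_pca(ensemble: StructureEnsemble, n_components: int | None = None) -> PCAModel:
    """PCA of the 3N-dimensional coordinate covariance (population norm).

    The ensemble must be superposed first; otherwise the leading components
    capture rigid-body motion.  Computed by SVD of the centered T x 3N
    coordinate matrix (equivalent to eigendecomposition of the covariance,
    but stable and cheap for T << 3N or 3N << T).  Component signs are
    fixed so each component's largest-magnitude element is positive.
    """
    t = ensemble.n_frames
    if t < 2:
        raise InsufficientFramesError(f"PCA needs >= 2 frames, got {t}")
    n3 = 3 * ensemble.n_atoms
    k_max = min(t - 1, n3)
    k = k_max if n_components is None else int(n_components)
    if not 1 <= k <= k_max:
        raise ValueError(f"n_components must be in [1, {k_max}], got {k}")

    flat = ensemble.coords.reshape(t, n3)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Deterministic sign convention.
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    eigenvalues = s**2 / t
    total_variance = float(centered.var(axis=0, ddof=0).sum())
    return PCAModel(
        mean_coords=mean_flat.reshape(-1, 3),
        components=vt[:k],
        eigenvalues=eigenvalues[:k],
        projections=u[:, :k] * s[:k],
        total_variance=total_variance,
    )


def maclaurin_weights(
    boost: BoostSeries, order: int | None = 10, normalize: bool = True
) -> np.ndarray:
    """Frame weights approximating exp(beta DeltaV), normalized to mean 1.

    ``order`` is the truncation order of the Maclaurin (power) series of
    the exponential; ``order=None`` uses the exact exponential (useful for
    validation, but noisy on real gaMD data).  For DeltaV >= 0 the raw
    weights increase monotonically with order and are bounded above by the
    exact exponential.  ``normalize=False`` returns the raw partial sums.
    """
    x = boost.beta * boost.delta_v
    if order is None:
        raw = np.exp(x)
    else:
        order = int(order)
        if order < 0:
            raise ValueError(f"order must be >= 0, got {order}")
        raw = np.ones_like(x)
        term = np.ones_like(x)
        for k in range(1, order + 1):
            term = term * x / k
            raw = raw + term
    return raw / raw.mean() if normalize else raw


def reweighted_fes(
    projections: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int | tuple[int, ...] = 60,
    bin_range: list[tuple[float, float]] | None = None,
    bin_edges: list[np.ndarray] | None = None,
    maclaurin_order: int | None = 10,
) -> FESResult:
    """Free-energy surface F = -ln p over 1-2 projection coordinates.

    ``weights`` are the per-frame reweighting factors (uniform when None:
    a conventional-MD histogram).  ``bin_edges`` (or ``bins`` counts plus
    an optional shared ``bin_range``) define the histogram; pass identical
    edges for surfaces that will be compared.  Empty bins are flagged, not
    assigned a sentinel free energy; the minimum over occupied bins is 0.
    ``maclaurin_order`` is recorded as provenance of the weights.
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim == 1:
        proj = proj[:, None]
    t, d = proj.shape
    if d not in (1, 2):
        raise ValueError(f"FES supports 1 or 2 dimensions, got {d}")
    if weights is None:
        w = np.ones(t)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != (t,):
            raise ValueError(f"{w.size} weights for {t} projections")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    if bin_edges is not None:
        edges = [np.asarray(e, dtype=float) for e in bin_edges]
        if len(edges) != d:
            raise ValueError(f"need {d} edge arrays, got {len(edges)}")
    else:
        nb = (bins,) * d if np.isscalar(bins) else tuple(bins)
        if any(b < 2 for b in nb):
            raise ValueError("need at least 2 bins per dimension")
        rng = bin_range or [(proj[:, j].min(), proj[:, j].max()) for j in range(d)]
        edges = [np.linspace(lo, hi, nb[j] + 1) for j, (lo, hi) in enumerate(rng)]

    hist, _ = np.histogramdd(proj, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no samples fall inside the histogram range")
    p = hist / total
    empty = hist == 0
    f = np.full(p.shape, np.nan)
    f[~empty] = -np.log(p[~empty])
    f -= np.nanmin(f)
    return FESResult(
        bin_edges=edges,
        probabilities=p,
        free_energy=f,
        empty=empty,
        maclaurin_order=maclaurin_order if weights is not None else None,
    )


def binding_competence(
    free_ensemble: StructureEnsemble,
    reference: StructureEnsemble | np.ndarray,
    cutoff: float,
    fit_selection: str | np.ndarray = "CA",
) -> SelectionReport:
    """Occupancy of the binding-competent state in a free ensemble.

    Every frame is Kabsch-fit to the reference on ``fit_selection`` and
    the RMSD over those atoms recorded; the competent fraction is the
    share of frames with RMSD <= cutoff.  When ``reference`` is an
    ensemble (e.g. the bound conformation), atoms are matched by identity
    (chain, resseq, icode, name); a bare (N, 3) array is matched by index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(reference, StructureEnsemble):
        ref_index = {
            (a.chain_id, a.residue_seq, a.icode, a.name): i
            for i, a in enumerate(reference.atoms)
        }
        pairs = [
            (i, ref_index[(a.chain_id, a.residue_seq, a.icode, a.name)])
            for i, a in enumerate(free_ensemble.atoms)
            if (a.chain_id, a.residue_seq, a.icode, a.name) in ref_index
        ]
        if not pairs:
            raise CorrespondenceError(
                "no atoms shared between free ensemble and reference"
            )
        ens_idx = np.array([p[0] for p in pairs])
        ref_coords = reference.coords[0][[p[1] for p in pairs]]
        sub = free_ensemble.select(np.isin(np.arange(free_ensemble.n_atoms), ens_idx))
        mask = sub.atom_mask(fit_selection)
        coords = sub.coords
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (free_ensemble.n_atoms, 3):
            raise CorrespondenceError(
                f"reference has shape {ref_coords.shape}, expected "
                f"({free_ensemble.n_atoms}, 3)"
            )
        mask = free_ensemble.atom_mask(fit_selection)
        coords = free_ensemble.coords

    ref_sel = ref_coords[mask]
    rmsd = np.empty(coords.shape[0])
    for t in range(coords.shape[0]):
        _, _, rmsd[t] = kabsch_superpose(coords[t, mask], ref_sel)
    fraction = float(np.count_nonzero(rmsd <= cutoff)) / rmsd.size
    return SelectionReport(
        rmsd_to_reference=rmsd, competent_fraction=fraction, cutoff=float(cutoff)
    )


def _count_local_minima(f: np.ndarray) -> int:
    """Strict local minima among occupied (finite) bins.

    1-D: 2-neighborhood; 2-D: 8-neighborhood.  A minimum must have *all*
    its neighbors inside the histogram, occupied, and strictly higher:
    plateaus are not minima, and the poorly-sampled fringe of the occupied
    region (where occupied bins border empty ones) cannot produce spurious
    minima.  This is why empty bins stay flagged instead of receiving a
    large sentinel free energy.
    """
    f = np.asarray(f, dtype=float)
    finite = np.isfinite(f)
    count = 0
    if f.ndim == 1:
        offsets = [(-1,), (1,)]
    else:
        offsets = [
            (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
        ]
    for idx in np.argwhere(finite):
        v = f[tuple(idx)]
        is_min = True
        for off in offsets:
            nb = idx + np.asarray(off)
            if np.any(nb < 0) or np.any(nb >= f.shape):
                is_min = False
                break
            nv = f[tuple(nb)]
            if not np.isfinite(nv) or nv <= v:
                is_min = False
                break
        if is_min:
            count += 1
    return count


def population_shift(
    fes_free: FESResult, fes_bound: FESResult, f_cut: float = 3.0
) -> PopulationShift:
    """Free-vs-bound landscape comparison on a shared PCA basis.

    Both surfaces must use identical bin edges (project both ensembles on
    one joint basis and histogram with shared edges).  Per PC the occupied
    range is the number of bin positions along that axis holding at least
    one bin with F <= ``f_cut``; the report gives the bound/free ratio.
    The minima difference is (free - bound) counts of strict local minima.
    """
    if len(fes_free.bin_edges) != len(fes_bound.bin_edges) or any(
        e1.shape != e2.shape or not np.allclose(e1, e2)
        for e1, e2 in zip(fes_free.bin_edges, fes_bound.bin_edges)
    ):
        raise GeometryError("free and bound FES have different bin edges")

    ndim = len(fes_free.bin_edges)
    ratios, occ_free, occ_bound = [], [], []
    for axis in range(ndim):
        other = tuple(a for a in range(ndim) if a != axis)

        def occupied_count(fes: FESResult) -> int:
            mask = np.isfinite(fes.free_energy) & (fes.free_energy <= f_cut)
            line = mask.any(axis=other) if other else mask
            return int(np.count_nonzero(line))

        nf, nb = occupied_count(fes_free), occupied_count(fes_bound)
        occ_free.append(nf)
        occ_bound.append(nb)
        ratios.append(nb / nf if nf else float("nan"))

    m_free = _count_local_minima(fes_free.free_energy)
    m_bound = _count_local_minima(fes_bound.free_energy)
    return PopulationShift(
        range_ratio=ratios,
        minima_free=m_free,
        minima_bound=m_bound,
        minima_difference=m_free - m_bound,
        f_cut=float(f_cut),
        occupied_bins_free=occ_free,
        occupied_bins_bound=occ_bound,
    )
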