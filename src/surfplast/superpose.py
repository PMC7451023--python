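"""Kabsch superposition, ensemble alignment and RMSF profiles.

Global rotation/translation must be removed before any per-atom
fluctuation measure (RMSF, density SD, Cartesian PCA) is meaningful;
otherwise rigid-body tumbling masquerades as internal flexibility.
Superpositions are always proper rotations — reflections are excluded by
sign-correcting the SVD — so chirality is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ResidueKey, StructureEnsemble
from .errors import GeometryError, InsufficientFramesError


@dataclass
class RMSFProfile:
    """Per-atom and per-residue root-mean-square fluctuations (Angstrom).

    per_residue is the arithmetic mean of the residue's per-atom values.
    Population (1/T) normalization.
    """

    per_atom: np.ndarray
    per_residue: dict[ResidueKey, float]


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD to
    ``target``.  Reflections are never returned: the smallest singular
    value's axis is flipped when det < 0 (standard sign-corrected SVD).

    Raises :class:`GeometryError` for fewer than 3 points or a collinear
    (rank-deficient) configuration, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 points for superposition, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - w @ mobile
    tar_c = target - w @ target
    # Collinear points leave the rotation about the line undetermined.
    scale = max(float(np.abs(mob_c).max()), 1e-12)
    if np.linalg.matrix_rank(mob_c, tol=1e-8 * scale) < 2:
        raise GeometryError("rank-deficient (collinear) point configuration")
    h = (mob_c * w[:, None]).T @ tar_c  # 3x3 cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = (w @ target) - rotation @ (w @ mobile)
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w * ((moved - target) ** 2).sum(1)).sum()))
    return rotation, translation, rmsd


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray, fit_mask: np.ndarray
) -> np.ndarray:
    """Fit every frame to ``reference`` on ``fit_mask``; transform all atoms."""
    out = np.empty_like(coords)
    ref_sel = reference[fit_mask]
    for t in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[t, fit_mask], ref_sel)
        out[t] = coords[t] @ rot.T + trans
    return out


def align_ensemble(
    ensemble: StructureEnsemble,
    reference: str = "mean",
    fit_selection: str | np.ndarray = "CA",
) -> StructureEnsemble:
    """Remove global rotation/translation from every frame.

    ``reference`` is ``"frame0"`` (single pass against the first frame) or
    ``"mean"`` (iterate fitting against the running mean structure until
    the mean moves < 1e-10 A or 20 iterations — tight enough that
    re-aligning an aligned ensemble is a no-op).  The fit uses ``fit_selection``
    (default CA atoms, matching C-alpha-based analyses); the transform is
    applied to all atoms.
    """
    mask = ensemble.atom_mask(fit_selection)
    if int(mask.sum()) < 3:
        raise GeometryError("fit selection must contain at least 3 atoms")
    coords = ensemble.coords
    if reference == "frame0":
        return ensemble.with_coords(superpose_frames(coords, coords[0], mask))
    if reference != "mean":
        raise ValueError(f"unknown reference {reference!r}")

    # Iterate against the running mean starting from the current mean (this
    # makes re-alignment of an already-aligned ensemble a no-op); fall back
    # to frame 0 when the raw mean is degenerate (e.g. scrambled rotations
    # averaging to a collinear cloud).
    ref = coords.mean(axis=0)
    try:
        aligned = superpose_frames(coords, ref, mask)
    except GeometryError:
        aligned = superpose_frames(coords, coords[0], mask)
    ref = aligned.mean(axis=0)
    for _ in range(20):
        aligned = superpose_frames(aligned, ref, mask)
        new_ref = aligned.mean(axis=0)
        shift = float(np.abs(new_ref - ref).max())
        ref = new_ref
        if shift < 1e-10:
            break
    return ensemble.with_coords(aligned)


def compute_rmsf(ensemble: StructureEnsemble) -> RMSFProfile:
    """Per-atom RMSF about the time-averaged position.

    rmsf_i = sqrt( (1/T) sum_t |r_i(t) - <r_i>|^2 ).  The ensemble is
    expected to be aligned already (not enforced — fluctuations relative to
    whatever frame of reference the coordinates are in are reported).
    """
    if ensemble.n_frames < 2:
        raise InsufficientFramesError(
            f"RMSF needs >= 2 frames, got {ensemble.n_frames}"
        )
    # Welford over frames: numerically stable, and exactly zero variance
    # for identical frames (a naive mean-then-subtract leaves ~1e-15 noise).
    coords = ensemble.coords
    mean = coords[0].copy()
    m2 = np.zeros_like(mean)
    for t in range(1, coords.shape[0]):
        delta = coords[t] - mean
        mean += delta / (t + 1)
        m2 += delta * (coords[t] - mean)
    per_atom = np.sqrt(m2.sum(axis=1) / coords.shape[0])
    per_residue = {
        key: float(per_atom[idx].mean())
        for key, idx in ensemble.residue_groups().items()
    }
    return RMSFProfile(per_atom=per_atom, per_residue=per_residue)
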