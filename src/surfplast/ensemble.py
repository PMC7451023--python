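"""Core in-memory containers: atoms, ensembles, gaMD boost series.

Units follow AMBER conventions: coordinates in Angstrom, energies in
kcal/mol, temperatures in Kelvin.  ``KB_KCAL`` is the Boltzmann constant in
kcal/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError

#: Boltzmann constant, kcal/(mol K)  (AMBER convention).
KB_KCAL = 0.0019872041

#: Residue identity used for grouping: (chain_id, residue_seq, icode).
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom, constant across frames.

    Full identity is (chain_id, residue_seq, icode, name): atoms that differ
    only in insertion code are distinct.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    element: str
    icode: str = ""

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.icode)


@dataclass
class StructureEnsemble:
    """T frames x N atoms of 3-D coordinates plus per-atom metadata.

    ``coords[t, i]`` always refers to ``atoms[i]``; every operation in this
    package preserves that ordering.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray  # (T, N, 3), Angstrom
    frame_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (T, N, 3), got {self.coords.shape}")
        t, n, _ = self.coords.shape
        if t < 1 or n < 1:
            raise ValueError("ensemble needs at least one frame and one atom")
        if n != len(self.atoms):
            raise ValueError(
                f"coords have {n} atoms but {len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if not self.frame_ids:
            self.frame_ids = list(range(t))
        if len(self.frame_ids) != t:
            raise ValueError("frame_ids length differs from number of frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(self, selection: str | np.ndarray) -> np.ndarray:
        """Boolean mask over atoms.

        ``selection`` is either "all", an atom name (e.g. "CA"), or an
        explicit boolean mask of length N.
        """
        if isinstance(selection, str):
            if selection.lower() == "all":
                return np.ones(self.n_atoms, dtype=bool)
            mask = np.array([a.name == selection for a in self.atoms])
        else:
            mask = np.asarray(selection, dtype=bool)
            if mask.shape != (self.n_atoms,):
                raise SelectionError(
                    f"mask has shape {mask.shape}, expected ({self.n_atoms},)"
                )
        if not mask.any():
            raise SelectionError(f"selection {selection!r} matches no atoms")
        return mask

    def select(self, selection: str | np.ndarray) -> "StructureEnsemble":
        """Sub-ensemble with only the selected atoms (order preserved)."""
        mask = self.atom_mask(selection)
        if mask.all():
            return self
        atoms = [a for a, keep in zip(self.atoms, mask) if keep]
        return StructureEnsemble(atoms, self.coords[:, mask, :], list(self.frame_ids))

    def with_coords(self, coords: np.ndarray) -> "StructureEnsemble":
        """Same atoms/frame ids, new coordinate array."""
        return StructureEnsemble(self.atoms, coords, list(self.frame_ids))

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residues in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_groups(self) -> dict[ResidueKey, np.ndarray]:
        """Map residue -> integer indices of its atoms."""
        groups: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault(a.residue_key, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class BoostSeries:
    """Per-frame gaMD boost potential DeltaV (kcal/mol) at a temperature (K).

    The gaMD bias is harmonic and hence non-negative; negative entries are
    rejected.
    """

    delta_v: np.ndarray
    temperature: float

    def __post_init__(self):
        self.delta_v = np.asarray(self.delta_v, dtype=float).ravel()
        if self.delta_v.size == 0:
            raise ValueError("empty boost series")
        if not np.all(np.isfinite(self.delta_v)):
            raise ValueError("non-finite boost energies")
        if np.any(self.delta_v < 0):
            raise ValueError("boost potential must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __len__(self) -> int:
        return self.delta_v.size

    @property
    def beta(self) -> float:
        """1/(k_B T) in mol/kcal."""
        return 1.0 / (KB_KCAL * self.temperature)


def pair_ensemble_boost(ensemble: StructureEnsemble, boost: BoostSeries) -> None:
    """Validate that a boost series matches an ensemble frame-for-frame.

    Length mismatch is an error at pairing time, not at read time.
    """
    if len(boost) != ensemble.n_frames:
        raise ValueError(
            f"boost series has {len(boost)} entries but ensemble has "
            f"{ensemble.n_frames} frames"
        )


__all__ = [
    "KB_KCAL",
    "ResidueKey",
    "AtomRecord",
    "StructureEnsemble",
    "BoostSeries",
    "pair_ensemble_boost",
]
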