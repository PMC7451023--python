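"""Synthetic conformational ensembles and a 1-D toy gaMD sampler.

Microsecond trajectories of antibody-antigen systems cannot ship with a
package, so validation runs on generated ensembles whose ground truth is
known by construction:

* :func:`sample_harmonic_ensemble` draws i.i.d. frames around a reference
  structure with region-dependent isotropic fluctuation amplitudes plus
  optional collective (concerted) displacement modes.  Frames are
  uncorrelated in time — every analysis in this package is
  time-order-invariant, so kinetics would add nothing testable.
* :func:`sample_toy_gamd` runs a Metropolis chain on a 1-D polynomial
  potential with the Gaussian-accelerated-MD harmonic boost
  ``DeltaV(x) = k/2 (E - V(x))^2`` applied below the threshold energy E,
  raising basins while leaving barrier tops untouched.  It returns both
  the biased samples and the per-sample boost energies, exactly what the
  Boltzmann-reweighting machinery consumes; the 1-D analytic Boltzmann
  integral provides an exact oracle for the reweighted free-energy
  profile.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import KB_KCAL, AtomRecord, BoostSeries, StructureEnsemble


def _ca_atoms(n_residues: int, chain_id: str = "A") -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="ALA",
            chain_id=chain_id,
            residue_seq=i + 1,
            element="C",
        )
        for i in range(n_residues)
    ]


def make_reference_structure(
    n_residues: int, geometry: str = "helix"
) -> StructureEnsemble:
    """Single-frame C-alpha trace: ideal alpha-helix or extended chain.

    Helix: rise 1.5 A per residue along z, radius 2.3 A, 100 degree twist.
    Extended: collinear CA atoms every 3.8 A along x.
    """
    if n_residues < 2:
        raise ValueError(f"need at least 2 residues, got {n_residues}")
    i = np.arange(n_residues)
    if geometry == "helix":
        theta = np.deg2rad(100.0) * i
        xyz = np.stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1
        )
    elif geometry == "extended":
        xyz = np.stack([3.8 * i, np.zeros(n_residues), np.zeros(n_residues)], axis=1)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return StructureEnsemble(_ca_atoms(n_residues), xyz[None, :, :])


@dataclass
class SyntheticSpec:
    """Generative parameters for a harmonic (i.i.d.-frame) ensemble.

    Each atom i fluctuates isotropically with per-coordinate s.d.
    ``region_amplitudes[region_labels[i]]`` around ``reference_coords[i]``;
    each collective mode (unit N x 3 direction, amplitude) adds a concerted
    displacement with a normal coefficient of that s.d. per frame.
    """

    reference_coords: np.ndarray
    region_labels: np.ndarray
    region_amplitudes: dict[int, float]
    collective_modes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        n = self.reference_coords.shape[0]
        if self.reference_coords.shape != (n, 3):
            raise ValueError("reference_coords must be (N, 3)")
        if self.region_labels.shape != (n,):
            raise ValueError("region_labels must have one label per atom")
        if any(a < 0 for a in self.region_amplitudes.values()):
            raise ValueError("region amplitudes must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for k, (direction, amp) in enumerate(self.collective_modes):
            direction = np.asarray(direction, dtype=float)
            if direction.shape != (n, 3):
                raise ValueError(f"mode {k} direction must be (N, 3)")
            norm = np.linalg.norm(direction)
            if abs(norm - 1.0) > 1e-10:
                raise ValueError(f"mode {k} direction not unit-norm ({norm})")
            if amp < 0:
                raise ValueError(f"mode {k} amplitude must be >= 0")
            self.collective_modes[k] = (direction, float(amp))

    def sigma_per_atom(self) -> np.ndarray:
        try:
            return np.array(
                [self.region_amplitudes[int(r)] for r in self.region_labels]
            )
        except KeyError as exc:
            raise KeyError(f"region label {exc} has no amplitude") from None


def sample_harmonic_ensemble(
    spec: SyntheticSpec, atoms: list[AtomRecord] | None = None
) -> StructureEnsemble:
    """Draw ``spec.n_frames`` i.i.d. frames from the harmonic model.

    coords[t, i] = ref[i] + sigma_i * eta[t, i] + sum_m c_m[t] * dir_m[i],
    with eta standard normal per coordinate and c_m ~ N(0, amplitude_m^2).
    Identical seed -> bitwise-identical output.
    """
    sigma = spec.sigma_per_atom()
    rng = np.random.default_rng(spec.seed)
    n = spec.reference_coords.shape[0]
    coords = spec.reference_coords[None, :, :] + sigma[None, :, None] * rng.standard_normal(
        (spec.n_frames, n, 3)
    )
    for direction, amp in spec.collective_modes:
        c = amp * rng.standard_normal(spec.n_frames)
        coords += c[:, None, None] * direction[None, :, :]
    if atoms is None:
        atoms = _ca_atoms(n)
    return StructureEnsemble(atoms, coords)


def three_segment_spec(
    n_per_segment: int = 3,
    amplitudes: tuple[float, float, float] = (0.2, 1.0, 0.2),
    n_frames: int = 2000,
    seed: int = 0,
    geometry: str = "extended",
) -> SyntheticSpec:
    """Three-segment peptide: mobile middle segment between two quiet flanks.

    The canonical ground-truth fixture: a surface-plasticity map must rank
    the middle segment above both flanks.
    """
    n = 3 * n_per_segment
    ref = make_reference_structure(n, geometry).coords[0]
    labels = np.repeat([0, 1, 2], n_per_segment)
    return SyntheticSpec(
        reference_coords=ref,
        region_labels=labels,
        region_amplitudes={0: amplitudes[0], 1: amplitudes[1], 2: amplitudes[2]},
        n_frames=n_frames,
        seed=seed,
    )


@dataclass
class ToyGamdSpec:
    """1-D toy gaMD system: polynomial potential plus harmonic boost.

    ``potential`` holds ascending polynomial coefficients (kcal/mol); the
    boost below threshold E is DeltaV(x) = k_boost/2 (E - V(x))^2, the gaMD
    form that raises basins and leaves regions with V >= E untouched.
    """

    potential: np.ndarray
    k_boost: float
    e_threshold: float
    temperature: float = 300.0
    n_samples: int = 100_000
    seed: int = 0
    mc_step: float = 0.5
    x0: float = 1.0

    def __post_init__(self):
        self.potential = np.asarray(self.potential, dtype=float)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.k_boost < 0:
            raise ValueError("k_boost must be >= 0")
        if self.mc_step <= 0:
            raise ValueError("mc_step must be > 0")

    def v(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(x, self.potential)

    def boost(self, x: np.ndarray | float) -> np.ndarray | float:
        """DeltaV(x): deterministic function of position given the spec."""
        v = self.v(x)
        gap = np.where(v < self.e_threshold, self.e_threshold - v, 0.0)
        return 0.5 * self.k_boost * gap * gap


def double_well_spec(**kwargs) -> ToyGamdSpec:
    """The standard validation system: V(x) = (x^2 - 1)^2 kcal/mol.

    Wells at x = +-1 (V = 0), barrier V(0) = 1.  Defaults: threshold at the
    barrier top (E = 1, the usual gaMD lower-bound choice) and k_boost = 1,
    giving beta*DeltaV ~ 0.84 in the wells at 300 K — a clearly visible
    bias that low-order Maclaurin reweighting still reconstructs.
    """
    kwargs.setdefault("potential", np.array([1.0, 0.0, -2.0, 0.0, 1.0]))
    kwargs.setdefault("k_boost", 1.0)
    kwargs.setdefault("e_threshold", 1.0)
    return ToyGamdSpec(**kwargs)


def metropolis_1d(
    energy_fn,
    n_samples: int,
    beta: float,
    step: float,
    x0: float,
    rng: np.random.Generator,
    burn_in_fraction: float = 0.1,
) -> np.ndarray:
    """Plain Metropolis chain on an arbitrary 1-D energy function.

    The first ``burn_in_fraction`` of ``n_samples`` is discarded.  Also
    serves as the independent sampler for unbiased cross-checks.
    """
    burn = int(burn_in_fraction * n_samples)
    steps = step * rng.standard_normal(n_samples)
    accept_u = rng.random(n_samples)
    xs = np.empty(n_samples)
    x = x0
    e = float(energy_fn(x))
    if not np.isfinite(e):
        raise FloatingPointError(f"non-finite energy at x={x}")
    for t in range(n_samples):
        x_new = x + steps[t]
        e_new = float(energy_fn(x_new))
        if not np.isfinite(e_new):
            raise FloatingPointError(f"non-finite energy at x={x_new}")
        if e_new <= e or accept_u[t] < np.exp(-beta * (e_new - e)):
            x, e = x_new, e_new
        xs[t] = x
    return xs[burn:]


def sample_toy_gamd(spec: ToyGamdSpec) -> tuple[np.ndarray, BoostSeries]:
    """Metropolis-sample the boosted potential V(x) + DeltaV(x).

    Returns the visited positions (burn-in removed) and the matching
    per-sample boost energies as a :class:`BoostSeries` — the inputs the
    Maclaurin reweighting stage needs to reconstruct the unbiased
    free-energy profile.
    """
    beta = 1.0 / (KB_KCAL * spec.temperature)
    rng = np.random.default_rng(spec.seed)

    def biased(x):
        return spec.v(x) + spec.boost(x)

    xs = metropolis_1d(biased, spec.n_samples, beta, spec.mc_step, spec.x0, rng)
    dv = np.asarray(spec.boost(xs), dtype=float)
    return xs, BoostSeries(dv, spec.temperature)
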