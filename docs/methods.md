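# Methods

`surfplast` quantifies where and how much a protein's molecular surface
fluctuates over a conformational ensemble, and whether binding proceeds by
conformational selection. This note documents the models, the defaults and
their rationale, the numerical choices, and what the synthetic validation
does and does not demonstrate.

## Surface plasticity from Gaussian density grids

For every frame *t* of an aligned ensemble a smooth density is built on a
regular grid (isotropic spacing Δ, origin at the ensemble bounding box
minus a padding margin):

    rho_t(x) = sum_i exp( -|x - r_i(t)|^2 / (2 sigma^2) )

with one unit-amplitude Gaussian per atom. The temporal mean grid
describes the typical surface (an isovalue of it renders as a molecular
surface); the temporal standard deviation (SD) grid is high exactly where
the protein sometimes is and sometimes is not — regions alternately
occupied by protein and solvent. A further Gaussian smoothing of the SD
grid suppresses voxel-level noise and emphasizes contiguous regions of
high flexibility. That smoothed SD field is the *surface plasticity* map;
sampling it by trilinear interpolation at each atom's time-averaged
position localizes plasticity per atom, and residue values are the
arithmetic mean over each residue's atoms.

Parameter defaults (all configurable, all echoed into `manifest.json`
because plasticity magnitudes are meaningless without them):

| parameter | default | units | rationale |
|---|---|---|---|
| `kernel_sigma` | 1.5 | Å | heavy-atom scale, comparable to van der Waals radii |
| `spacing` | 0.5 | Å | ≤ sigma/2, keeps the discretized Gaussian integral exact to ≪0.5% |
| `padding` | 6.0 | Å | = 4 sigma, so truncation does not clip boundary density |
| `cutoff_sigmas` | 4 | — | per-axis kernel truncation; <2e-4 of mass lost |
| `smooth_sigma` | 1.5 | Å | one kernel width; large enough to merge per-atom speckle |
| `isovalue` | 0.5 | — | half-maximum of a single unit-amplitude atom |

Choices worth making explicit:

* **Unit amplitude, not a normalized density.** With amplitude 1 per atom
  the isovalue has the same meaning regardless of atom count, so surfaces
  of different systems are directly comparable.
* **Population (1/T) normalization** for the SD grid and RMSF. The frames
  are the complete sample being described, not a draw from which a
  population parameter is estimated.
* **Welford one-pass accumulation** for the mean/SD grids (and RMSF):
  numerically stable for tiny fluctuations on a large mean, and *exactly*
  zero SD for identical frames — the null model is exact, not approximate.
* **Frames are superposed before gridding** (Kabsch on Cα, iterated-mean
  reference, 1e-10 Å convergence, reflections excluded). Gridding an
  unaligned trajectory conflates rigid-body tumbling with plasticity.
  `--no-align` is available for pre-aligned input.
* **Systems to be compared share one grid geometry** (union bounding box)
  so voxels, and therefore plasticity values, correspond one-to-one.
* Kernel truncation is applied per axis (the separable implementation's
  natural box region, which contains the sphere of the same radius).
* All atoms present in the input are gridded; supply a heavy-atom or Cα
  PDB (or a `selection`) to restrict.

## RMSF

After superposition, `rmsf_i = sqrt( (1/T) sum_t |r_i(t) - <r_i>|^2 )`,
per residue the mean over its atoms, exportable as CSV and as a B-factor
PDB for viewer coloring. RMSF and plasticity are complementary: RMSF is
atom-attached (side-chain rotations inflate it without changing the
surface shape), while the SD grid is space-attached and directly reflects
shape fluctuation. No mass weighting.

## Cartesian PCA and free-energy surfaces

PCA is the eigendecomposition of the 3N×3N population covariance of
aligned Cα coordinates, computed by SVD of the centered T×3N matrix.
Component signs are fixed (largest-magnitude element positive) so runs are
reproducible. Free-energy surfaces over 1–2 PCs are

    F(bin) = -ln p(bin)   [units of k_B T],

gauged so the minimum over occupied bins is zero. Empty bins are *flagged*
rather than assigned a sentinel value: a large constant would manufacture
walls and corrupt minima counting.

### gaMD reweighting

Gaussian-accelerated MD adds a harmonic boost ΔV = k/2 (E − V)² whenever
V < E, raising basins and leaving barrier tops untouched. Canonical
populations are recovered by weighting each frame with exp(β ΔV); because
the exponential amplifies the noisiest high-boost frames, the standard
stabilization is a truncated Maclaurin series,

    w_t = sum_{k=0}^{order} (beta DeltaV_t)^k / k! ,

normalized to mean 1. Default order 10 (common gaMD practice); an
exact-exponential mode exists for validation. For ΔV ≥ 0 the raw weights
grow monotonically with order and are bounded by the exponential — both
are tested. k_B = 0.0019872041 kcal/(mol·K), energies kcal/mol,
temperatures K (AMBER conventions).

### Conformational selection

Two statistics:

* `binding_competence`: each free-ensemble frame is Kabsch-fit to the
  bound reference (atom correspondence by chain/resseq/icode/name) and the
  fraction of frames with fitted RMSD ≤ cutoff is reported. The cutoff has
  no defensible universal default and must be supplied; it is always
  echoed in the report.
* `population_shift`: free and bound ensembles are projected onto a PCA
  basis fit to the *concatenated* aligned ensembles (the symmetric choice;
  single-ensemble bases are available) and histogrammed on identical bin
  edges. Reported per PC: the ratio of occupied range (bin positions with
  any F ≤ F_cut, default 3 k_BT) bound/free, and the difference in local
  minima counts. A minimum must have all neighbors (2-neighborhood in 1-D,
  8-neighborhood in 2-D) present, occupied, and strictly higher; plateaus
  and bins at the occupied region's fringe are excluded, which keeps the
  count robust against sparsely sampled tails.

## Synthetic validation data

No microsecond trajectories can ship with the package, so every stage is
validated against generators with analytic ground truth:

* **Harmonic ensembles** — i.i.d. frames around a reference Cα trace
  (ideal helix: 1.5 Å rise, 2.3 Å radius, 100° twist; or extended chain at
  3.8 Å), with per-region isotropic amplitudes plus optional collective
  modes (unit N×3 direction, Gaussian coefficient). The per-atom
  coordinate covariance is σ²I + Σ amp²·outer(mode) by construction, so
  RMSF (σ√3 per atom), plasticity ranking, and PCA mode recovery all have
  closed-form or generator-truth oracles. Frames are uncorrelated in time:
  every analysis here is time-order-invariant, so kinetics would add
  nothing testable.
* **1-D toy gaMD** — Metropolis sampling (Gaussian proposals, default step
  0.5 Å, 10% burn-in, fixed seed) of V(x) + ΔV(x) for a polynomial V. The
  validation system is the double well V = (x²−1)² kcal/mol at 300 K with
  E = 1 kcal/mol (the barrier top, the usual gaMD lower-bound choice) and
  k = 1 (kcal/mol)⁻¹, giving βΔV ≈ 0.84 in the wells — a clearly visible
  bias that order-10 reweighting must undo. The analytic bin-integrated
  Boltzmann distribution of V is the exact oracle for the recovered
  free-energy profile.

What passing these tests shows: the grid statistics, superposition, PCA,
reweighting and selection machinery are quantitatively correct on data
whose truth is known. What they do not show: that the defaults are optimal
for real antibody-antigen ensembles (solvent, anisotropic and temporally
correlated fluctuations, side-chain rotamers are absent from the
generators), nor anything about force-field accuracy — those questions
live upstream of this package.

## Problem sizes used in the shipped validation

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each stochastic check has comfortable statistical margin: T = 10⁴ frames
for closed-form RMSF (2% tolerance vs ~0.4% expected fluctuation),
T = 2000 frames × 100 seeds (suite) or 25 seeds (script) for plasticity
ranking, 2×10⁵ Metropolis samples for barrier recovery (0.5 k_BT tolerance
vs ~0.03 typical error), 10⁶ oracle draws for the competence fraction.

## Known limitations

* Multi-model PDB is the only built-in trajectory reader; convert binary
  formats upstream (e.g. with MDAnalysis/mdtraj) or construct
  `StructureEnsemble` directly from arrays.
* Grids are dense `float64`; at 0.5 Å spacing a 100 Å box is ~8·10⁶
  voxels × 3 grids. Use coarser spacing for very large systems.
* The competence statistic compares whole-selection RMSD; it does not
  decompose which residues block competence.
* Solvent-accessible surfaces, electrostatics and rendering are out of
  scope; grids/meshes export as OpenDX/OBJ for standard viewers.
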