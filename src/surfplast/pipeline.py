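"""End-to-end orchestration: ensembles in, plasticity/RMSF/PCA-FES out.

A run takes one or more labeled ensembles (multi-model PDB, optional gaMD
boost table each, optional bound reference), aligns them, and writes every
analysis product plus a ``manifest.json`` echoing all parameters —
plasticity magnitudes depend on kernel and smoothing widths, so outputs
are only interpretable together with the parameters that made them.

Multi-system runs grid every ensemble on one shared geometry and project
free/bound onto one joint PCA basis, so their plasticity fields and
free-energy surfaces are directly comparable (same voxels, same bins).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grids as g
from .ensemble import StructureEnsemble, pair_ensemble_boost
from .errors import CorrespondenceError
from .grids import PlasticityResult, compute_plasticity, extract_isosurface, grid_geometry
from .io import (
    read_boost_series,
    read_multimodel_pdb,
    residue_table,
    write_bfactor_pdb,
    write_dx_grid,
    write_obj_mesh,
)
from .landscape import (
    FESResult,
    binding_competence,
    fit_pca,
    maclaurin_weights,
    population_shift,
    reweighted_fes,
)
from .superpose import align_ensemble, compute_rmsf

logger = logging.getLogger("surfplast")

MANIFEST_SCHEMA_VERSION = 1


@dataclass
class SystemInput:
    """One labeled ensemble: a multi-model PDB plus optional boost table."""

    label: str
    ensemble: str
    boost: str | None = None


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run (echoed into the manifest)."""

    systems: list[SystemInput]
    reference: str | None = None
    selection: str = "all"
    fit_selection: str = "CA"
    align: bool = True
    frame_stride: int = 1
    kernel_sigma: float = g.DEFAULT_KERNEL_SIGMA
    spacing: float = g.DEFAULT_SPACING
    padding: float = g.DEFAULT_PADDING
    smooth_sigma: float = g.DEFAULT_SMOOTH_SIGMA
    isovalue: float = g.DEFAULT_ISOVALUE
    pca_components: int = 2
    fes_bins: int = 60
    maclaurin_order: int = 10
    temperature: float = 300.0
    competence_cutoff: float | None = None
    f_cut: float = 3.0
    seed: int = 0
    output_dir: str = "surfplast_out"

    def validate(self) -> None:
        if not self.systems:
            raise ValueError("at least one input system is required")
        labels = [s.label for s in self.systems]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate system labels: {labels}")
        for s in self.systems:
            if not Path(s.ensemble).exists():
                raise FileNotFoundError(f"ensemble file not found: {s.ensemble}")
            if s.boost and not Path(s.boost).exists():
                raise FileNotFoundError(f"boost table not found: {s.boost}")
        if self.reference and not Path(self.reference).exists():
            raise FileNotFoundError(f"reference structure not found: {self.reference}")
        if self.reference and self.competence_cutoff is None:
            raise ValueError(
                "competence_cutoff (Angstrom) must be given with a reference; "
                "there is no universally sensible default"
            )
        for name in ("kernel_sigma", "spacing", "padding", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.smooth_sigma < 0 or self.maclaurin_order < 0:
            raise ValueError("smooth_sigma and maclaurin_order must be >= 0")
        if self.frame_stride < 1 or self.pca_components < 1 or self.fes_bins < 2:
            raise ValueError("frame_stride, pca_components, fes_bins out of range")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        systems = [
            SystemInput(**s) if isinstance(s, dict) else SystemInput(*s)
            for s in data.pop("systems", [])
        ]
        return cls(systems=systems, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["systems"] = [asdict(s) for s in self.systems]
        return d


@dataclass
class SystemResult:
    label: str
    ensemble: StructureEnsemble
    plasticity: PlasticityResult
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _stride(ens: StructureEnsemble, stride: int) -> StructureEnsemble:
    if stride == 1:
        return ens
    return StructureEnsemble(
        ens.atoms, ens.coords[::stride], ens.frame_ids[::stride]
    )


def _fes_table(fes: FESResult) -> pd.DataFrame:
    ndim = len(fes.bin_edges)
    centers = [fes.bin_centers(d) for d in range(ndim)]
    mesh = np.meshgrid(*centers, indexing="ij")
    data = {f"pc{d + 1}_center": mesh[d].ravel() for d in range(ndim)}
    data["probability"] = fes.probabilities.ravel()
    data["free_energy_kT"] = fes.free_energy.ravel()
    data["empty"] = fes.empty.ravel()
    return pd.DataFrame(data)


def compare_systems(
    labeled: dict[str, tuple[StructureEnsemble, PlasticityResult]]
) -> pd.DataFrame:
    """Per-residue plasticity deltas/ratios between labeled systems.

    All systems must cover the same residues (their grids must already
    share a geometry for the values to be comparable).  Deltas and ratios
    are reported for every label pair in input order, as
    ``delta_<b>_minus_<a>`` and ``ratio_<b>_over_<a>``.
    """
    if len(labeled) < 2:
        raise ValueError("need at least two systems to compare")
    labels = list(labeled)
    keysets = {lab: set(labeled[lab][1].per_residue) for lab in labels}
    common = set.intersection(*keysets.values())
    union = set.union(*keysets.values())
    if common != union:
        missing = sorted(union - common)
        raise CorrespondenceError(
            f"residue sets differ between systems; unmatched residues: {missing}"
        )

    base_lab = labels[0]
    base_ens = labeled[base_lab][0]
    table = residue_table(
        base_ens, labeled[base_lab][1].per_residue, f"plasticity_{base_lab}"
    ).sort_values(["chain", "resseq", "icode"], kind="stable").reset_index(drop=True)
    keys = list(zip(table["chain"], table["resseq"], table["icode"]))
    for lab in labels[1:]:
        table[f"plasticity_{lab}"] = [labeled[lab][1].per_residue[k] for k in keys]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va, vb = table[f"plasticity_{a}"], table[f"plasticity_{b}"]
            table[f"delta_{b}_minus_{a}"] = vb - va
            with np.errstate(divide="ignore", invalid="ignore"):
                table[f"ratio_{b}_over_{a}"] = np.where(va > 0, vb / va, np.nan)
    return table


def _write_fes_plot(fes: FESResult, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if len(fes.bin_edges) == 1:
        ax.plot(fes.bin_centers(0), fes.free_energy, "-o", ms=2)
        ax.set_xlabel("PC1")
        ax.set_ylabel("F / kT")
    else:
        x, y = fes.bin_centers(0), fes.bin_centers(1)
        masked = np.ma.masked_invalid(fes.free_energy)
        im = ax.contourf(x, y, masked.T, levels=12)
        fig.colorbar(im, ax=ax, label="F / kT")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    multi = len(config.systems) > 1

    loaded = []
    for sysin in config.systems:
        logger.info("reading ensemble %s (%s)", sysin.label, sysin.ensemble)
        ens = read_multimodel_pdb(sysin.ensemble, selection=config.selection)
        ens = _stride(ens, config.frame_stride)
        boost = None
        if sysin.boost:
            boost = read_boost_series(sysin.boost, config.temperature)
            if config.frame_stride > 1:
                boost = type(boost)(
                    boost.delta_v[:: config.frame_stride], boost.temperature
                )
            pair_ensemble_boost(ens, boost)
        if config.align:
            ens = align_ensemble(ens, "mean", config.fit_selection)
        loaded.append((sysin.label, ens, boost))

    geometry = None
    if multi:
        geometry = grid_geometry(
            [e.coords.reshape(-1, 3) for _, e, _ in loaded],
            spacing=config.spacing,
            padding=config.padding,
        )

    reference = (
        read_multimodel_pdb(config.reference, selection=config.selection)
        if config.reference
        else None
    )

    results: dict[str, SystemResult] = {}
    pca_inputs: dict[str, StructureEnsemble] = {}
    for label, ens, boost in loaded:
        d = outdir / label if multi else outdir
        d.mkdir(parents=True, exist_ok=True)
        res = SystemResult(label=label, ensemble=ens, plasticity=None)  # type: ignore[arg-type]

        logger.info("[%s] plasticity grids", label)
        stats, plast = compute_plasticity(
            ens,
            kernel_sigma=config.kernel_sigma,
            spacing=config.spacing,
            padding=config.padding,
            smooth_sigma=config.smooth_sigma,
            isovalue=config.isovalue,
            geometry=geometry,
        )
        res.plasticity = plast
        write_dx_grid(stats.mean, d / "mean.dx")
        write_dx_grid(stats.sd, d / "sd.dx")
        write_dx_grid(plast.smoothed_sd, d / "sd_smoothed.dx")
        residue_table(ens, plast.per_residue, "plasticity").to_csv(
            d / "plasticity_per_residue.csv", index=False
        )
        write_bfactor_pdb(ens, plast.per_atom, d / "plasticity_bfactor.pdb")
        vmin, vmax = stats.mean.values.min(), stats.mean.values.max()
        if vmin < config.isovalue < vmax:
            verts, faces = extract_isosurface(stats.mean, config.isovalue)
            write_obj_mesh(verts, faces, d / "mean_surface.obj")

        if ens.n_frames >= 2:
            rmsf = compute_rmsf(ens)
            df = residue_table(ens, rmsf.per_residue, "rmsf_A")
            df.to_csv(d / "rmsf.csv", index=False)
            write_bfactor_pdb(ens, rmsf.per_atom, d / "rmsf_bfactor.pdb")
            res.summary["mean_rmsf_A"] = float(rmsf.per_atom.mean())

            ca = ens.select(config.fit_selection)
            pca_inputs[label] = ca
            k = min(config.pca_components, ca.n_frames - 1, 3 * ca.n_atoms)
            pca = fit_pca(ca, k)
            pd.DataFrame(
                pca.projections, columns=[f"pc{j + 1}" for j in range(k)]
            ).to_csv(d / "pca_projections.csv", index=False)
            res.summary["pca_eigenvalues_A2"] = [float(v) for v in pca.eigenvalues]

            ndim = min(2, k)
            fes = reweighted_fes(
                pca.projections[:, :ndim], bins=config.fes_bins, maclaurin_order=None
            )
            _fes_table(fes).to_csv(d / "fes.csv", index=False)
            _write_fes_plot(fes, d / "fes.png", f"{label}: unweighted")
            if boost is not None:
                w = maclaurin_weights(boost, config.maclaurin_order)
                fes_rw = reweighted_fes(
                    pca.projections[:, :ndim],
                    weights=w,
                    bins=config.fes_bins,
                    maclaurin_order=config.maclaurin_order,
                )
                _fes_table(fes_rw).to_csv(d / "fes_reweighted.csv", index=False)
                _write_fes_plot(
                    fes_rw, d / "fes_reweighted.png", f"{label}: reweighted"
                )

        if reference is not None:
            report = binding_competence(
                ens,
                reference,
                cutoff=config.competence_cutoff,
                fit_selection=config.fit_selection,
            )
            sel = {
                "competent_fraction": report.competent_fraction,
                "cutoff_A": report.cutoff,
                "mean_rmsd_A": float(report.rmsd_to_reference.mean()),
                "n_frames": int(report.rmsd_to_reference.size),
            }
            (d / "selection_report.json").write_text(
                json.dumps(sel, indent=2, sort_keys=True)
            )
            res.summary["selection"] = sel

        res.summary["mean_plasticity"] = float(np.mean(list(plast.per_residue.values())))
        res.outputs = {p.name: str(p) for p in sorted(d.iterdir()) if p.is_file()}
        results[label] = res

    manifest: dict = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "parameters": config.to_dict(),
        "shared_grid_geometry": (
            {"origin_A": list(map(float, geometry[0])), "dims": list(geometry[1])}
            if geometry
            else None
        ),
        "systems": {
            lab: {"outputs": r.outputs, "summary": r.summary}
            for lab, r in results.items()
        },
    }

    if multi:
        comparison: dict = {}
        table = compare_systems(
            {lab: (r.ensemble, r.plasticity) for lab, r in results.items()}
        )
        table.to_csv(outdir / "plasticity_comparison.csv", index=False)
        comparison["per_residue_csv"] = str(outdir / "plasticity_comparison.csv")
        comparison["global_mean_plasticity"] = {
            lab: r.summary["mean_plasticity"] for lab, r in results.items()
        }

        if len(pca_inputs) == 2:
            (lab_a, ens_a), (lab_b, ens_b) = pca_inputs.items()
            if ens_a.n_atoms == ens_b.n_atoms:
                joint = StructureEnsemble(
                    ens_a.atoms,
                    np.concatenate([ens_a.coords, ens_b.coords]),
                )
                k = min(2, joint.n_frames - 1, 3 * joint.n_atoms)
                jpca = fit_pca(joint, k)
                proj_a = jpca.project(ens_a.coords)[:, :k]
                proj_b = jpca.project(ens_b.coords)[:, :k]
                both = np.concatenate([proj_a, proj_b])
                edges = [
                    np.linspace(both[:, j].min(), both[:, j].max(), config.fes_bins + 1)
                    for j in range(k)
                ]
                fes_a = reweighted_fes(proj_a, bin_edges=edges, maclaurin_order=None)
                fes_b = reweighted_fes(proj_b, bin_edges=edges, maclaurin_order=None)
                shift = population_shift(fes_a, fes_b, f_cut=config.f_cut)
                comparison["population_shift"] = {
                    "basis": f"joint PCA ({lab_a} + {lab_b})",
                    "labels": [lab_a, lab_b],
                    "range_ratio_per_pc": shift.range_ratio,
                    "occupied_bins": {
                        lab_a: shift.occupied_bins_free,
                        lab_b: shift.occupied_bins_bound,
                    },
                    "minima": {lab_a: shift.minima_free, lab_b: shift.minima_bound},
                    "minima_difference": shift.minima_difference,
                    "f_cut_kT": shift.f_cut,
                }
            else:
                comparison["population_shift"] = {
                    "skipped": "systems have different atom counts; no joint basis"
                }
        manifest["comparison"] = comparison

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
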