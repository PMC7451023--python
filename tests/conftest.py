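"""Shared fixtures: tiny PDB texts and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from surfplast import StructureEnsemble, make_reference_structure
from surfplast.ensemble import AtomRecord


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element):
    """One correctly-columned PDB ATOM record (v3.3 fixed columns)."""
    name_fmt = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_fmt} {resname:<3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


@pytest.fixture
def two_model_pdb(tmp_path):
    """2 MODELs x 3 atoms (N, CA, C of one residue)."""
    lines = []
    for m, shift in ((1, 0.0), (2, 1.0)):
        lines.append(f"MODEL     {m:>4d}")
        lines.append(pdb_atom_line(1, "N", "ALA", "A", 1, 0.0 + shift, 0.0, 0.0, "N"))
        lines.append(pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5 + shift, 0.0, 0.0, "C"))
        lines.append(pdb_atom_line(3, "C", "ALA", "A", 1, 2.9 + shift, 0.5, 0.0, "C"))
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def gaussian_ensemble(n_atoms=20, n_frames=100, sigma=0.5, seed=0, geometry="helix"):
    """Reference structure plus i.i.d. isotropic Gaussian noise per coordinate."""
    ref = make_reference_structure(n_atoms, geometry)
    rng = np.random.default_rng(seed)
    coords = ref.coords[0][None] + sigma * rng.standard_normal((n_frames, n_atoms, 3))
    return StructureEnsemble(ref.atoms, coords)


def static_ensemble(n_atoms=10, n_frames=5, geometry="helix"):
    """Identical frames: the null model for every fluctuation measure."""
    ref = make_reference_structure(n_atoms, geometry)
    coords = np.repeat(ref.coords, n_frames, axis=0)
    return StructureEnsemble(ref.atoms, coords)


def single_atom_ensemble(positions):
    """T frames of one CA atom at the given positions."""
    atoms = [
        AtomRecord(serial=1, name="CA", residue_name="ALA", chain_id="A",
                   residue_seq=1, element="C")
    ]
    coords = np.asarray(positions, dtype=float).reshape(-1, 1, 3)
    return StructureEnsemble(atoms, coords)
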