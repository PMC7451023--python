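"""Reading and writing the package's external formats.

Multi-model PDB is the one mandatory trajectory format (one MODEL per
frame); grids go out as OpenDX scalar fields via GridDataFormats; gaMD
boost energies come from a plain-text table (one DeltaV per line, ``#``
comments); per-residue reports are CSV; meshes are Wavefront OBJ.

The PDB reader is deliberately strict about the contracts downstream code
relies on: atom order is preserved exactly as in the file, every MODEL must
contain the same atoms, and malformed records fail with their line number.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from gridData import Grid as _DXGrid

from .ensemble import AtomRecord, BoostSeries, StructureEnsemble
from .errors import PDBParseError, StructureMismatchError
from .grids import ScalarGrid

# ---------------------------------------------------------------------------
# multi-model PDB


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, tuple[float, float, float]]:
    # PDB v3.3 fixed columns (0-based slices).
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        res_seq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparseable ATOM/HETATM record: {exc}", lineno) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    if not element:
        raise PDBParseError(f"cannot determine element for atom {serial!r}", lineno)
    record = AtomRecord(
        serial=serial,
        name=name,
        residue_name=res_name,
        chain_id=chain_id,
        residue_seq=res_seq,
        element=element,
        icode=icode,
    )
    return record, (x, y, z)


def read_multimodel_pdb(path: str | os.PathLike, selection: str = "all") -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    One frame per MODEL record; a file without MODEL records yields a
    single-frame ensemble.  ``selection`` is "all" or an atom name such as
    "CA".  Atom order is preserved as in the file.

    Raises
    ------
    StructureMismatchError
        if any MODEL's atoms differ (count or identity) from the first.
    PDBParseError
        on an unparseable ATOM/HETATM record, with the line number.
    """
    frames: list[list[tuple[AtomRecord, tuple[float, float, float]]]] = []
    frame_ids: list[int] = []
    current: list[tuple[AtomRecord, tuple[float, float, float]]] | None = None
    saw_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current:
                    frames.append(current)
                current = []
                try:
                    frame_ids.append(int(line[6:].split()[0]))
                except (ValueError, IndexError):
                    frame_ids.append(len(frames) + 1)
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                    if not saw_model:
                        frame_ids.append(1)
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
    if current:
        frames.append(current)

    if not frames or not frames[0]:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")

    atoms = [rec for rec, _ in frames[0]]
    identity = [(a.chain_id, a.residue_seq, a.icode, a.name) for a in atoms]
    for k, frame in enumerate(frames[1:], start=2):
        model_id = frame_ids[k - 1] if k - 1 < len(frame_ids) else k
        if len(frame) != len(atoms):
            raise StructureMismatchError(
                f"MODEL {model_id} has {len(frame)} atoms, expected {len(atoms)}"
            )
        ident_k = [(r.chain_id, r.residue_seq, r.icode, r.name) for r, _ in frame]
        if ident_k != identity:
            raise StructureMismatchError(
                f"MODEL {model_id} atom identities differ from MODEL {frame_ids[0]}"
            )

    coords = np.array(
        [[xyz for _, xyz in frame] for frame in frames], dtype=float
    )
    ens = StructureEnsemble(atoms, coords, frame_ids[: len(frames)])
    if selection != "all":
        ens = ens.select(selection)
    return ens


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {elem:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    # Names of 1-3 chars start in column 14 (PDB convention).
    return f" {name:<3s}" if len(name) < 4 else name


def _write_frame(fh, atoms: Sequence[AtomRecord], xyz: np.ndarray, bfac: np.ndarray):
    for a, (x, y, z), b in zip(atoms, xyz, bfac):
        fh.write(
            _PDB_ATOM_FMT.format(
                serial=a.serial % 100000,
                name=_format_atom_name(a.name),
                alt=" ",
                res=a.residue_name[:3],
                chain=(a.chain_id or " ")[:1],
                resseq=a.residue_seq % 10000,
                icode=(a.icode or " ")[:1],
                x=x, y=y, z=z,
                occ=1.0,
                b=b,
                elem=a.element[:2],
            )
        )


def write_multimodel_pdb(ensemble: StructureEnsemble, path: str | os.PathLike) -> None:
    """Write every frame of the ensemble as one MODEL block."""
    zeros = np.zeros(ensemble.n_atoms)
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"MODEL     {ensemble.frame_ids[t]:>4d}\n")
            _write_frame(fh, ensemble.atoms, ensemble.coords[t], zeros)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_bfactor_pdb(
    ensemble: StructureEnsemble,
    per_atom_values: np.ndarray,
    path: str | os.PathLike,
) -> None:
    """Write frame 0 with per-atom values in the B-factor column.

    Values are clamped to [0, 999.99] so they survive the %6.2f field; this
    is the standard vehicle for projecting RMSF or plasticity onto a
    structure for molecular viewers.
    """
    values = np.asarray(per_atom_values, dtype=float).ravel()
    if values.shape != (ensemble.n_atoms,):
        raise ValueError(
            f"got {values.size} values for {ensemble.n_atoms} atoms"
        )
    clamped = np.clip(values, 0.0, 999.99)
    with open(path, "w") as fh:
        _write_frame(fh, ensemble.atoms, ensemble.coords[0], clamped)
        fh.write("END\n")


# ---------------------------------------------------------------------------
# boost-energy tables


def read_boost_series(path: str | os.PathLike, temperature: float) -> BoostSeries:
    """Read a plain-text gaMD boost table: one DeltaV (kcal/mol) per line.

    Blank lines and ``#`` comments are skipped.  Negative energies are
    rejected (the gaMD harmonic boost is non-negative by construction).
    """
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: not a number: {line!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}, line {lineno}: negative boost potential {v}"
                )
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no boost energies found")
    return BoostSeries(np.asarray(values), temperature)


def write_boost_series(boost: BoostSeries, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gaMD boost potential DeltaV, kcal/mol, T={boost.temperature} K\n")
        for v in boost.delta_v:
            fh.write(f"{v:.8f}\n")


# ---------------------------------------------------------------------------
# OpenDX grids (via GridDataFormats)


def write_dx_grid(grid: ScalarGrid, path: str | os.PathLike) -> None:
    """Export a scalar grid as an OpenDX file readable by PyMOL/VMD/Chimera."""
    if min(grid.dims) < 1:
        raise ValueError(f"grid dims must all be >= 1, got {grid.dims}")
    g = _DXGrid(grid.values, origin=np.asarray(grid.origin), delta=grid.spacing)
    g.export(str(path), file_format="dx")


def read_dx_grid(path: str | os.PathLike) -> ScalarGrid:
    """Read an OpenDX scalar field written by :func:`write_dx_grid`."""
    g = _DXGrid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError(f"anisotropic grid spacing {delta} not supported")
    return ScalarGrid(origin=np.asarray(g.origin, dtype=float),
                      spacing=float(delta[0]),
                      values=np.asarray(g.grid, dtype=float))


# ---------------------------------------------------------------------------
# meshes and tables


def write_obj_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | os.PathLike) -> None:
    """Write a triangle mesh as Wavefront OBJ (1-based face indices)."""
    with open(path, "w") as fh:
        for v in np.asarray(vertices, dtype=float):
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in np.asarray(faces, dtype=int):
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def residue_table(
    ensemble: StructureEnsemble, per_residue: dict, value_name: str
) -> pd.DataFrame:
    """Tabulate a per-residue map as (chain, resseq, icode, resname, value)."""
    resnames = {}
    for a in ensemble.atoms:
        resnames.setdefault(a.residue_key, a.residue_name)
    rows = [
        {
            "chain": key[0],
            "resseq": key[1],
            "icode": key[2],
            "resname": resnames.get(key, ""),
            value_name: value,
        }
        for key, value in per_residue.items()
    ]
    return pd.DataFrame(rows)
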