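"""Coordinate-file and table I/O.

Multi-model PDB reading/writing is delegated to biotite; this module maps
between biotite's atom arrays and the package's own
:class:`~surfdyn.core.MolecularSystem` / :class:`~surfdyn.core.Trajectory`
types, assigns per-element van der Waals radii and masses, and defines the
plain-text "XYZ-table" trajectory dialect used for synthetic-data interchange
(one line per atom per frame: frame, atom_index, x, y, z; tab-delimited with
a header).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    Atom,
    MolecularSystem,
    Residue,
    Trajectory,
    residue_key,
)
from .tables import ATOMIC_MASSES, VDW_RADII


def _scan_model_atom_counts(path: str | Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (cheap text pre-scan)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM", "HETATM")):
                current += 1
    if not saw_model:
        return [current]
    if in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def _lookup(table: Mapping[str, float], element: str, kind: str,
            fallback: float | None) -> float:
    try:
        return table[element.upper()]
    except KeyError:
        if fallback is not None:
            return fallback
        raise ValueError(
            f"unknown element {element!r}: no {kind} available and no "
            f"fallback configured"
        ) from None


def system_from_atom_array(
    array: "struc.AtomArray",
    name: str = "",
    radius_table: Mapping[str, float] | None = None,
    fallback_radius: float | None = None,
) -> MolecularSystem:
    """Build a MolecularSystem from a biotite AtomArray (one frame)."""
    radius_table = dict(VDW_RADII if radius_table is None else radius_table)
    if np.any(array.ins_code != ""):
        bad = int(np.flatnonzero(array.ins_code != "")[0])
        raise ValueError(
            f"insertion-coded residue at atom {bad} "
            f"({array.chain_id[bad]}:{array.res_id[bad]}{array.ins_code[bad]}): "
            "insertion codes are not supported"
        )
    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i])
        atoms.append(
            Atom(
                index=i,
                name=str(array.atom_name[i]),
                element=element,
                residue_key=residue_key(str(array.chain_id[i]), int(array.res_id[i])),
                vdw_radius=_lookup(radius_table, element, "vdW radius", fallback_radius),
                mass=ATOMIC_MASSES.get(element.upper(), 12.011),
            )
        )
    residues = []
    res_starts = struc.get_residue_starts(array, add_exclusive_stop=True)
    for s, e in zip(res_starts[:-1], res_starts[1:]):
        residues.append(
            Residue(
                key=residue_key(str(array.chain_id[s]), int(array.res_id[s])),
                name=str(array.res_name[s]),
                atom_indices=tuple(range(int(s), int(e))),
            )
        )
    return MolecularSystem(atoms=tuple(atoms), residues=tuple(residues), name=name)


def read_multi_model_pdb(
    path: str | Path,
    radius_table: Mapping[str, float] | None = None,
    fallback_radius: float | None = None,
    ignore_hydrogens: bool = False,
    frame_spacing_ns: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB into a Trajectory.

    Every MODEL must contain the same atoms in the same order. Radii are
    assigned per element from ``radius_table`` (Bondi-style defaults); an
    unknown element is a hard error unless ``fallback_radius`` is given.
    Times default to the frame index times ``frame_spacing_ns``.
    """
    path = Path(path)
    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts) if c != ref)
        raise ValueError(
            f"inconsistent atom count in MODEL {bad + 1}: "
            f"{counts[bad]} atoms, expected {ref}"
        )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="first")
    if ignore_hydrogens:
        keep = stack.element != "H"
        stack = stack[..., keep]
    frame0 = stack[0]
    system = system_from_atom_array(
        frame0, name=path.stem, radius_table=radius_table,
        fallback_radius=fallback_radius,
    )
    coords = np.asarray(stack.coord, dtype=float)
    times = np.arange(coords.shape[0], dtype=float) * frame_spacing_ns
    return Trajectory(system=system, coordinates=coords, times=times, label=path.stem)


def _atom_array_from_system(system: MolecularSystem) -> "struc.AtomArray":
    n = system.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3), dtype=np.float32)
    array.chain_id = system.chain_ids.astype("U4")
    array.res_id = system.res_ids
    res_names = np.empty(n, dtype="U5")
    for res in system.residues:
        for i in res.atom_indices:
            res_names[i] = res.name
    array.res_name = res_names
    array.atom_name = system.atom_names.astype("U6")
    array.element = np.array([a.element for a in system.atoms], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    return array


def write_multi_model_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a MODEL/ENDMDL multi-model PDB."""
    template = _atom_array_from_system(trajectory.system)
    stack = struc.AtomArrayStack(trajectory.n_frames, trajectory.n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = trajectory.coordinates.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_xyz_table(trajectory: Trajectory, path: str | Path,
                    float_digits: int = 6) -> None:
    """Write the plain-text per-atom-per-frame dialect (frame, atom_index, x, y, z)."""
    n_frames, n_atoms, _ = trajectory.coordinates.shape
    frames = np.repeat(np.arange(n_frames), n_atoms)
    atom_idx = np.tile(np.arange(n_atoms), n_frames)
    flat = trajectory.coordinates.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frames, "atom_index": atom_idx,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_xyz_table(path: str | Path, system: MolecularSystem,
                   frame_spacing_ns: float = 1.0, label: str = "") -> Trajectory:
    """Read the XYZ-table dialect back into a Trajectory bound to ``system``."""
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "atom_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"XYZ-table is missing columns: {sorted(required - set(df.columns))}"
        )
    n_frames = int(df["frame"].max()) + 1
    n_atoms = system.n_atoms
    if len(df) != n_frames * n_atoms:
        raise ValueError(
            f"XYZ-table has {len(df)} rows, expected {n_frames * n_atoms} "
            f"({n_frames} frames x {n_atoms} atoms)"
        )
    df = df.sort_values(["frame", "atom_index"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(n_frames, n_atoms, 3)
    times = np.arange(n_frames, dtype=float) * frame_spacing_ns
    return Trajectory(system=system, coordinates=coords, times=times,
                      label=label or Path(path).stem)


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                float_digits: int = 6) -> None:
    """Write flat rows as a tab-delimited table with a header line.

    An empty record list still produces a header-only file when a DataFrame
    (which carries its columns) is passed; an empty plain list produces an
    empty file with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
        if df.empty and not len(df.columns):
            warnings.warn("writing table with no rows and unknown columns")
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_two_column_table(path: str | Path) -> dict[str, float]:
    """Read a two-column text table (key, value) such as a radius or
    max-SASA override file. '#' starts a comment; blank lines are ignored."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            out[parts[0]] = float(parts[1])
    return out
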