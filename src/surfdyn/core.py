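"""Topology and trajectory data model, atom selections, complex partitioning.

A :class:`MolecularSystem` is the static topology (atoms grouped into
residues, with per-atom radii and masses); a :class:`Trajectory` attaches a
``(frames, atoms, 3)`` coordinate array with a time axis in nanoseconds.
Selections are sorted, unique index masks produced by a small expression
language (``name CA``, ``chain A``, ``resid 23-186``, combined with
``and`` / ``or`` / ``not`` and parentheses).

Units: Angstrom for coordinates and radii, nanoseconds for time, Dalton for
masses. Atom indices are 0-based throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np


class SelectionError(ValueError):
    """Raised for malformed selection expressions; carries the position."""


def residue_key(chain_id: str, res_id: int) -> str:
    """Canonical residue key, e.g. ``"A:42"``."""
    return f"{chain_id}:{res_id}"


def split_residue_key(key: str) -> tuple[str, int]:
    chain, _, num = key.rpartition(":")
    return chain, int(num)


@dataclass(frozen=True)
class Atom:
    """One atom: identity, residue membership, vdW radius (A), mass (Da)."""

    index: int
    name: str
    element: str
    residue_key: str
    vdw_radius: float
    mass: float

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.index}: element must be non-empty")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")
        if not self.mass > 0:
            raise ValueError(f"atom {self.index}: mass must be > 0")


@dataclass(frozen=True)
class Residue:
    """A residue: key ("chain:resid"), 3-letter name, member atom indices."""

    key: str
    name: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atom_indices) == 0:
            raise ValueError(f"residue {self.key}: atom_indices must be non-empty")


@dataclass(frozen=True)
class MolecularSystem:
    """Static topology: ordered atoms partitioned into ordered residues."""

    atoms: tuple[Atom, ...]
    residues: tuple[Residue, ...]
    name: str = ""

    def __post_init__(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be contiguous 0..N-1 in order")
        seen: set[int] = set()
        for res in self.residues:
            overlap = seen.intersection(res.atom_indices)
            if overlap:
                raise ValueError(
                    f"atom {min(overlap)} belongs to more than one residue"
                )
            seen.update(res.atom_indices)
        if seen != set(indices):
            missing = sorted(set(indices) - seen)
            raise ValueError(f"atoms not assigned to any residue: {missing[:5]}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @cached_property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @cached_property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @cached_property
    def atom_names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms], dtype=object)

    @cached_property
    def chain_ids(self) -> np.ndarray:
        return np.array(
            [split_residue_key(a.residue_key)[0] for a in self.atoms], dtype=object
        )

    @cached_property
    def res_ids(self) -> np.ndarray:
        return np.array(
            [split_residue_key(a.residue_key)[1] for a in self.atoms], dtype=int
        )

    @cached_property
    def residue_index_of_atom(self) -> np.ndarray:
        """For each atom, the index of its residue in ``self.residues``."""
        out = np.empty(self.n_atoms, dtype=int)
        for ri, res in enumerate(self.residues):
            out[list(res.atom_indices)] = ri
        return out

    @cached_property
    def residue_keys(self) -> list[str]:
        return [r.key for r in self.residues]

    @cached_property
    def residue_names(self) -> dict[str, str]:
        return {r.key: r.name for r in self.residues}

    def residue_by_key(self, key: str) -> Residue:
        for res in self.residues:
            if res.key == key:
                return res
        raise KeyError(key)


@dataclass(frozen=True)
class Trajectory:
    """Frames x atoms x 3 coordinates (A) with a strictly increasing time axis (ns)."""

    system: MolecularSystem
    coordinates: np.ndarray
    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "times", times)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if coords.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} != system "
                f"atom count {self.system.n_atoms}"
            )
        if coords.shape[0] != times.shape[0]:
            raise ValueError("times length must equal number of frames")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class SelectionMask:
    """Sorted unique atom indices into a system of ``n_atoms`` atoms."""

    indices: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_atoms):
            raise ValueError("selection indices out of range for system")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def boolean(self) -> np.ndarray:
        out = np.zeros(self.n_atoms, dtype=bool)
        out[self.indices] = True
        return out

    def union(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(np.union1d(self.indices, other.indices), self.n_atoms)

    def intersection(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(np.intersect1d(self.indices, other.indices), self.n_atoms)

    def difference(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(np.setdiff1d(self.indices, other.indices), self.n_atoms)

    def complement(self) -> "SelectionMask":
        return SelectionMask(
            np.setdiff1d(np.arange(self.n_atoms), self.indices), self.n_atoms
        )

    def _check(self, other: "SelectionMask") -> None:
        if other.n_atoms != self.n_atoms:
            raise ValueError("masks refer to systems of different sizes")


@dataclass(frozen=True)
class ComplexPartition:
    """Disjoint receptor / partner atom masks covering the SASA-relevant atoms."""

    receptor_mask: SelectionMask
    partner_mask: SelectionMask

    def __post_init__(self) -> None:
        if np.intersect1d(
            self.receptor_mask.indices, self.partner_mask.indices
        ).size:
            raise ValueError("receptor and partner masks must be disjoint")


# ---------------------------------------------------------------------------
# Selection expression language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_'\*:\-]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip() == "":
                break
            raise SelectionError(
                f"unexpected character {expression[pos]!r} at position {pos}"
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the selection grammar.

    expr    := term ('or' term)*
    term    := factor ('and' factor)*
    factor  := 'not' factor | '(' expr ')' | primary
    primary := 'all' | 'name' WORD+ | 'chain' WORD+ | 'resid' RANGE+
    """

    _KEYWORDS = {"and", "or", "not", "name", "chain", "resid", "all", "(", ")"}

    def __init__(self, system: MolecularSystem, expression: str):
        self.system = system
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of expression at position {len(self.expression)}"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        result = self._expr()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(f"unexpected token {tok!r} at position {pos}")
        return result

    def _expr(self) -> np.ndarray:
        out = self._term()
        while self._peek() == "or":
            self._next()
            out = out | self._term()
        return out

    def _term(self) -> np.ndarray:
        out = self._factor()
        while self._peek() == "and":
            self._next()
            out = out & self._factor()
        return out

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            out = self._expr()
            nxt, pos = self._next() if self.i < len(self.tokens) else (None, -1)
            if nxt != ")":
                raise SelectionError(f"expected ')' at position {pos}")
            return out
        return self._primary()

    def _values(self) -> list[tuple[str, int]]:
        vals = []
        while True:
            tok = self._peek()
            if tok is None or tok in self._KEYWORDS:
                break
            vals.append(self._next())
        return vals

    def _primary(self) -> np.ndarray:
        tok, pos = self._next()
        sysm = self.system
        if tok == "all":
            return np.ones(sysm.n_atoms, dtype=bool)
        if tok == "name":
            vals = self._values()
            if not vals:
                raise SelectionError(f"'name' needs at least one value near {pos}")
            names = {v for v, _ in vals}
            return np.isin(sysm.atom_names, list(names))
        if tok == "chain":
            vals = self._values()
            if not vals:
                raise SelectionError(f"'chain' needs at least one value near {pos}")
            chains = {v for v, _ in vals}
            return np.isin(sysm.chain_ids, list(chains))
        if tok == "resid":
            vals = self._values()
            if not vals:
                raise SelectionError(f"'resid' needs at least one value near {pos}")
            out = np.zeros(sysm.n_atoms, dtype=bool)
            for v, vpos in vals:
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if m is None:
                    raise SelectionError(
                        f"bad residue range {v!r} at position {vpos}"
                    )
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                out |= (sysm.res_ids >= lo) & (sysm.res_ids <= hi)
            return out
        raise SelectionError(f"unknown keyword {tok!r} at position {pos}")


def select(system: MolecularSystem, expression: str) -> SelectionMask:
    """Evaluate a selection expression to a sorted, unique atom mask.

    An empty result is legal but raises a ``UserWarning`` since it is usually
    a sign of a mistyped chain id or residue range.
    """
    boolean = _Parser(system, expression).parse()
    mask = SelectionMask(np.flatnonzero(boolean), system.n_atoms)
    if len(mask) == 0:
        warnings.warn(
            f"selection {expression!r} matched no atoms", UserWarning, stacklevel=2
        )
    return mask


def partition_complex(
    system: MolecularSystem, partner_chains: Iterable[str]
) -> ComplexPartition:
    """Split a complex into receptor (complement) and partner (given chains)."""
    partner_chains = list(partner_chains)
    present = set(system.chain_ids.tolist())
    missing = [c for c in partner_chains if c not in present]
    if missing:
        raise ValueError(f"partner chain(s) not present in system: {missing}")
    partner_bool = np.isin(system.chain_ids, partner_chains)
    if partner_bool.all():
        raise ValueError("partner chains cover every atom; no receptor left")
    partner = SelectionMask(np.flatnonzero(partner_bool), system.n_atoms)
    receptor = partner.complement()
    return ComplexPartition(receptor_mask=receptor, partner_mask=partner)


def subset_system(system: MolecularSystem, mask: SelectionMask) -> MolecularSystem:
    """New system containing only the masked atoms (indices renumbered).

    Residues losing all atoms are dropped; residues losing some atoms keep
    the remaining ones.
    """
    old_to_new = {old: new for new, old in enumerate(mask.indices.tolist())}
    atoms = tuple(
        Atom(
            index=old_to_new[a.index],
            name=a.name,
            element=a.element,
            residue_key=a.residue_key,
            vdw_radius=a.vdw_radius,
            mass=a.mass,
        )
        for a in (system.atoms[i] for i in mask.indices)
    )
    residues = []
    for res in system.residues:
        kept = tuple(old_to_new[i] for i in res.atom_indices if i in old_to_new)
        if kept:
            residues.append(Residue(key=res.key, name=res.name, atom_indices=kept))
    return MolecularSystem(atoms=atoms, residues=tuple(residues), name=system.name)
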