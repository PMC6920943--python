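"""Synthetic receptor/partner ensembles with planted, verifiable ground truth.

Real binding studies of a multi-domain receptor rest on trajectories that
are rarely shareable; this generator reproduces the *statistical structure*
those analyses assume — nothing more (no force field, no solvent):

* a toy receptor whose residues are small rigid bead clusters (one central
  "CA" bead plus three satellites) laid out on a self-avoiding spherical
  spiral, with a few tightly packed core residues that are mainly buried;
* a rigid bead partner placed to physically occlude a chosen set of
  surface residues (**planted interfacial** residues);
* a bound-state-only conformational change of another residue set,
  calibrated by bisection against the SASA engine so the realized
  relative-SASA change matches a signed target in percentage points
  (**planted allosteric** residues);
* block-correlated rigid domain motions driven by jointly Gaussian latent
  scalars with prescribed correlation, plus isotropic positional noise —
  giving the cross-correlation analysis an analytically known target.

Identical spec (including seed) gives bit-identical ensembles; replicate
streams are derived with ``numpy.random.SeedSequence([seed, stream, rep])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import Atom, MolecularSystem, Residue, Trajectory, residue_key
from .equilibration import ReplicateEnsemble
from .sasa import atom_sasa, sphere_points
from .tables import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS

_BEAD_RADIUS = 1.70  # carbon-like beads throughout
_BEAD_MASS = 12.011
_CA_SPACING = 7.5  # target neighbour spacing of surface residues (A)
_SAT_OFFSET = 2.2  # satellite bead distance from the CA bead (A)
_INNER_SAT_OFFSET = 1.8
_CORE_SAT_OFFSET = 1.5
_FRAME_SPACING_NS = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic study (receptor, partner, dynamics).

    ``domain_blocks`` are half-open residue-index ranges with a label; only
    blocks named in ``moving_blocks`` (default: those appearing in the
    ``correlation_plan``) are displaced. ``planted_allosteric`` maps residue
    index -> signed target change of relative SASA in percentage points,
    realized only in the bound state.

    Residues are laid out in three layers: a surface shell (indices
    ``0 .. n - n_inner - n_core``), an inner layer whose satellites point
    inward, and the last ``n_core`` residues packed at the centre and
    occluded by the inner layer (relative SASA below the 20 % burial line).
    Planted residues must be shell residues.
    """

    n_residues_receptor: int = 30
    domain_blocks: tuple[tuple[int, int, str], ...] = (
        (0, 6, "D1"),
        (12, 18, "D2"),
    )
    planted_interfacial: tuple[int, ...] = (8, 9)
    planted_allosteric: Mapping[int, float] = field(
        default_factory=lambda: {6: -10.0, 11: 10.0}
    )
    correlation_plan: tuple[tuple[str, str, float], ...] = (("D1", "D2", 0.9),)
    moving_blocks: tuple[str, ...] | None = None
    noise_sigma: float = 0.1
    block_amplitude: float = 1.0
    n_frames: int = 2000
    n_replicates: int = 4
    n_inner: int = 9
    n_core: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_allosteric", dict(self.planted_allosteric)
        )
        n = self.n_residues_receptor
        if n < 4:
            raise ValueError("need at least 4 receptor residues")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_core < 0 or self.n_inner < 0 or self.n_core + self.n_inner >= n:
            raise ValueError("n_core/n_inner leave no surface shell")
        inter = set(self.planted_interfacial)
        allo = set(self.planted_allosteric)
        if inter & allo:
            raise ValueError("planted interfacial and allosteric sets overlap")
        n_shell = n - self.n_core - self.n_inner
        for idx in inter | allo:
            if not 0 <= idx < n_shell:
                raise ValueError(
                    f"planted residue index {idx} is not a surface-shell residue "
                    f"(shell is 0..{n_shell - 1})"
                )
        labels = [lab for _, _, lab in self.domain_blocks]
        if len(labels) != len(set(labels)):
            raise ValueError("block labels must be unique")
        covered: set[int] = set()
        for start, stop, lab in self.domain_blocks:
            if not 0 <= start < stop <= n:
                raise ValueError(f"block {lab}: bad range ({start}, {stop})")
            if covered & set(range(start, stop)):
                raise ValueError(f"block {lab} overlaps another block")
            covered.update(range(start, stop))
        for a, b, rho in self.correlation_plan:
            if a not in labels or b not in labels:
                raise ValueError(f"correlation plan names unknown block: {a}, {b}")
            if a == b:
                raise ValueError("correlation plan entries must pair distinct blocks")
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
        if self.moving_blocks is not None:
            for lab in self.moving_blocks:
                if lab not in labels:
                    raise ValueError(f"moving_blocks names unknown block: {lab}")

    @property
    def n_shell(self) -> int:
        return self.n_residues_receptor - self.n_inner - self.n_core

    @property
    def shell_indices(self) -> tuple[int, ...]:
        return tuple(range(self.n_shell))

    @property
    def inner_indices(self) -> tuple[int, ...]:
        return tuple(range(self.n_shell, self.n_shell + self.n_inner))

    @property
    def core_indices(self) -> tuple[int, ...]:
        n = self.n_residues_receptor
        return tuple(range(n - self.n_core, n))

    def moving_block_labels(self) -> tuple[str, ...]:
        if self.moving_blocks is not None:
            return tuple(self.moving_blocks)
        seen: list[str] = []
        for a, b, _ in self.correlation_plan:
            for lab in (a, b):
                if lab not in seen:
                    seen.append(lab)
        return tuple(seen)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic spec, keyed like detection reports."""

    interfacial: tuple[str, ...]
    allosteric: dict[str, float]
    block_correlations: tuple[tuple[str, str, float], ...]


def truth(spec: SyntheticSpec) -> PlantedTruth:
    """Planted ground truth with residue keys matching the built system."""
    return PlantedTruth(
        interfacial=tuple(
            residue_key("A", i + 1) for i in sorted(spec.planted_interfacial)
        ),
        allosteric={
            residue_key("A", i + 1): float(d)
            for i, d in sorted(spec.planted_allosteric.items())
        },
        block_correlations=tuple(spec.correlation_plan),
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def _satellite_offsets(normal: np.ndarray, twist: float, offset: float,
                       tilt_deg: float = 45.0) -> np.ndarray:
    """Three bead offsets tilted outward from the CA along ``normal``."""
    t1, t2 = _tangent_frame(normal)
    tilt = np.deg2rad(tilt_deg)
    out = []
    for j in range(3):
        theta = twist + j * 2.0 * np.pi / 3.0
        direction = (
            np.cos(tilt) * normal
            + np.sin(tilt) * (np.cos(theta) * t1 + np.sin(theta) * t2)
        )
        out.append(offset * direction)
    return np.array(out)


def _layer_params(spec: SyntheticSpec, i: int) -> tuple[str, str, float, float]:
    """(layer, residue name, satellite offset, satellite tilt deg) for residue i."""
    if i < spec.n_shell:
        return "shell", "BEA", _SAT_OFFSET, 45.0
    if i < spec.n_shell + spec.n_inner:
        return "inner", "INN", _INNER_SAT_OFFSET, 45.0
    return "core", "COR", _CORE_SAT_OFFSET, 60.0


def _receptor_geometry(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CA positions, satellite normals and per-residue twists (deterministic).

    Shell satellites point outward; inner-layer satellites point inward so
    they crowd the core; core satellites point outward from the tiny core
    sphere (they are occluded by the inner layer regardless).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    n = spec.n_residues_receptor
    r_shell = _CA_SPACING * np.sqrt(spec.n_shell / (4.0 * np.pi))
    r_inner = 0.5 * r_shell
    ca = np.zeros((n, 3))
    normals = np.zeros((n, 3))
    shell_dirs = sphere_points(max(spec.n_shell, 1))[: spec.n_shell]
    ca[: spec.n_shell] = r_shell * shell_dirs
    normals[: spec.n_shell] = shell_dirs
    if spec.n_inner:
        inner_dirs = sphere_points(max(spec.n_inner, 2))[: spec.n_inner]
        sl = slice(spec.n_shell, spec.n_shell + spec.n_inner)
        ca[sl] = r_inner * inner_dirs
        normals[sl] = -inner_dirs  # satellites point toward the core
    if spec.n_core:
        core_dirs = sphere_points(max(spec.n_core, 2))[: spec.n_core]
        sl = slice(n - spec.n_core, n)
        ca[sl] = 1.3 * core_dirs
        normals[sl] = core_dirs
    twists = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return ca, normals, twists


def _build_receptor_coords(spec: SyntheticSpec) -> np.ndarray:
    """Reference coordinates, (4 * n_residues, 3): CA then 3 satellites each."""
    ca, normals, twists = _receptor_geometry(spec)
    n = spec.n_residues_receptor
    coords = np.zeros((4 * n, 3))
    for i in range(n):
        _, _, offset, tilt = _layer_params(spec, i)
        coords[4 * i] = ca[i]
        coords[4 * i + 1: 4 * i + 4] = ca[i] + _satellite_offsets(
            normals[i], twists[i], offset, tilt
        )
    return coords


def _check_self_avoidance(coords: np.ndarray, n_residues: int,
                          min_ca_dist: float = 2.0,
                          min_bead_dist: float = 0.8) -> bool:
    """Backbone (CA trace) self-avoiding; no two beads near-coincident.

    Satellite beads of neighbouring residues may pack closer than their
    vdW diameter - that bonded-like packing is what buries the core.
    """
    from scipy.spatial import cKDTree

    ca = coords[::4]
    if ca.shape[0] > 1:
        d, _ = cKDTree(ca).query(ca, k=2)
        if d[:, 1].min() < min_ca_dist:
            return False
    pairs = cKDTree(coords).query_pairs(min_bead_dist, output_type="ndarray")
    if pairs.size == 0:
        return True
    res_of = np.repeat(np.arange(n_residues), 4)
    return bool(np.all(res_of[pairs[:, 0]] == res_of[pairs[:, 1]]))


def _receptor_system(spec: SyntheticSpec) -> MolecularSystem:
    n = spec.n_residues_receptor
    atoms = []
    residues = []
    names = ("CA", "S1", "S2", "S3")
    for i in range(n):
        key = residue_key("A", i + 1)
        _, res_name, _, _ = _layer_params(spec, i)
        idx = []
        for j, atom_name in enumerate(names):
            a = 4 * i + j
            atoms.append(
                Atom(index=a, name=atom_name, element="C", residue_key=key,
                     vdw_radius=_BEAD_RADIUS, mass=_BEAD_MASS)
            )
            idx.append(a)
        residues.append(Residue(key=key, name=res_name, atom_indices=tuple(idx)))
    return MolecularSystem(tuple(atoms), tuple(residues), name="toy_receptor")


def build_toy_receptor(spec: SyntheticSpec) -> tuple[MolecularSystem, np.ndarray]:
    """Toy receptor topology and reference frame (deterministic per seed).

    Surface residues sit on a spherical spiral (relative SASA well above the
    20 % burial line); the last ``n_core`` residues form a tightly packed,
    mainly buried core. Raises if the layout violates self-avoidance after
    bounded retries.
    """
    base = spec
    for attempt in range(5):
        coords = _build_receptor_coords(base)
        if _check_self_avoidance(coords, spec.n_residues_receptor):
            return _receptor_system(spec), coords
        base = replace(base, seed=base.seed + 104729 * (attempt + 1))
    raise RuntimeError(
        "toy receptor construction failed self-avoidance after bounded retries"
    )


def max_sasa_table(spec: SyntheticSpec,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_points: int = DEFAULT_N_POINTS) -> dict[str, float]:
    """Maximum exposure per toy residue type: SASA of one isolated cluster."""
    normal = np.array([0.0, 0.0, 1.0])
    table: dict[str, float] = {}
    for name, offset, tilt in (
        ("BEA", _SAT_OFFSET, 45.0),
        ("INN", _INNER_SAT_OFFSET, 45.0),
        ("COR", _CORE_SAT_OFFSET, 60.0),
    ):
        coords = np.zeros((4, 3))
        coords[1:] = _satellite_offsets(normal, 0.0, offset, tilt)
        radii = np.full(4, _BEAD_RADIUS)
        table[name] = float(
            atom_sasa(coords, radii, probe_radius=probe_radius,
                      n_points=n_points).sum()
        )
    # partner cap residue: 7 beads, one centre + hexagon
    cap = _cap_offsets()
    radii = np.full(len(cap), _BEAD_RADIUS)
    table["LIG"] = float(
        atom_sasa(cap, radii, probe_radius=probe_radius, n_points=n_points).sum()
    )
    return table


# ---------------------------------------------------------------------------
# Partner construction (planted interfacial occlusion)
# ---------------------------------------------------------------------------


def _cap_offsets(ring_radius: float = 2.3) -> np.ndarray:
    """Seven bead offsets of one occluding cap, in its local frame
    (z = outward normal of the capped residue); centred on the origin."""
    pts = [np.zeros(3)]
    for k in range(6):
        theta = k * np.pi / 3.0
        pts.append(np.array([ring_radius * np.cos(theta),
                             ring_radius * np.sin(theta), 0.0]))
    return np.array(pts)


def _place_partner(
    spec: SyntheticSpec,
    receptor_coords: np.ndarray,
    system: MolecularSystem,
    max_table: Mapping[str, float],
    target_occlusion: float = 10.0,
) -> np.ndarray:
    """Cap coordinates occluding exactly the planted interfacial residues.

    One seven-bead cap hovers over each planted residue along its outward
    normal; the hover height is lowered stepwise until each planted residue
    loses at least ``target_occlusion`` percentage points of relative SASA
    (partner present vs. absent, identical coordinates). Raises if the
    target cannot be reached geometrically.

    With no planted residues a single cap is placed far from the receptor
    (three shell radii along +z), so a partner chain exists but occludes
    nothing - the null configuration.
    """
    ca, normals, _ = _receptor_geometry(spec)
    if not spec.planted_interfacial:
        r_shell = np.linalg.norm(ca[0]) if spec.n_shell else 10.0
        return _cap_offsets() + np.array([0.0, 0.0, 3.0 * r_shell + 15.0])
    n_rec = receptor_coords.shape[0]
    base_rel = _relative_residue_sasa_partial(
        receptor_coords, np.full(n_rec, _BEAD_RADIUS), spec, max_table
    )
    for height in np.arange(5.6, 3.3, -0.3):
        caps = []
        for i in sorted(spec.planted_interfacial):
            t1, t2 = _tangent_frame(normals[i])
            rot = np.column_stack([t1, t2, normals[i]])
            caps.append(ca[i] + height * normals[i] + _cap_offsets() @ rot.T)
        partner = np.concatenate(caps, axis=0)
        joint = np.concatenate([receptor_coords, partner], axis=0)
        radii = np.full(joint.shape[0], _BEAD_RADIUS)
        rel = _relative_residue_sasa_partial(joint, radii, spec, max_table)
        drop = base_rel - rel
        planted = sorted(spec.planted_interfacial)
        if all(drop[i] >= target_occlusion for i in planted):
            # partner must not clash with the receptor
            from scipy.spatial import cKDTree

            d, _ = cKDTree(receptor_coords).query(partner)
            if d.min() > 2.0:
                return partner
    raise RuntimeError(
        "occlusion calibration failed: partner cannot reach the planted "
        "interfacial residues with the required occlusion"
    )


def _relative_residue_sasa_partial(
    coords: np.ndarray, radii: np.ndarray, spec: SyntheticSpec,
    max_table: Mapping[str, float],
) -> np.ndarray:
    """Receptor-residue relative SASA from raw coordinates (receptor atoms
    first, 4 per residue); extra atoms occlude but are not reported."""
    per_atom = atom_sasa(coords, radii)
    n = spec.n_residues_receptor
    rel = np.empty(n)
    for i in range(n):
        _, name, _, _ = _layer_params(spec, i)
        rel[i] = 100.0 * per_atom[4 * i: 4 * i + 4].sum() / max_table[name]
    return rel


# ---------------------------------------------------------------------------
# Allosteric shift calibration
# ---------------------------------------------------------------------------


def _apply_satellite_scale(coords: np.ndarray, residue_idx: int,
                           scale: float) -> np.ndarray:
    out = coords.copy()
    ca = coords[4 * residue_idx]
    for j in range(1, 4):
        a = 4 * residue_idx + j
        out[a] = ca + scale * (coords[a] - ca)
    return out


def _calibrate_allosteric(
    spec: SyntheticSpec,
    receptor_coords: np.ndarray,
    max_table: Mapping[str, float],
    tol_pp: float = 0.5,
) -> np.ndarray:
    """Bound-state receptor reference realizing the planted allosteric deltas.

    For each planted residue the satellite beads are scaled about the CA
    (collapse buries, expansion exposes); the scale is found by bisection
    against the SASA engine so the partner-excluded relative-SASA change
    matches the signed target within ``tol_pp`` percentage points.
    """
    coords = receptor_coords.copy()
    radii = np.full(coords.shape[0], _BEAD_RADIUS)
    base = _relative_residue_sasa_partial(coords, radii, spec, max_table)
    for idx in sorted(spec.planted_allosteric):
        target = float(spec.planted_allosteric[idx])
        lo, hi = (0.05, 1.0) if target < 0 else (1.0, 2.6)

        def realized(scale: float) -> float:
            trial = _apply_satellite_scale(coords, idx, scale)
            rel = _relative_residue_sasa_partial(trial, radii, spec, max_table)
            return float(rel[idx] - base[idx])

        f_lo, f_hi = realized(lo), realized(hi)
        if not (min(f_lo, f_hi) - tol_pp <= target <= max(f_lo, f_hi) + tol_pp):
            raise RuntimeError(
                f"allosteric calibration failed for residue index {idx}: "
                f"target {target:+.1f} pp outside achievable "
                f"[{min(f_lo, f_hi):+.1f}, {max(f_lo, f_hi):+.1f}]"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            f_mid = realized(mid)
            if abs(f_mid - target) <= tol_pp:
                lo = hi = mid
                break
            # realized delta increases with scale on both branches
            if (f_mid < target) == (f_hi > f_lo):
                lo = mid
            else:
                hi = mid
        coords = _apply_satellite_scale(coords, idx, 0.5 * (lo + hi))
    return coords


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def _block_setup(spec: SyntheticSpec) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Moving-block atom index lists, unit directions, latent factor L."""
    moving = spec.moving_block_labels()
    blocks = {lab: (start, stop) for start, stop, lab in spec.domain_blocks}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    # one direction per correlation-connected group, so the planted latent
    # correlation is what the cross-correlation analysis should recover
    parent = {lab: lab for lab in moving}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in spec.correlation_plan:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    group_dir: dict[str, np.ndarray] = {}
    directions = []
    for lab in moving:
        root = find(lab)
        if root not in group_dir:
            v = rng.standard_normal(3)
            group_dir[root] = v / np.linalg.norm(v)
        directions.append(group_dir[root])
    atom_lists = []
    for lab in moving:
        start, stop = blocks[lab]
        atom_lists.append(
            np.concatenate([np.arange(4 * i, 4 * i + 4) for i in range(start, stop)])
        )
    k = len(moving)
    if k == 0:
        return [], np.zeros((0, 3)), np.zeros((0, 0))
    corr = np.eye(k)
    pos = {lab: i for i, lab in enumerate(moving)}
    for a, b, rho in spec.correlation_plan:
        if a in pos and b in pos:
            corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = rho
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-9:
        raise ValueError("correlation plan is not positive semidefinite")
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return atom_lists, np.array(directions), factor


def _simulate(
    spec: SyntheticSpec,
    system: MolecularSystem,
    reference: np.ndarray,
    stream: int,
    label_prefix: str,
) -> ReplicateEnsemble:
    atom_lists, directions, factor = _block_setup(spec)
    trajectories = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, stream, rep])
        )
        coords = np.broadcast_to(
            reference, (spec.n_frames,) + reference.shape
        ).copy()
        if atom_lists:
            z = rng.standard_normal((spec.n_frames, factor.shape[0])) @ factor.T
            for b, atoms in enumerate(atom_lists):
                disp = spec.block_amplitude * np.outer(z[:, b], directions[b])
                coords[:, atoms, :] += disp[:, None, :]
        if spec.noise_sigma > 0:
            coords += spec.noise_sigma * rng.standard_normal(coords.shape)
        times = np.arange(spec.n_frames, dtype=float) * _FRAME_SPACING_NS
        trajectories.append(
            Trajectory(system=system, coordinates=coords, times=times,
                       label=f"{label_prefix}_rep{rep}")
        )
    return ReplicateEnsemble(trajectories).with_full_windows()


def simulate_unbound_ensemble(spec: SyntheticSpec) -> ReplicateEnsemble:
    """Replicate ensemble of the unbound receptor (windows set to full)."""
    system, reference = build_toy_receptor(spec)
    return _simulate(spec, system, reference, stream=0, label_prefix="unbound")


def _bound_system(spec: SyntheticSpec, receptor: MolecularSystem,
                  n_caps: int) -> MolecularSystem:
    atoms = list(receptor.atoms)
    residues = list(receptor.residues)
    names = ("CA", "S1", "S2", "S3", "S4", "S5", "S6")
    next_index = len(atoms)
    for c in range(n_caps):
        key = residue_key("B", c + 1)
        idx = []
        for j in range(7):
            atoms.append(
                Atom(index=next_index, name=names[j], element="C",
                     residue_key=key, vdw_radius=_BEAD_RADIUS, mass=_BEAD_MASS)
            )
            idx.append(next_index)
            next_index += 1
        residues.append(Residue(key=key, name="LIG", atom_indices=tuple(idx)))
    return MolecularSystem(tuple(atoms), tuple(residues), name="toy_complex")


def simulate_bound_ensemble(spec: SyntheticSpec) -> ReplicateEnsemble:
    """Receptor+partner ensemble with planted interfacial occlusion and
    planted bound-state allosteric exposure changes (windows set to full).

    The partner is chain ``B``; receptor residues keep identical keys and
    types to the unbound ensemble, so the two can be differenced residue by
    residue.
    """
    receptor_sys, receptor_ref = build_toy_receptor(spec)
    table = max_sasa_table(spec)
    bound_receptor_ref = (
        _calibrate_allosteric(spec, receptor_ref, table)
        if spec.planted_allosteric
        else receptor_ref
    )
    partner = _place_partner(spec, bound_receptor_ref, receptor_sys, table)
    n_caps = max(len(spec.planted_interfacial), 1)
    system = _bound_system(spec, receptor_sys, n_caps)
    reference = np.concatenate([bound_receptor_ref, partner], axis=0)
    return _simulate(spec, system, reference, stream=1, label_prefix="bound")
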