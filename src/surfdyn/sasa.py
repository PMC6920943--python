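"""Shrake-Rupley solvent-accessible surface area and SASA-based residue detection.

The engine rolls a probe sphere (default 1.4 A) over the van der Waals
surface: each atom's expanded sphere of radius ``r + probe`` is sampled with
a deterministic golden-section spiral of quasi-uniform points, and the SASA
is the expanded-sphere area times the fraction of points not buried inside
any other atom's expanded sphere. Only atoms inside the supplied mask
receive SASA *and* occlude: atoms outside the mask are invisible, which is
what makes the "with partner / without partner" differencing protocols
well defined on identical coordinates.

Built on top of the engine:

* per-residue, time-averaged SASA over an equilibrated window;
* conversion to *relative* SASA (percent of the maximum a fully exposed
  residue of that type would have);
* replicate statistics with delete-one jack-knife SEM;
* a burial filter (drop residues below 20 % relative exposure);
* the two detection protocols: **interfacial** residues (occluded by the
  physical presence of the partner: SASA with vs. without partner atoms on
  identical coordinates) and **allosteric** residues (partner-excluded SASA
  differs between bound and unbound ensembles - a conformational effect).

A residue is reported when the relative-SASA difference exceeds
``delta_min`` (default 5 percentage points) and the jack-knife SEM of the
difference is smaller than the difference itself.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import MolecularSystem, SelectionMask, ComplexPartition, Trajectory
from .tables import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, MAX_SASA

try:  # optional compiled kernel; the numpy path gives identical results
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the golden-section spiral.

    Deterministic; each point carries quadrature weight 1/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n, dtype=float)
    # z strata midpoints, golden-angle azimuth
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _neighbor_csr(
    coords: np.ndarray,
    radii: np.ndarray,
    mask_idx: np.ndarray,
    probe: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-masked-atom candidate occluder lists in CSR form.

    ``coords`` may be one frame ``(N, 3)`` or a trajectory ``(F, N, 3)``;
    for a trajectory the candidate test accounts for how far each atom
    strays from its frame-0 position, so the list is valid for every frame.
    """
    if coords.ndim == 2:
        ref = coords
        disp = np.zeros(coords.shape[0])
    else:
        ref = coords[0]
        disp = np.sqrt(((coords - ref[None]) ** 2).sum(axis=2)).max(axis=0)
    sub = ref[mask_idx]
    sub_r = radii[mask_idx]
    sub_d = disp[mask_idx]
    cutoff = 2.0 * (sub_r.max() + probe) + 2.0 * (sub_d.max() if sub_d.size else 0.0)
    tree = cKDTree(sub)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        a, b = pairs[:, 0], pairs[:, 1]
        d0 = np.linalg.norm(sub[a] - sub[b], axis=1)
        ok = d0 < (sub_r[a] + sub_r[b] + 2.0 * probe + sub_d[a] + sub_d[b])
        a, b = a[ok], b[ok]
    else:
        a = b = np.empty(0, dtype=int)
    m = mask_idx.size
    counts = np.bincount(a, minlength=m) + np.bincount(b, minlength=m)
    indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for i, j in zip(a, b):
        indices[fill[i]] = j
        fill[i] += 1
        indices[fill[j]] = i
        fill[j] += 1
    return indptr, indices


def _sasa_frames_numpy(
    coords: np.ndarray,
    radii: np.ndarray,
    mask_idx: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
    points: np.ndarray,
    probe: float,
) -> np.ndarray:
    F = coords.shape[0]
    m = mask_idx.size
    out = np.zeros((F, m))
    n_pts = points.shape[0]
    sub_coords = coords[:, mask_idx, :]  # (F, m, 3)
    exp_r = radii[mask_idx] + probe
    for a in range(m):
        R = exp_r[a]
        nbr = indices[indptr[a]: indptr[a + 1]]
        if nbr.size == 0:
            out[:, a] = 4.0 * np.pi * R * R
            continue
        # squared distance from each test point to each neighbour centre:
        # |R*u + (c_i - c_j)|^2 = R^2 + |v|^2 + 2R u.v
        v = sub_coords[:, a, None, :] - sub_coords[:, nbr, :]  # (F, k, 3)
        n2 = (v * v).sum(axis=2)  # (F, k)
        uv = np.einsum("pd,fkd->fpk", points, v)  # (F, P, k)
        d2 = R * R + n2[:, None, :] + 2.0 * R * uv
        accessible = (d2 >= (exp_r[nbr] ** 2)[None, None, :]).all(axis=2)
        out[:, a] = 4.0 * np.pi * R * R * accessible.sum(axis=1) / n_pts
    return out


if _HAVE_NUMBA:

    @njit(cache=True)
    def _sasa_frames_kernel(coords, radii, mask_idx, indptr, indices, points, probe):
        # The CSR candidate lists are valid for every frame (they include a
        # motion bound); per frame they are narrowed to the atoms actually
        # within occlusion range before the expensive point loop.
        F = coords.shape[0]
        m = mask_idx.size
        P = points.shape[0]
        out = np.zeros((F, m))
        max_k = 0
        for a in range(m):
            k = indptr[a + 1] - indptr[a]
            if k > max_k:
                max_k = k
        nbr_x = np.empty(max_k)
        nbr_y = np.empty(max_k)
        nbr_z = np.empty(max_k)
        nbr_r2 = np.empty(max_k)
        for f in range(F):
            for a in range(m):
                i = mask_idx[a]
                R = radii[i] + probe
                cx = coords[f, i, 0]
                cy = coords[f, i, 1]
                cz = coords[f, i, 2]
                k = 0
                for jj in range(indptr[a], indptr[a + 1]):
                    j = mask_idx[indices[jj]]
                    rj = radii[j] + probe
                    dx = coords[f, j, 0] - cx
                    dy = coords[f, j, 1] - cy
                    dz = coords[f, j, 2] - cz
                    if dx * dx + dy * dy + dz * dz < (R + rj) * (R + rj):
                        nbr_x[k] = coords[f, j, 0]
                        nbr_y[k] = coords[f, j, 1]
                        nbr_z[k] = coords[f, j, 2]
                        nbr_r2[k] = rj * rj
                        k += 1
                n_acc = 0
                for p in range(P):
                    px = cx + R * points[p, 0]
                    py = cy + R * points[p, 1]
                    pz = cz + R * points[p, 2]
                    blocked = False
                    for q in range(k):
                        dx = px - nbr_x[q]
                        dy = py - nbr_y[q]
                        dz = pz - nbr_z[q]
                        if dx * dx + dy * dy + dz * dz < nbr_r2[q]:
                            blocked = True
                            break
                    if not blocked:
                        n_acc += 1
                out[f, a] = 4.0 * np.pi * R * R * n_acc / P
        return out


def sasa_frames(
    coords: np.ndarray,
    radii: np.ndarray,
    mask: SelectionMask | np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA for one frame ``(N, 3)`` or many frames ``(F, N, 3)``.

    Returns an array of the same leading shape with one SASA value per atom
    (A^2); atoms outside ``mask`` neither receive SASA nor occlude, and get
    0 in the output.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    radii = np.asarray(radii, dtype=float)
    n_atoms = coords.shape[1]
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if mask is None:
        mask_idx = np.arange(n_atoms)
    elif isinstance(mask, SelectionMask):
        mask_idx = mask.indices
    else:
        mask_idx = np.unique(np.asarray(mask, dtype=int))
    points = sphere_points(n_points)
    out = np.zeros((coords.shape[0], n_atoms))
    if mask_idx.size == 0:
        return out[0] if single else out
    indptr, indices = _neighbor_csr(coords, radii, mask_idx, probe_radius)
    if _HAVE_NUMBA:
        vals = _sasa_frames_kernel(
            coords, radii, mask_idx.astype(np.int64), indptr, indices,
            points, float(probe_radius),
        )
    else:
        vals = _sasa_frames_numpy(
            coords, radii, mask_idx, indptr, indices, points, probe_radius
        )
    out[:, mask_idx] = vals
    return out[0] if single else out


def atom_sasa(
    frame_coords: np.ndarray,
    radii: np.ndarray,
    mask: SelectionMask | np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Single-frame per-atom SASA (see :func:`sasa_frames`)."""
    return sasa_frames(frame_coords, radii, mask, probe_radius, n_points)


def residue_sasa_from_atoms(system: MolecularSystem,
                            atom_values: np.ndarray) -> pd.Series:
    """Sum per-atom SASA into per-residue SASA, indexed by residue key."""
    res_idx = system.residue_index_of_atom
    sums = np.bincount(res_idx, weights=atom_values, minlength=system.n_residues)
    return pd.Series(sums, index=system.residue_keys, name="sasa")


def trajectory_residue_sasa(
    trajectory: Trajectory,
    window: "tuple[int, int] | None" = None,
    mask: SelectionMask | None = None,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> pd.Series:
    """Time-averaged per-residue SASA (A^2) over an equilibrated window.

    ``window`` is ``(start_frame, end_frame_exclusive)``; frames are taken
    with the given stride starting at ``start_frame``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    start, end = (0, trajectory.n_frames) if window is None else window
    if hasattr(window, "start_frame"):  # EquilibratedWindow duck-typing
        start, end = window.start_frame, window.end_frame
    if not (0 <= start < end <= trajectory.n_frames):
        raise ValueError(f"empty or invalid window ({start}, {end})")
    coords = trajectory.coordinates[start:end:stride]
    per_atom = sasa_frames(
        coords, trajectory.system.radii, mask, probe_radius, n_points
    )
    return residue_sasa_from_atoms(trajectory.system, per_atom.mean(axis=0))


def relative_sasa(
    residue_sasa: pd.Series,
    residue_names: Mapping[str, str],
    max_table: Mapping[str, float] | None = None,
) -> pd.Series:
    """Convert absolute residue SASA (A^2) to percent of maximum exposure.

    Values above 100 % are possible for distorted conformers and are *not*
    clipped (a warning is emitted instead).
    """
    table = MAX_SASA if max_table is None else max_table
    missing = sorted(
        {residue_names[k] for k in residue_sasa.index} - set(table)
    )
    if missing:
        raise KeyError(
            f"residue type(s) missing from the max-SASA table: {missing}"
        )
    maxima = np.array([table[residue_names[k]] for k in residue_sasa.index])
    rel = 100.0 * residue_sasa.to_numpy() / maxima
    if np.any(rel > 100.0 + 1e-9):
        warnings.warn(
            "relative SASA above 100% for some residues (distorted conformer?)",
            stacklevel=2,
        )
    return pd.Series(rel, index=residue_sasa.index, name="relative_sasa")


def jackknife_mean_sem(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and delete-one jack-knife SEM across replicates.

    ``sem = sqrt((n-1)/n * sum_i (theta_(i) - theta_bar)^2)`` with
    ``theta_(i)`` the leave-one-out means; for the plain mean this equals
    ``s/sqrt(n)`` exactly.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    if n < 2:
        raise ValueError("jack-knife needs at least 2 replicates")
    total = values.sum(axis=axis, keepdims=True)
    loo = (total - values) / (n - 1)  # theta_(i) along axis
    loo_mean = loo.mean(axis=axis, keepdims=True)
    sem = np.sqrt((n - 1) / n * ((loo - loo_mean) ** 2).sum(axis=axis))
    mean = values.mean(axis=axis)
    return mean, sem


def filter_buried(stats: pd.DataFrame, burial_threshold: float = 20.0) -> set[str]:
    """Residue keys whose reference relative SASA is >= the burial threshold.

    Residues *below* the threshold are considered mainly internalised and
    dropped from detection.
    """
    if not 0.0 < burial_threshold < 100.0:
        raise ValueError("burial_threshold must be in (0, 100)")
    keep = stats["relative_sasa_mean"] >= burial_threshold
    return set(stats.loc[keep, "residue_key"])


# ---------------------------------------------------------------------------
# Replicate-level relative SASA and the two detection protocols
# ---------------------------------------------------------------------------


def _require_windows(ensemble) -> list[tuple[int, int]]:
    if ensemble.windows is None or any(w is None for w in ensemble.windows):
        raise ValueError(
            "equilibrated windows must be set on every replicate before "
            "SASA statistics (detect or assign them first)"
        )
    return [(w.start_frame, w.end_frame) for w in ensemble.windows]


def replicate_relative_sasa(
    ensemble,
    mask: SelectionMask | None = None,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Relative SASA per residue for each replicate (rows = replicates)."""
    windows = _require_windows(ensemble)
    system = ensemble.trajectories[0].system
    rows = []
    for traj, win in zip(ensemble.trajectories, windows):
        absolute = trajectory_residue_sasa(
            traj, win, mask, stride, probe_radius, n_points
        )
        rows.append(relative_sasa(absolute, system.residue_names, max_table))
    return pd.DataFrame(rows).reset_index(drop=True)


def residue_sasa_stats(
    ensemble,
    mask: SelectionMask | None = None,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue relative-SASA mean and jack-knife SEM across replicates."""
    rel = replicate_relative_sasa(
        ensemble, mask, stride, probe_radius, n_points, max_table
    )
    mean, sem = jackknife_mean_sem(rel.to_numpy(), axis=0)
    return pd.DataFrame(
        {
            "residue_key": rel.columns,
            "relative_sasa_mean": mean,
            "sem": sem,
            "n_replicates": len(rel),
        }
    )


def _apply_rule(
    delta: np.ndarray,
    sem: np.ndarray,
    keys: Sequence[str],
    names: Mapping[str, str],
    ref_mean: np.ndarray,
    cond_mean: np.ndarray,
    retained: set[str],
    delta_min: float,
    sem_rule: bool,
    classification: str,
) -> pd.DataFrame:
    rows = []
    for i, key in enumerate(keys):
        if key not in retained:
            continue
        if abs(delta[i]) <= delta_min:
            continue
        if sem_rule and not sem[i] < abs(delta[i]):
            continue
        rows.append(
            {
                "residue_key": key,
                "residue_name": names[key],
                "ref_mean": ref_mean[i],
                "cond_mean": cond_mean[i],
                "delta": delta[i],
                "sem": sem[i],
                "classification": classification,
                "direction": "occluded" if delta[i] < 0 else "exposed",
            }
        )
    columns = [
        "residue_key", "residue_name", "ref_mean", "cond_mean",
        "delta", "sem", "classification", "direction",
    ]
    return pd.DataFrame(rows, columns=columns)


def detect_interfacial(
    bound_ensemble,
    partition: ComplexPartition,
    delta_min: float = 5.0,
    burial_threshold: float = 20.0,
    sem_rule: bool = True,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Residues of the receptor occluded by the physical presence of the partner.

    For every replicate, each receptor residue's relative SASA is computed
    twice on identical coordinates: with the partner atoms occluding (full
    mask) and with the partner removed from the computation (receptor-only
    mask). The per-replicate differences (with - without; negative means
    occluded) are combined with a jack-knife across replicates, and a
    residue is reported when |delta| exceeds ``delta_min`` percentage points
    and the SEM of delta is smaller than |delta|. The burial filter is
    applied on the partner-excluded (reference) condition.
    """
    system = bound_ensemble.trajectories[0].system
    full_mask = partition.receptor_mask.union(partition.partner_mask)
    rel_with = replicate_relative_sasa(
        bound_ensemble, full_mask, stride, probe_radius, n_points, max_table
    )
    rel_without = replicate_relative_sasa(
        bound_ensemble, partition.receptor_mask, stride, probe_radius,
        n_points, max_table,
    )
    receptor_res = sorted(
        {system.atoms[i].residue_key for i in partition.receptor_mask.indices},
        key=system.residue_keys.index,
    )
    rel_with = rel_with[receptor_res]
    rel_without = rel_without[receptor_res]
    delta_reps = rel_with.to_numpy() - rel_without.to_numpy()
    delta, sem = jackknife_mean_sem(delta_reps, axis=0)
    ref_mean = rel_without.to_numpy().mean(axis=0)
    cond_mean = rel_with.to_numpy().mean(axis=0)
    retained = filter_buried(
        pd.DataFrame(
            {"residue_key": receptor_res, "relative_sasa_mean": ref_mean}
        ),
        burial_threshold,
    )
    return _apply_rule(
        delta, sem, receptor_res, system.residue_names, ref_mean, cond_mean,
        retained, delta_min, sem_rule, "interfacial",
    )


def detect_allosteric(
    bound_ensemble,
    unbound_ensemble,
    partition: ComplexPartition,
    delta_min: float = 5.0,
    burial_threshold: float = 20.0,
    sem_rule: bool = True,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Receptor residues whose exposure changes indirectly upon binding.

    Compares the *partner-excluded* relative SASA of each receptor residue
    in the bound ensemble against the same residue in the unbound ensemble,
    so residues occluded merely by partner contact do not register; what
    remains is a conformational (allosteric) effect. SEM of the difference
    is propagated in quadrature from the two independent ensembles; the
    burial filter is applied on the unbound (reference) condition.
    """
    bound_system = bound_ensemble.trajectories[0].system
    unbound_system = unbound_ensemble.trajectories[0].system
    receptor_res = sorted(
        {bound_system.atoms[i].residue_key for i in partition.receptor_mask.indices},
        key=bound_system.residue_keys.index,
    )
    unbound_keys = set(unbound_system.residue_keys)
    for key in receptor_res:
        if key not in unbound_keys:
            raise ValueError(
                f"receptor topology mismatch: residue {key} missing from the "
                "unbound ensemble"
            )
        if bound_system.residue_names[key] != unbound_system.residue_names[key]:
            raise ValueError(
                f"receptor topology mismatch at residue {key}: "
                f"{bound_system.residue_names[key]} (bound) vs "
                f"{unbound_system.residue_names[key]} (unbound)"
            )
    rel_bound = replicate_relative_sasa(
        bound_ensemble, partition.receptor_mask, stride, probe_radius,
        n_points, max_table,
    )[receptor_res]
    rel_unbound = replicate_relative_sasa(
        unbound_ensemble, None, stride, probe_radius, n_points, max_table
    )[receptor_res]
    mean_b, sem_b = jackknife_mean_sem(rel_bound.to_numpy(), axis=0)
    mean_u, sem_u = jackknife_mean_sem(rel_unbound.to_numpy(), axis=0)
    delta = mean_b - mean_u
    sem = np.sqrt(sem_b**2 + sem_u**2)
    retained = filter_buried(
        pd.DataFrame(
            {"residue_key": receptor_res, "relative_sasa_mean": mean_u}
        ),
        burial_threshold,
    )
    return _apply_rule(
        delta, sem, receptor_res, bound_system.residue_names, mean_u, mean_b,
        retained, delta_min, sem_rule, "allosteric",
    )
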