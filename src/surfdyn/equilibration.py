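"""Equilibration assessment: RMSD series, centre-of-mass separation, windows.

RMSD is computed after an optimal rigid-body (Kabsch) superposition on the
same atom mask used for the measurement, so any common rigid-body motion is
removed. The centre-of-mass distance between receptor and partner tracks
the slower inter-domain motions that RMSD on a subdomain may miss.

All downstream ensemble statistics (SASA averages, covariance, PCA) are
taken over a per-replicate *equilibrated window*: the trailing portion of
the trajectory over which the monitored series are statistically
stationary. The window can be chosen automatically (flat linear trend and
bounded sliding-window spread) or set explicitly per replicate,
reproducing by-inspection choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import MolecularSystem, SelectionMask, Trajectory


@dataclass(frozen=True)
class SeriesResult:
    """A per-frame scalar series (RMSD or COM distance, A) with times in ns."""

    times: np.ndarray
    values: np.ndarray
    selection_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(values < -1e-12):
            raise ValueError("series values must be non-negative")


@dataclass(frozen=True)
class EquilibratedWindow:
    """Frame window ``[start_frame, end_frame)`` judged stationary."""

    start_frame: int
    end_frame: int
    criterion_log: str = ""
    equilibrated: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError("need 0 <= start_frame < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class ReplicateEnsemble:
    """Independent trajectories of one system plus per-replicate windows."""

    trajectories: list[Trajectory]
    windows: list[EquilibratedWindow | None] | None = None

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble needs at least one trajectory")
        ref = self.trajectories[0].system
        for traj in self.trajectories[1:]:
            if traj.system.n_atoms != ref.n_atoms or (
                traj.system.residue_keys != ref.residue_keys
            ):
                raise ValueError("all replicates must share one topology")
        if self.windows is None:
            self.windows = [None] * len(self.trajectories)
        elif len(self.windows) != len(self.trajectories):
            raise ValueError("one window per trajectory required")
        for traj, win in zip(self.trajectories, self.windows):
            if win is not None and win.end_frame > traj.n_frames:
                raise ValueError("window exceeds trajectory length")

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    @property
    def system(self) -> MolecularSystem:
        return self.trajectories[0].system

    def with_full_windows(self) -> "ReplicateEnsemble":
        """Treat every full trajectory as equilibrated (synthetic data)."""
        wins = [
            EquilibratedWindow(0, t.n_frames, criterion_log="full trajectory")
            for t in self.trajectories
        ]
        return ReplicateEnsemble(self.trajectories, wins)


def _masked(coords: np.ndarray, mask: SelectionMask | np.ndarray | None) -> np.ndarray:
    if mask is None:
        return coords
    idx = mask.indices if isinstance(mask, SelectionMask) else np.asarray(mask, int)
    return coords[..., idx, :]


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    mask: SelectionMask | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The rotation/translation is determined on the masked atoms and applied
    to all atoms. Returns ``(transformed, rotation, translation)`` with
    ``transformed = mobile @ R.T + t`` and ``det(R) = +1`` (proper rotation,
    reflections excluded by the standard sign correction on the smallest
    singular value).
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    mob = _masked(mobile, mask)
    ref = _masked(reference, mask)
    if mob.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms in the mask")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = mob - mob_c
    b = ref - ref_c
    # collinearity check: centered coordinates must span a plane
    if np.linalg.matrix_rank(a, tol=1e-8 * max(1.0, np.abs(a).max())) < 2:
        raise ValueError("masked atoms are collinear; superposition is degenerate")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    trans = ref_c - rot @ mob_c
    transformed = mobile @ rot.T + trans
    return transformed, rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsd_series(
    trajectory: Trajectory,
    reference: int | np.ndarray = 0,
    mask: SelectionMask | None = None,
    label: str = "",
) -> SeriesResult:
    """Per-frame RMSD (A) to a reference after Kabsch fitting on ``mask``.

    ``reference`` is a frame index or an external ``(n_atoms, 3)`` structure.
    Fit and measurement use the same atoms.
    """
    if isinstance(reference, (int, np.integer)):
        ref_coords = trajectory.coordinates[int(reference)]
    else:
        ref_coords = np.asarray(reference, dtype=float)
    ref_m = _masked(ref_coords, mask)
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        mob_m = _masked(trajectory.coordinates[f], mask)
        fitted, _, _ = kabsch_superpose(mob_m, ref_m, mask=None)
        values[f] = rmsd(fitted, ref_m)
    return SeriesResult(trajectory.times, values, label or "rmsd")


def com_distance_series(
    trajectory: Trajectory,
    mask_a: SelectionMask,
    mask_b: SelectionMask,
    weighting: str = "mass",
    label: str = "",
) -> SeriesResult:
    """Per-frame distance (A) between the centres of two atom groups.

    ``weighting`` is ``"mass"`` (centre of mass) or ``"geometric"``.
    """
    if len(mask_a) == 0 or len(mask_b) == 0:
        raise ValueError("COM groups must be non-empty")
    if np.intersect1d(mask_a.indices, mask_b.indices).size:
        raise ValueError("COM groups must be disjoint")
    if weighting not in ("mass", "geometric"):
        raise ValueError("weighting must be 'mass' or 'geometric'")
    masses = trajectory.system.masses
    coords = trajectory.coordinates

    def centre(idx: np.ndarray) -> np.ndarray:
        sub = coords[:, idx, :]
        if weighting == "mass":
            w = masses[idx]
            return (sub * w[None, :, None]).sum(axis=1) / w.sum()
        return sub.mean(axis=1)

    dist = np.linalg.norm(centre(mask_a.indices) - centre(mask_b.indices), axis=1)
    return SeriesResult(trajectory.times, dist, label or "com_distance")


def detect_equilibrated_window(
    series_list: Sequence[SeriesResult],
    min_tail_fraction: float = 0.2,
    slope_tol: float = 0.02,
    spread_tol: float = 1.5,
    sliding_window: int | None = None,
) -> EquilibratedWindow:
    """Longest trailing window over which every series is stationary.

    A candidate suffix ``[start, n)`` qualifies when, for every series, the
    absolute slope of a linear fit is <= ``slope_tol`` (units per ns) and the
    max-min spread within every sliding sub-window of length
    ``sliding_window`` frames (default ``max(10, n // 20)``) is <=
    ``spread_tol``. The earliest qualifying start wins. If no suffix of at
    least ``min_tail_fraction`` of the trajectory qualifies, the full-range
    window is returned flagged ``equilibrated=False`` rather than raising.
    """
    if not series_list:
        raise ValueError("need at least one series")
    n = len(series_list[0].values)
    times = series_list[0].times
    for s in series_list[1:]:
        if len(s.values) != n or not np.allclose(s.times, times):
            raise ValueError("all series must share one time axis")
    win = sliding_window or max(10, n // 20)
    min_len = max(2, int(np.ceil(min_tail_fraction * n)))

    # precompute rolling spreads per series, then the earliest start from
    # which every sliding sub-window to the right stays within spread_tol
    spread_ok_from = 0
    for s in series_list:
        v = s.values
        if n >= win:
            import pandas as pd

            roll = pd.Series(v).rolling(win)
            spread = (roll.max() - roll.min()).to_numpy()[win - 1:]
            bad = np.flatnonzero(spread > spread_tol)
            if bad.size:
                # sub-window starting at bad[-1] violates; suffix must start after
                spread_ok_from = max(spread_ok_from, int(bad[-1]) + 1)

    best: int | None = None
    for start in range(spread_ok_from, n - min_len + 1):
        ok = True
        t = times[start:]
        for s in series_list:
            v = s.values[start:]
            slope = np.polyfit(t, v, 1)[0] if t[-1] > t[0] else 0.0
            if abs(slope) > slope_tol:
                ok = False
                break
        if ok:
            best = start
            break

    if best is None:
        log = (
            f"not equilibrated: no suffix of >= {min_len} frames with "
            f"|slope| <= {slope_tol}/ns and spread <= {spread_tol} "
            f"(sliding window {win} frames)"
        )
        return EquilibratedWindow(0, n, criterion_log=log, equilibrated=False)
    t = times[best:]
    slopes = [float(np.polyfit(t, s.values[best:], 1)[0]) for s in series_list]
    log = (
        f"start_frame={best} (t={times[best]:.4g} ns); slopes="
        f"{[f'{x:.4g}' for x in slopes]}; slope_tol={slope_tol}; "
        f"spread_tol={spread_tol}; sliding_window={win}; "
        f"min_tail_fraction={min_tail_fraction}"
    )
    return EquilibratedWindow(best, n, criterion_log=log, equilibrated=True)
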