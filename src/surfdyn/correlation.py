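"""Cartesian covariance, dynamical cross-correlation (DCCM), and PCA.

After superposing every equilibrated frame of every replicate onto one
common reference and subtracting the per-atom trajectory mean, the
covariance of atomic displacements is

    C_ij = < dr_i . dr_j >        (3-vector dot product, trajectory average)

The DCCM is the Pearson-normalised form ``C_ij / sqrt(C_ii C_jj)``,
conventionally computed on one representative atom per residue (the
``CA``-named atom) so the matrix is residue x residue. Cartesian PCA
eigendecomposes the full ``3N x 3N`` coordinate covariance: eigenvectors
are collective motions, eigenvalues their mean-square amplitude, and the
per-residue contribution of a component is the summed squared eigenvector
weight on that residue's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MolecularSystem, SelectionMask, Trajectory, subset_system
from .equilibration import ReplicateEnsemble, kabsch_superpose


@dataclass(frozen=True)
class CenteredEnsemble:
    """Superposed, mean-free coordinates pooled over replicate windows."""

    coordinates: np.ndarray  # (total_frames, n_sel, 3), mean-free
    mean_structure: np.ndarray  # (n_sel, 3)
    system: MolecularSystem
    mask: SelectionMask
    frames_per_replicate: tuple[int, ...]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class CorrelationResult:
    """Symmetric atoms x atoms matrix, raw covariance (A^2) or normalised."""

    matrix: np.ndarray
    mode: str  # "covariance" | "normalized"
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        if self.mode == "normalized":
            if not np.allclose(np.diag(m), 1.0, atol=1e-9):
                raise ValueError("normalized matrix must have unit diagonal")
            if m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9:
                raise ValueError("normalized entries must lie in [-1, 1]")


@dataclass(frozen=True)
class EigenResult:
    """Eigenvalues (non-increasing) and orthonormal eigenvectors (columns)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass(frozen=True)
class PcaResult:
    """Cartesian PCA of the 3N coordinate covariance."""

    eigen: EigenResult
    projections: np.ndarray  # (frames, components)
    variance_fraction: np.ndarray
    residue_contributions: pd.DataFrame  # residues x components
    centered: CenteredEnsemble


def center_ensemble(
    ensemble: ReplicateEnsemble,
    mask: SelectionMask | None = None,
    reference: np.ndarray | None = None,
    fit_mask: SelectionMask | None = None,
) -> CenteredEnsemble:
    """Superpose all equilibrated frames onto one reference and remove the mean.

    ``mask`` selects the atoms retained for analysis (default: all).
    ``fit_mask`` selects the atoms the rigid-body fit is computed on
    (default: the analysis mask); fitting on a quasi-static core avoids
    leaking collective motion into the rigid-body parameters.
    ``reference`` is a full-system frame (default: the first equilibrated
    frame of the first replicate).
    """
    system = ensemble.system
    if mask is None:
        mask = SelectionMask(np.arange(system.n_atoms), system.n_atoms)
    if len(mask) < 1:
        raise ValueError("analysis mask is empty")
    fit = fit_mask if fit_mask is not None else mask
    if len(fit) < 3:
        raise ValueError("fit mask needs at least 3 atoms")
    windows = []
    for traj, win in zip(ensemble.trajectories, ensemble.windows):
        if win is None:
            raise ValueError("all replicate windows must be set before centering")
        windows.append((win.start_frame, win.end_frame))
    if reference is None:
        reference = ensemble.trajectories[0].coordinates[windows[0][0]]
    reference = np.asarray(reference, dtype=float)

    chunks = []
    per_rep = []
    for traj, (start, end) in zip(ensemble.trajectories, windows):
        block = np.empty((end - start, len(mask), 3))
        for k, f in enumerate(range(start, end)):
            fitted, _, _ = kabsch_superpose(
                traj.coordinates[f], reference, mask=fit
            )
            block[k] = fitted[mask.indices]
        chunks.append(block)
        per_rep.append(end - start)
    coords = np.concatenate(chunks, axis=0)
    mean = coords.mean(axis=0)
    return CenteredEnsemble(
        coordinates=coords - mean,
        mean_structure=mean,
        system=system,
        mask=mask,
        frames_per_replicate=tuple(per_rep),
    )


def _labels(centered: CenteredEnsemble) -> tuple[str, ...]:
    return tuple(
        centered.system.atoms[i].residue_key for i in centered.mask.indices
    )


def covariance_matrix(centered: CenteredEnsemble) -> CorrelationResult:
    """C_ij = <dr_i . dr_j> over pooled equilibrated frames (A^2)."""
    if centered.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    x = centered.coordinates
    c = np.einsum("fia,fja->ij", x, x) / x.shape[0]
    c = 0.5 * (c + c.T)
    return CorrelationResult(matrix=c, mode="covariance", labels=_labels(centered))


def dccm(centered: CenteredEnsemble) -> CorrelationResult:
    """Pearson-normalised cross-correlation matrix, entries in [-1, 1].

    The caller chooses the representative atoms through the centering mask;
    by convention one ``CA`` atom per residue (see :func:`ca_mask`), which
    makes the matrix residue x residue.
    """
    cov = covariance_matrix(centered).matrix
    var = np.diag(cov)
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        labels = _labels(centered)
        raise ValueError(
            f"zero-variance atom in DCCM: {labels[zero[0]]} "
            f"(selection index {zero[0]})"
        )
    norm = np.sqrt(var)
    m = cov / np.outer(norm, norm)
    np.fill_diagonal(m, 1.0)
    m = np.clip(0.5 * (m + m.T), -1.0, 1.0)
    return CorrelationResult(matrix=m, mode="normalized", labels=_labels(centered))


def ca_mask(system: MolecularSystem, name: str = "CA") -> SelectionMask:
    """One representative atom per residue: the ``CA``-named atom, falling
    back to the residue's first atom for non-standard residues."""
    indices = []
    for res in system.residues:
        named = [i for i in res.atom_indices if system.atoms[i].name == name]
        indices.append(named[0] if named else res.atom_indices[0])
    return SelectionMask(np.array(indices), system.n_atoms)


def eigendecompose(matrix: np.ndarray | CorrelationResult,
                   symmetry_tol: float = 1e-8) -> EigenResult:
    """Symmetric eigendecomposition, eigenvalues sorted non-increasing."""
    m = matrix.matrix if isinstance(matrix, CorrelationResult) else np.asarray(
        matrix, dtype=float
    )
    scale = max(1.0, np.abs(m).max())
    if not np.allclose(m, m.T, atol=symmetry_tol * scale):
        raise ValueError("matrix is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh(0.5 * (m + m.T))
    order = np.argsort(vals)[::-1]
    return EigenResult(eigenvalues=vals[order], eigenvectors=vecs[:, order])


def pca(centered: CenteredEnsemble) -> PcaResult:
    """Cartesian PCA of the pooled, superposed ensemble.

    Eigendecomposes the ``3N x 3N`` coordinate covariance; returns
    projections of every frame on every component, per-component variance
    fractions, and per-residue contributions (summed squared eigenvector
    entries over each residue's coordinates; they sum to 1 per component).
    """
    if centered.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    x = centered.coordinates.reshape(centered.n_frames, -1)  # (F, 3N)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 coordinates")
    cov = (x.T @ x) / x.shape[0]
    eig = eigendecompose(cov)
    vals = np.maximum(eig.eigenvalues, 0.0)
    variance_fraction = vals / vals.sum() if vals.sum() > 0 else vals
    projections = x @ eig.eigenvectors
    # per-residue contribution: squared eigvec weight summed over each
    # residue's (atom, xyz) entries
    res_of_sel = centered.system.residue_index_of_atom[centered.mask.indices]
    res_ids_present = np.unique(res_of_sel)
    sq = eig.eigenvectors**2  # (3N, n_comp)
    sq_per_atom = sq.reshape(len(centered.mask), 3, -1).sum(axis=1)
    contrib = np.zeros((res_ids_present.size, sq.shape[1]))
    for row, ri in enumerate(res_ids_present):
        contrib[row] = sq_per_atom[res_of_sel == ri].sum(axis=0)
    keys = [centered.system.residues[ri].key for ri in res_ids_present]
    contrib_df = pd.DataFrame(
        contrib, index=keys,
        columns=[f"PC{k + 1}" for k in range(sq.shape[1])],
    )
    return PcaResult(
        eigen=eig,
        projections=projections,
        variance_fraction=variance_fraction,
        residue_contributions=contrib_df,
        centered=centered,
    )


def interpolate_pc_extremes(
    pca_result: PcaResult, component: int = 0, n_steps: int = 10
) -> Trajectory:
    """Linear path between the most dissimilar structures along one component.

    Finds the frames with minimum and maximum projection on the component
    and emits ``n_steps`` structures reconstructed as the mean structure
    plus the linearly interpolated projection times the eigenvector.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    proj = pca_result.projections[:, component]
    lo, hi = float(proj.min()), float(proj.max())
    vec = pca_result.eigen.eigenvectors[:, component]
    mean = pca_result.centered.mean_structure
    alphas = np.linspace(lo, hi, n_steps)
    coords = mean[None] + (alphas[:, None] * vec[None]).reshape(n_steps, -1, 3)
    sub = subset_system(pca_result.centered.system, pca_result.centered.mask)
    times = np.arange(n_steps, dtype=float)
    return Trajectory(
        system=sub, coordinates=coords, times=times,
        label=f"pc{component + 1}_interpolation",
    )
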