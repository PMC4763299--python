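"""Cartesian-coordinate PCA of a conformational ensemble.

Snapshots (optionally strided, mirroring sparse snapshot sampling) are
rigid-body aligned to a fixed reference structure on the analysis selection;
the 3N×3N covariance matrix of the selected coordinates is diagonalized and
snapshots are projected onto the leading principal components.  The leading
PCs capture the collective motions that separate conformational states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import align_frames
from .io import StructureModel, Trajectory
from .selection import Selection, select_atoms

logger = logging.getLogger(__name__)

__all__ = ["PCAModel", "fit_pca", "project", "pc_scatter", "DegenerateEnsembleError"]


class DegenerateEnsembleError(ValueError):
    """The ensemble has (numerically) zero positional variance."""


@dataclass
class PCAModel:
    """Eigendecomposition of the aligned-coordinate covariance matrix.

    ``eigenvalues`` (Å², descending) are the mode amplitudes; ``eigenvectors``
    (rows, orthonormal 3N-vectors) the mode directions.  The sign of each
    eigenvector is fixed so its largest-magnitude component is positive,
    making the decomposition deterministic.
    """

    mean_coords: np.ndarray       # (3N,) Å, mean of aligned training frames
    eigenvalues: np.ndarray       # (3N,) Å², descending
    eigenvectors: np.ndarray      # (3N, 3N), row i = V_i
    n_atoms: int
    reference: StructureModel
    atom_indices: np.ndarray      # analysis selection on the reference topology
    fit_indices: np.ndarray       # alignment selection (defaults to atom_indices)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def explained_fraction(self, k: int) -> float:
        return float(self.eigenvalues[:k].sum() / self.total_variance)


def fit_pca(traj: Trajectory,
            sel: Selection | str | np.ndarray = "name CA",
            reference: StructureModel | None = None,
            stride: int = 1,
            fit_sel: Selection | str | np.ndarray | None = None) -> PCAModel:
    """Build covariance over aligned selected coordinates and diagonalize it.

    Every retained frame (one in ``stride``) is Kabsch-aligned to
    ``reference`` (default: first frame) on ``fit_sel`` (default: the
    analysis selection itself); the covariance uses the uniform average over
    retained frames.  Raises :class:`DegenerateEnsembleError` for a
    variance-free ensemble.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if reference is None:
        reference = traj[0]
    if isinstance(sel, (Selection, str)):
        idx = select_atoms(reference, sel)
    else:
        idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("PCA selection is empty")
    if reference.topology != traj.topology:
        raise ValueError("reference topology does not match the trajectory")
    if fit_sel is None:
        fit_idx = idx
    elif isinstance(fit_sel, (Selection, str)):
        fit_idx = select_atoms(reference, fit_sel)
    else:
        fit_idx = np.asarray(fit_sel, dtype=int)

    coords = traj.coords[::stride]
    if coords.shape[0] < 2:
        raise ValueError("PCA requires >= 2 retained frames after striding")

    aligned = align_frames(coords, reference.coords, fit_idx)
    x = aligned[:, idx, :].reshape(coords.shape[0], -1)   # (F, 3N)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    trace = float(np.trace(cov))
    if trace < 1e-12:
        raise DegenerateEnsembleError("ensemble has no positional variance after alignment")

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T                              # rows are components
    # deterministic sign: largest-magnitude component of each PC is positive
    signs = np.sign(evecs[np.arange(len(evecs)), np.argmax(np.abs(evecs), axis=1)])
    evecs = evecs * signs[:, None]

    logger.debug("PCA: %d frames, 3N=%d, PC1 explains %.1f%%",
                 x.shape[0], x.shape[1], 100 * evals[0] / evals.sum())
    return PCAModel(mean, evals, evecs, int(idx.size), reference.copy(), idx, fit_idx)


def project(model: PCAModel, frame: StructureModel, pc_index: int) -> float:
    """Projection of one structure onto PC ``pc_index`` (0-based), in Å.

    The frame is aligned to the model's reference on the PCA selection,
    the training mean subtracted, and the result dotted with the eigenvector.
    """
    if not 0 <= pc_index < len(model.eigenvalues):
        raise IndexError(f"pc_index {pc_index} out of range")
    if frame.topology != model.reference.topology:
        raise ValueError("frame topology does not match the PCA reference")
    aligned = align_frames(frame.coords[None], model.reference.coords, model.fit_indices)
    x = aligned[0, model.atom_indices, :].ravel()
    return float((x - model.mean_coords) @ model.eigenvectors[pc_index])


def pc_scatter(model: PCAModel, traj: Trajectory,
               n_components: int = 2) -> pd.DataFrame:
    """Per-frame projections onto the leading PCs as a tidy table."""
    if traj.topology != model.reference.topology:
        raise ValueError("trajectory topology does not match the PCA reference")
    aligned = align_frames(traj.coords, model.reference.coords, model.fit_indices)
    x = aligned[:, model.atom_indices, :].reshape(len(traj), -1) - model.mean_coords
    proj = x @ model.eigenvectors[:n_components].T
    data = {"frame": np.arange(len(traj))}
    for k in range(n_components):
        data[f"pc{k + 1}_A"] = proj[:, k]
    return pd.DataFrame(data)
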