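"""Dynamic cross-correlation of Cα displacement vectors.

For aligned frames, the correlation between atoms i and j is

    C(i, j) = <Δr_i · Δr_j> / sqrt(<|Δr_i|^2> <|Δr_j|^2>),

with Δr_i(t) = r_i(t) − <r_i> and <·> the uniform time average.  Values lie
in [−1, 1]: positive pairs move in the same direction, negative pairs in
opposite directions.  Alignment removes overall rotation/translation using
the same iterated-mean protocol as the RMSF calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import iterative_mean_alignment
from .io import Trajectory
from .selection import Selection, select_atoms

logger = logging.getLogger(__name__)

__all__ = ["DCCMatrix", "dccm"]


@dataclass
class DCCMatrix:
    """Residue-by-residue displacement correlation map, entries in [−1, 1].

    Zero-variance atoms yield NaN rows/columns (undefined, never silently 0).
    """

    residue_seqs: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residue_seqs)
        if self.matrix.shape != (n, n):
            raise ValueError("DCCM must be square over the selected residues")

    def to_dataframe(self, long_format: bool = False) -> pd.DataFrame:
        seqs = np.asarray(self.residue_seqs)
        if not long_format:
            return pd.DataFrame(self.matrix, index=seqs, columns=seqs)
        i, j = np.meshgrid(np.arange(len(seqs)), np.arange(len(seqs)), indexing="ij")
        return pd.DataFrame({"resseq_i": seqs[i.ravel()], "resseq_j": seqs[j.ravel()],
                             "cij": self.matrix.ravel()})


def dccm(traj: Trajectory,
         sel: Selection | str | np.ndarray = "name CA",
         fit_sel: Selection | str | np.ndarray = "name CA") -> DCCMatrix:
    """Displacement cross-correlation matrix over a selection.

    Frames are superposed onto the iteratively recomputed ensemble mean on
    ``fit_sel`` before displacements are measured, so one global rigid
    transform applied to every frame leaves the result unchanged.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    if isinstance(sel, (Selection, str)):
        idx = select_atoms(traj, sel)
    else:
        idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("selection is empty")

    aligned, mean = iterative_mean_alignment(traj, fit_sel)
    disp = aligned[:, idx, :] - mean[idx]          # (F, n, 3)
    inner = np.einsum("fia,fja->ij", disp, disp) / traj.n_frames
    var = np.diag(inner).copy()

    zero = var <= 1e-12          # static atoms: numerically zero variance, Å²
    if np.any(zero):
        logger.warning("DCCM: %d zero-variance atoms; their rows are undefined (NaN)",
                       int(zero.sum()))
    denom = np.sqrt(np.where(zero, np.nan, var))
    matrix = inner / denom[:, None] / denom[None, :]
    np.clip(matrix, -1.0, 1.0, out=matrix)
    matrix[np.diag_indices(len(matrix))] = np.where(zero, np.nan, 1.0)
    return DCCMatrix(traj.topology.residue_seqs[idx], matrix)
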