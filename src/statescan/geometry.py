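"""Rigid-body superposition and the per-frame metrics built on it.

Kabsch least-squares superposition (proper rotations only), RMSD time
series with separate fit/measure selections, iteratively re-aligned RMSF
profiles, and internal-coordinate distance/angle monitors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StructureModel, Trajectory
from .selection import Selection, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "SuperposeResult",
    "DistanceSeries",
    "ResidueProfile",
    "kabsch_rotation",
    "kabsch_superpose",
    "align_frames",
    "iterative_mean_alignment",
    "rmsd_series",
    "rmsf_profile",
    "pair_distance_series",
    "angle_series",
]


@dataclass(frozen=True)
class SuperposeResult:
    """Optimal rigid map ``x -> R x + t`` of a mobile onto a reference."""

    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd_after: float        # Å, over the fit selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DistanceSeries:
    """A per-frame scalar monitor (Å) such as d1, d2 or an RMSD trace."""

    label: str
    values: np.ndarray
    frames: np.ndarray | None = None
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frames is None:
            self.frames = np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": self.frames}
        if self.time_ps is not None:
            data["time_ps"] = self.time_ps
        data["value"] = self.values
        return pd.DataFrame(data)


@dataclass
class ResidueProfile:
    """One scalar per residue (e.g. Cα RMSF in Å)."""

    residue_seqs: np.ndarray
    values: np.ndarray
    label: str = "rmsf"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_seq": self.residue_seqs,
                             f"{self.label}_A": self.values})


def _resolve(obj, sel: Selection | str | np.ndarray) -> np.ndarray:
    if isinstance(sel, (Selection, str)):
        return select_atoms(obj, sel)
    return np.asarray(sel, dtype=int)


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||mobile @ R.T - reference|| for centered inputs.

    Reflections are corrected by flipping the smallest singular direction,
    so ``det(R) = +1`` always.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _check_fit_set(coords: np.ndarray, label: str) -> None:
    if coords.shape[0] < 3:
        raise ValueError(f"{label}: superposition needs >= 3 fit atoms, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    # rank < 2 means all fit atoms are collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError(f"{label}: fit atoms are collinear; rotation is underdetermined")


def kabsch_superpose(mobile: StructureModel, reference: StructureModel,
                     fit_sel: Selection | str | np.ndarray = "name CA",
                     ) -> tuple[SuperposeResult, StructureModel]:
    """Least-squares superpose ``mobile`` onto ``reference`` over a fit selection.

    Returns the optimal transform (applied to the *whole* model) and the
    transformed copy.  The fit set must contain at least three non-collinear
    atoms on both structures.
    """
    idx = _resolve(reference, fit_sel)
    if isinstance(fit_sel, (Selection, str)):
        idx_mobile = _resolve(mobile, fit_sel)
    else:
        idx_mobile = idx
    if len(idx) != len(idx_mobile):
        raise ValueError("fit selection resolves to different atom counts on mobile and reference")

    p = mobile.coords[idx_mobile]
    q = reference.coords[idx]
    _check_fit_set(p, "mobile")
    _check_fit_set(q, "reference")

    p_cent, q_cent = p.mean(axis=0), q.mean(axis=0)
    rot = kabsch_rotation(p - p_cent, q - q_cent)
    trans = q_cent - rot @ p_cent
    moved = mobile.transformed(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((moved.coords[idx_mobile] - q) ** 2, axis=1))))
    return SuperposeResult(rot, trans, rmsd), moved


def align_frames(coords: np.ndarray, reference: np.ndarray,
                 fit_idx: np.ndarray) -> np.ndarray:
    """Batch-superpose every frame of ``coords`` onto ``reference`` over ``fit_idx``.

    ``coords`` is (F, N, 3); the returned array has each frame optimally
    rotated/translated (whole frame moved, fit on the index subset).
    """
    coords = np.asarray(coords, dtype=float)
    ref_fit = reference[fit_idx]
    ref_cent = ref_fit.mean(axis=0)
    q = ref_fit - ref_cent

    mob_fit = coords[:, fit_idx, :]
    mob_cent = mob_fit.mean(axis=1, keepdims=True)
    p = mob_fit - mob_cent

    h = np.einsum("fai,aj->fij", p, q)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.transpose(vt, (0, 2, 1)) @ np.transpose(u, (0, 2, 1)))
    corr = np.tile(np.eye(3), (len(coords), 1, 1))
    corr[:, 2, 2] = np.sign(det)
    rot = np.transpose(vt, (0, 2, 1)) @ corr @ np.transpose(u, (0, 2, 1))

    centered = coords - mob_cent
    return np.einsum("fij,faj->fai", rot, centered) + ref_cent


def iterative_mean_alignment(traj: Trajectory,
                             fit_sel: Selection | str | np.ndarray = "name CA",
                             tol: float = 1e-4, max_iter: int = 10,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Align all frames to the ensemble mean, iterating until the mean converges.

    Protocol: align every frame to the current mean structure on the fit
    selection, recompute the mean, repeat until the RMS shift of the mean
    drops below ``tol`` Å (default 1e-4) or ``max_iter`` iterations.

    Returns ``(aligned_coords, mean_coords)``.
    """
    if traj.n_frames < 2:
        raise ValueError("mean alignment requires at least 2 frames")
    fit_idx = _resolve(traj, fit_sel)
    if fit_idx.size < 3:
        raise ValueError("fit selection must contain >= 3 atoms")

    mean = traj.coords[0]
    aligned = traj.coords
    for _ in range(max_iter):
        aligned = align_frames(traj.coords, mean, fit_idx)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return aligned, mean


def rmsd_series(traj: Trajectory, reference: StructureModel,
                fit_sel: Selection | str | np.ndarray = "name CA",
                measure_sel: Selection | str | np.ndarray | None = None,
                label: str = "rmsd") -> DistanceSeries:
    """Per-frame RMSD to a reference: superpose on ``fit_sel``, measure on ``measure_sel``.

    The two selections may differ (e.g. global Cα fit, switch-region
    measurement), which is how region-restricted plasticity is quantified.
    """
    fit_idx = _resolve(reference, fit_sel)
    measure_idx = fit_idx if measure_sel is None else _resolve(reference, measure_sel)
    if fit_idx.size < 3:
        raise ValueError("fit selection must contain >= 3 atoms")
    if measure_idx.size == 0:
        raise ValueError("measure selection is empty")

    aligned = align_frames(traj.coords, reference.coords, fit_idx)
    diff = aligned[:, measure_idx, :] - reference.coords[measure_idx]
    values = np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))
    time = None if traj.frame_interval is None else np.arange(len(traj)) * traj.frame_interval
    return DistanceSeries(label, values, time_ps=time)


def rmsf_profile(traj: Trajectory,
                 fit_sel: Selection | str | np.ndarray = "name CA",
                 measure_sel: Selection | str | np.ndarray = "name CA",
                 ) -> ResidueProfile:
    """Per-residue RMSF about the iteratively re-aligned ensemble mean.

    Per-atom RMSF is ``sqrt(<|r_i(t) - <r_i>|^2>_t)``; residues with several
    selected atoms report the mean of their atoms' RMSF.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    measure_idx = _resolve(traj, measure_sel)
    if measure_idx.size == 0:
        raise ValueError("measure selection is empty")
    aligned, mean = iterative_mean_alignment(traj, fit_sel)
    dev = aligned[:, measure_idx, :] - mean[measure_idx]
    per_atom = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))

    seqs = traj.topology.residue_seqs[measure_idx]
    order = []
    seen = set()
    for s in seqs:
        if s not in seen:
            order.append(s)
            seen.add(s)
    values = np.array([per_atom[seqs == s].mean() for s in order])
    return ResidueProfile(np.array(order), values)


def _single_atom(obj, sel: Selection | str | np.ndarray, label: str) -> int:
    idx = _resolve(obj, sel)
    if idx.size != 1:
        expr = sel.expression if isinstance(sel, Selection) else sel
        raise ValueError(f"{label}: selection {expr!r} resolves to {idx.size} atoms, need exactly 1")
    return int(idx[0])


def pair_distance_series(traj: Trajectory,
                         atom_a: Selection | str | np.ndarray,
                         atom_b: Selection | str | np.ndarray,
                         label: str = "distance") -> DistanceSeries:
    """Euclidean distance between two single atoms per frame (no superposition).

    Distances are internal coordinates and therefore invariant under any
    rigid motion of a frame.
    """
    ia = _single_atom(traj, atom_a, "atom_a")
    ib = _single_atom(traj, atom_b, "atom_b")
    diff = traj.coords[:, ia, :] - traj.coords[:, ib, :]
    values = np.linalg.norm(diff, axis=1)
    time = None if traj.frame_interval is None else np.arange(len(traj)) * traj.frame_interval
    return DistanceSeries(label, values, time_ps=time)


def angle_series(traj: Trajectory,
                 atom_a: Selection | str | np.ndarray,
                 atom_b: Selection | str | np.ndarray,
                 atom_c: Selection | str | np.ndarray,
                 label: str = "angle") -> DistanceSeries:
    """Angle a–b–c in degrees per frame, with b the vertex; range [0, 180]."""
    ia = _single_atom(traj, atom_a, "atom_a")
    ib = _single_atom(traj, atom_b, "atom_b")
    ic = _single_atom(traj, atom_c, "atom_c")
    v1 = traj.coords[:, ia, :] - traj.coords[:, ib, :]
    v2 = traj.coords[:, ic, :] - traj.coords[:, ib, :]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("coincident atoms: zero-length vector in angle computation")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    values = np.degrees(np.arccos(cosang))
    time = None if traj.frame_interval is None else np.arange(len(traj)) * traj.frame_interval
    return DistanceSeries(label, values, time_ps=time)
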