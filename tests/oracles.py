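"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately takes a different computational route than the
package (scipy rotation fitting instead of our SVD Kabsch, explicit Python
loops instead of vectorized estimators, naive agglomeration instead of the
linkage cut) so agreement is evidence of correctness, not of shared code.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def superposed_rmsd_scipy(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two point sets via scipy's rotation fitting."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot, _ = Rotation.align_vectors(qc, pc)
    return float(np.sqrt(np.mean(np.sum((rot.apply(pc) - qc) ** 2, axis=1))))


def superposed_rmsd_grid(p: np.ndarray, q: np.ndarray, n_grid: int = 10) -> float:
    """Minimum RMSD by dense Euler-angle grid search plus local refinement."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1))))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best_angles, best = None, np.inf
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, n_grid):
            for c in grid:
                v = cost((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(cost, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(min(best, res.fun))


def mean_align_scipy(coords: np.ndarray, fit_idx: np.ndarray,
                     tol: float = 1e-4, max_iter: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Iterated alignment to the ensemble mean, one scipy rotation fit per frame."""
    mean = coords[0].copy()
    aligned = coords.copy()
    for _ in range(max_iter):
        new = np.empty_like(coords)
        for f in range(coords.shape[0]):
            p = coords[f, fit_idx]
            q = mean[fit_idx]
            pc_cent, qc_cent = p.mean(axis=0), q.mean(axis=0)
            rot, _ = Rotation.align_vectors(q - qc_cent, p - pc_cent)
            new[f] = rot.apply(coords[f] - pc_cent) + qc_cent
        new_mean = new.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        aligned, mean = new, new_mean
        if shift < tol:
            break
    return aligned, mean


def dccm_loops(coords: np.ndarray, sel_idx: np.ndarray,
               fit_idx: np.ndarray) -> np.ndarray:
    """DCCM by explicit loops after scipy-based mean alignment."""
    aligned, mean = mean_align_scipy(coords, fit_idx)
    n_frames = coords.shape[0]
    n = len(sel_idx)
    disp = aligned[:, sel_idx, :] - mean[sel_idx]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(float(disp[f, i] @ disp[f, j]) for f in range(n_frames)) / n_frames
            vi = sum(float(disp[f, i] @ disp[f, i]) for f in range(n_frames)) / n_frames
            vj = sum(float(disp[f, j] @ disp[f, j]) for f in range(n_frames)) / n_frames
            out[i, j] = num / np.sqrt(vi * vj)
    return out


def average_linkage_naive(dist: np.ndarray, threshold: float) -> np.ndarray:
    """Naive agglomeration recomputing every inter-cluster average each step.

    Ties break to the lexicographically lowest pair of current cluster
    indices.  Returns labels renumbered densely by first member appearance.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best_pair, best_avg = None, np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = float(np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]]))
                if avg < best_avg - 1e-12:
                    best_avg, best_pair = avg, (a, b)
        if best_avg > threshold:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    order = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for new_id, c in enumerate(order):
        for member in clusters[c]:
            labels[member] = new_id
    # renumber by first appearance to match the package convention
    remap, out = {}, np.empty(n, dtype=int)
    for frame in range(n):
        lab = labels[frame]
        if lab not in remap:
            remap[lab] = len(remap)
        out[frame] = remap[lab]
    return out


def pca_eig_naive(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariance by explicit accumulation, eigenstructure via the generic solver."""
    n_frames, dim = x.shape
    mean = x.mean(axis=0)
    cov = np.zeros((dim, dim))
    for f in range(n_frames):
        d = x[f] - mean
        cov += np.outer(d, d)
    cov /= n_frames
    evals, evecs = np.linalg.eig(cov)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


def contacts_loops(coords: np.ndarray, ia, ib, cutoff: float) -> set[tuple[int, int]]:
    """All (a, b) pairs within cutoff by exhaustive scan."""
    found = set()
    for a in ia:
        for b in ib:
            if a != b and np.linalg.norm(coords[a] - coords[b]) <= cutoff:
                found.add((int(a), int(b)))
    return found


def water_bridges_loops(coords: np.ndarray, ia, ib, iw, cutoff: float) -> set[int]:
    """Water indices bridging two sites, by exhaustive triple scan."""
    bridges = set()
    for w in iw:
        ok_a = any(np.linalg.norm(coords[a] - coords[w]) <= cutoff for a in ia)
        ok_b = any(np.linalg.norm(coords[b] - coords[w]) <= cutoff for b in ib)
        if ok_a and ok_b:
            bridges.add(int(w))
    return bridges


def two_sphere_sasa_caps(r: float, probe: float, d: float) -> float:
    """Closed-form per-sphere SASA for two equal spheres at center distance d."""
    big_r = r + probe
    if d >= 2 * big_r:
        return 4.0 * np.pi * big_r ** 2
    h = big_r - d / 2.0
    return 4.0 * np.pi * big_r ** 2 - 2.0 * np.pi * big_r * h
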