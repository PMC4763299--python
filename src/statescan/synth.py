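"""Synthetic GTPase-like ensembles with known two-state ground truth.

The generator builds a compact pseudo-fold — Cα atoms of a 70-residue
chain laid along a constant-speed spherical spiral, with backbone N/C/O
atoms attached along the local tangent frame — and buries a pseudo-
nucleotide (PA/PB/PG phosphates with their oxygens) between the switch-I
and switch-II analogue segments, at prescribed diagnostic distances
d1 (residue-60 Cα to Pβ) and d2 (residue-35 Cα to Pβ).  A two-state
trajectory alternates between a *closed* (active-like) and an *open*
(inactive-like) centroid via a stationary two-state Markov chain; the open
centroid rigidly retracts both switch segments away from the nucleotide,
which raises the nucleotide's accessible surface by construction.  Each
frame adds isotropic iid Gaussian noise to every atom, so fluctuation and
correlation statistics have analytic expectations; coherent motion enters
only through state switching.

Nothing here aims at physical realism beyond named atoms and distance
scales — the point is desk-scale ground truth for every analysis stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import StructureModel, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ToySystemSpec",
    "TwoStateSpec",
    "TwoStateResult",
    "build_toy_gtpase",
    "simulate_two_state_trajectory",
    "transition_matrix_for",
    "ground_truth_table",
    "CLOSED", "OPEN",
]

CLOSED, OPEN = 0, 1
STATE_NAMES = {CLOSED: "closed", OPEN: "open"}

_ELEMENT_FROM_NAME = {"MG": "MG"}


def _element_of(name: str) -> str:
    if name in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass(frozen=True)
class ToySystemSpec:
    """Parameters of the base (closed) pseudo-GTPase structure."""

    n_residues: int = 70
    switch_segment: tuple[int, int] = (59, 67)     # switch-II analogue, contains residue 60
    switch1_segment: tuple[int, int] = (32, 38)    # switch-I analogue, contains residue 35
    d1_residue: int = 60                           # glycine analogue, Cα defines d1
    d2_residue: int = 35                           # threonine analogue, Cα defines d2
    catalytic_residue: int = 61                    # glutamine analogue (OE1/NE2)
    arg_finger_residue: int = 789                  # pseudo arginine finger, chain B
    ligand_name: str = "GTP"                       # or "GDP" (no γ-phosphate)
    d1_base: float = 6.8                           # Å, closed-state d1
    d2_base: float = 6.5                           # Å, closed-state d2
    sphere_radius: float = 11.0                    # Å, pseudo-fold shell radius
    include_waters: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.switch_segment, self.switch1_segment):
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError("switch segments must lie within [1, n_residues]")
        if not self.switch_segment[0] <= self.d1_residue <= self.switch_segment[1]:
            raise ValueError("d1 residue must lie in the switch segment")
        if not self.switch1_segment[0] <= self.d2_residue <= self.switch1_segment[1]:
            raise ValueError("d2 residue must lie in the switch-I segment")
        if self.ligand_name not in ("GTP", "GDP"):
            raise ValueError("ligand must be GTP or GDP")


def _spiral_ca_positions(n: int, radius: float) -> np.ndarray:
    """Cα positions along a constant-speed spherical spiral (3.8 Å steps)."""
    bond = 3.8
    total = bond * (n - 1)
    k = max(total / (2.0 * radius), 4.0)          # winding number of the spiral

    # arc-length parametrization by dense numerical integration
    phi = np.linspace(1e-3, np.pi - 1e-3, 20000)
    speed = radius * np.sqrt(1.0 + (k * np.sin(phi)) ** 2)
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(phi))])
    targets = np.linspace(0.0, arc[-1], n)
    phi_i = np.interp(targets, arc, phi)
    lam = k * phi_i
    return radius * np.column_stack([
        np.sin(phi_i) * np.cos(lam),
        np.sin(phi_i) * np.sin(lam),
        np.cos(phi_i),
    ])


def _segment_weights(n_residues: int, segment: tuple[int, int], ramp: int = 3) -> np.ndarray:
    """Per-residue displacement weights: 1 inside the segment, cosine decay outside.

    The ramp keeps the chain continuous when a segment is pulled toward the
    ligand pocket instead of tearing it off its neighbors.
    """
    w = np.zeros(n_residues)
    lo, hi = segment
    for seq in range(1, n_residues + 1):
        if lo <= seq <= hi:
            w[seq - 1] = 1.0
        else:
            d = min(abs(seq - lo), abs(seq - hi))
            if d <= ramp:
                w[seq - 1] = 0.5 * (1.0 + np.cos(np.pi * d / (ramp + 1)))
    return w


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e1 = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(e1 @ ref) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return e1, e2, e3


def build_toy_gtpase(spec: ToySystemSpec | None = None) -> StructureModel:
    """Deterministic closed-state pseudo-GTPase with all named atoms present.

    Chain A: the pseudo-fold (backbone N/CA/C/O, THR-analogue OG1 at the d2
    residue, GLN-analogue OE1/NE2 at the catalytic residue).  Chain B: a
    minimal arginine-finger residue (CA/CZ/NH1/NH2) pre-positioned for salt
    bridges with the α- and γ-phosphate oxygens.  HETATM records: the
    pseudo-nucleotide, one Mg²⁺, and waters (one bridging the catalytic
    carbonyl oxygen and a γ-oxygen; the rest on an outer shell).
    """
    spec = spec or ToySystemSpec()
    ca = _spiral_ca_positions(spec.n_residues, spec.sphere_radius)

    # pocket point between the diagnostic anchors, pulled toward the interior
    a60 = ca[spec.d1_residue - 1]
    a35 = ca[spec.d2_residue - 1]
    mid = 0.5 * (a60 + a35)
    pb = 0.75 * mid

    # pull both switch segments inward so the anchors sit at the prescribed
    # diagnostic distances from Pβ (windowed, chain stays continuous)
    for segment, anchor_seq, target in ((spec.switch_segment, spec.d1_residue, spec.d1_base),
                                        (spec.switch1_segment, spec.d2_residue, spec.d2_base)):
        anchor = ca[anchor_seq - 1]
        u = (anchor - pb) / np.linalg.norm(anchor - pb)
        shift = (pb + target * u) - anchor
        ca = ca + np.outer(_segment_weights(spec.n_residues, segment), shift)

    a60 = ca[spec.d1_residue - 1]
    a35 = ca[spec.d2_residue - 1]
    # phosphate chain axis: perpendicular-ish to both anchor directions
    e1, e2, e3 = _orthonormal_frame(np.cross(a60 - pb, a35 - pb))
    pa = pb - 3.0 * e1
    pg = pb + 3.0 * e1

    records: list[tuple] = []   # (name, resname, chain, resseq, pos, hetero)

    def tangent(i: int) -> np.ndarray:
        lo = max(i - 1, 0)
        hi = min(i + 1, spec.n_residues - 1)
        t = ca[hi] - ca[lo]
        return t / np.linalg.norm(t)

    for i in range(spec.n_residues):
        seq = i + 1
        resname = "GLY"
        if seq == spec.d2_residue:
            resname = "THR"
        elif seq == spec.catalytic_residue:
            resname = "GLN"
        t = tangent(i)
        out = ca[i] / np.linalg.norm(ca[i])       # outward shell normal
        records.append(("N", resname, "A", seq, ca[i] - 1.2 * t + 0.5 * out, False))
        records.append(("CA", resname, "A", seq, ca[i], False))
        records.append(("C", resname, "A", seq, ca[i] + 1.2 * t + 0.3 * out, False))
        records.append(("O", resname, "A", seq, ca[i] + 1.4 * t + 1.4 * out, False))
        if resname == "THR":
            toward = pb - ca[i]
            toward /= np.linalg.norm(toward)
            records.append(("OG1", resname, "A", seq, ca[i] + 2.4 * toward, False))
        if resname == "GLN":
            toward = pg - ca[i]
            dist = np.linalg.norm(toward)
            toward /= dist
            oe1 = ca[i] + (dist - 4.0) * toward   # carbonyl O sits 4 Å from Pγ
            _, p2, _ = _orthonormal_frame(toward)
            records.append(("OE1", resname, "A", seq, oe1, False))
            records.append(("NE2", resname, "A", seq, oe1 + 1.1 * p2 - 0.6 * toward, False))

    # pseudo arginine finger on chain B, salt-bridge competent
    o1a = pa + 1.5 * e2
    o1g = pg + 1.5 * e2
    out_dir = -e3 if (pb @ e3) > 0 else e3        # away from the fold center
    nh1 = o1g + 3.0 * out_dir
    nh2 = o1a + 3.0 * out_dir
    cz = 0.5 * (nh1 + nh2) + 1.2 * out_dir
    records.append(("CA", "ARG", "B", spec.arg_finger_residue, cz + 3.8 * out_dir, False))
    records.append(("CZ", "ARG", "B", spec.arg_finger_residue, cz, False))
    records.append(("NH1", "ARG", "B", spec.arg_finger_residue, nh1, False))
    records.append(("NH2", "ARG", "B", spec.arg_finger_residue, nh2, False))

    # pseudo-nucleotide: PA/PB/PG with two (α) and three (β, γ) oxygens each
    lig = spec.ligand_name
    records.append(("PA", lig, "A", 201, pa, True))
    records.append(("O1A", lig, "A", 201, o1a, True))
    records.append(("O2A", lig, "A", 201, pa - 1.5 * e2, True))
    records.append(("PB", lig, "A", 201, pb, True))
    records.append(("O1B", lig, "A", 201, pb + 1.5 * e2, True))
    records.append(("O2B", lig, "A", 201, pb - 1.5 * e2, True))
    records.append(("O3B", lig, "A", 201, pb + 1.5 * e3, True))
    if lig == "GTP":
        records.append(("PG", lig, "A", 201, pg, True))
        records.append(("O1G", lig, "A", 201, o1g, True))
        records.append(("O2G", lig, "A", 201, pg - 1.5 * e2, True))
        records.append(("O3G", lig, "A", 201, pg + 1.5 * e3, True))

    records.append(("MG", "MG", "A", 202, pb + 1.5 * e2 + 2.0 * e3, True))

    if spec.include_waters > 0:
        oe1_pos = next(p for (n, r, c, s, p, h) in records
                       if n == "OE1" and s == spec.catalytic_residue)
        anchor = o1g if lig == "GTP" else pb + 1.5 * e2
        bridge = 0.5 * (oe1_pos + anchor)
        records.append(("O", "HOH", "W", 301, bridge, True))
        shell = _spiral_ca_positions(max(spec.include_waters - 1, 1),
                                     spec.sphere_radius + 6.0)
        for w in range(spec.include_waters - 1):
            records.append(("O", "HOH", "W", 302 + w, shell[w], True))

    names = [r[0] for r in records]
    topology = Topology(
        serials=np.arange(1, len(records) + 1),
        names=names,
        residue_names=[r[1] for r in records],
        chain_ids=[r[2] for r in records],
        residue_seqs=[r[3] for r in records],
        elements=[_element_of(n) for n in names],
        is_hetero=[r[5] for r in records],
    )
    coords = np.array([r[4] for r in records], dtype=float)
    return StructureModel(topology, coords, model_id=1)


def transition_matrix_for(p_open: float, mixing: float = 0.2) -> np.ndarray:
    """Row-stochastic 2×2 switching matrix with stationary open occupancy ``p_open``.

    ``mixing`` = (closed→open rate) + (open→closed rate) sets how fast the
    chain decorrelates (per-frame autocorrelation is ``1 − mixing``).
    """
    if not 0.0 <= p_open <= 1.0:
        raise ValueError("p_open must lie in [0, 1]")
    if not 0.0 < mixing <= 1.0:
        raise ValueError("mixing must lie in (0, 1]")
    a = mixing * p_open          # closed -> open
    b = mixing * (1.0 - p_open)  # open -> closed
    return np.array([[1.0 - a, a], [b, 1.0 - b]])


@dataclass
class TwoStateSpec:
    """Two conformational basins plus Markov switching between them.

    The open centroid differs from the closed one only in the rigid
    displacement of the two switch segments directly away from the
    nucleotide Pβ atom, tuned so d1 has the stated per-state means.
    """

    closed_centroid: np.ndarray
    open_centroid: np.ndarray
    transition: np.ndarray = field(default_factory=lambda: transition_matrix_for(0.3))
    sigma: float = 0.3            # Å, per-coordinate iid Gaussian noise
    n_frames: int = 5000
    seed: int = 1
    frame_interval: float = 20.0  # ps per snapshot
    d1_means: tuple[float, float] = (6.8, 9.0)

    def __post_init__(self) -> None:
        self.closed_centroid = np.asarray(self.closed_centroid, float)
        self.open_centroid = np.asarray(self.open_centroid, float)
        if self.closed_centroid.shape != self.open_centroid.shape:
            raise ValueError("centroids must be topology-identical (same shape)")
        self.transition = np.asarray(self.transition, float)
        if self.transition.shape != (2, 2) or np.any(self.transition < 0) \
                or not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix must be 2x2 row-stochastic")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @classmethod
    def from_base(cls, base: StructureModel, spec: ToySystemSpec | None = None,
                  d1_closed: float = 6.8, d1_open: float = 9.0,
                  switch1_shift: float = 3.0, switch2_swing: float = 4.0,
                  p_active: float = 0.7,
                  mixing: float = 0.2, sigma: float = 0.3,
                  n_frames: int = 5000, seed: int = 1) -> "TwoStateSpec":
        """Derive closed/open centroids from a base structure.

        ``p_active`` is the stationary occupancy of the closed (active-like)
        basin.  In the open centroid the switch-II segment moves rigidly so
        that its anchor Cα sits exactly ``d1_open`` Å from Pβ, combining a
        radial retraction with a ``switch2_swing`` Å lateral swing (the
        outward rearrangement of the flexible switch II); switch-I retracts
        ``switch1_shift`` Å straight away from the nucleotide.  The two
        basins therefore differ well beyond the clustering threshold on a
        Cα-RMSD scale while d1 keeps its prescribed per-state means.
        """
        spec = spec or ToySystemSpec()
        top = base.topology
        pb = base.coords[(top.names == "PB") & top.is_hetero][0]
        ca60 = base.coords[(top.names == "CA") & (top.residue_seqs == spec.d1_residue)
                           & (top.chain_ids == "A")][0]
        ca35 = base.coords[(top.names == "CA") & (top.residue_seqs == spec.d2_residue)
                           & (top.chain_ids == "A")][0]
        u2 = (ca60 - pb) / np.linalg.norm(ca60 - pb)
        u1 = (ca35 - pb) / np.linalg.norm(ca35 - pb)
        d1_base = float(np.linalg.norm(ca60 - pb))
        if not 0.0 <= switch2_swing < d1_open:
            raise ValueError("switch2_swing must lie in [0, d1_open)")
        lateral = np.cross(u2, u1)
        lateral /= np.linalg.norm(lateral)

        in_seg = lambda seg: ((top.residue_seqs >= seg[0]) & (top.residue_seqs <= seg[1])
                              & (top.chain_ids == "A") & ~top.is_hetero)
        sw2 = in_seg(spec.switch_segment)
        sw1 = in_seg(spec.switch1_segment)

        closed = base.coords.copy()
        closed[sw2] += (d1_closed - d1_base) * u2
        opened = base.coords.copy()
        radial = np.sqrt(d1_open ** 2 - switch2_swing ** 2)
        opened[sw2] += (radial - d1_base) * u2 + switch2_swing * lateral
        opened[sw1] += switch1_shift * u1
        return cls(closed, opened, transition_matrix_for(1.0 - p_active, mixing),
                   sigma=sigma, n_frames=n_frames, seed=seed,
                   d1_means=(d1_closed, d1_open))


@dataclass
class TwoStateResult:
    """A simulated ensemble plus its hidden ground truth."""

    trajectory: Trajectory
    states: np.ndarray            # 0 = closed, 1 = open, per frame
    stationary: np.ndarray        # stationary distribution of the chain

    def state_names(self) -> np.ndarray:
        return np.array([STATE_NAMES[s] for s in self.states])


def _stationary_distribution(t: np.ndarray) -> np.ndarray:
    a, b = t[0, 1], t[1, 0]
    if a + b == 0.0:
        return np.array([1.0, 0.0])       # absorbing: convention, start-state driven
    return np.array([b / (a + b), a / (a + b)])


def simulate_two_state_trajectory(base: StructureModel,
                                  spec: TwoStateSpec) -> TwoStateResult:
    """Markov-switched two-basin trajectory with iid Gaussian positional noise.

    Frame t is ``centroid(state_t) + N(0, sigma²)`` on every coordinate; the
    initial state is drawn from the stationary distribution.  A single
    seeded random stream drives state switching and noise, so output is
    bitwise reproducible.
    """
    if spec.closed_centroid.shape != (base.n_atoms, 3):
        raise ValueError("centroids do not match the base topology")
    rng = np.random.default_rng(spec.seed)
    pi = _stationary_distribution(spec.transition)

    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(2, p=pi)
    jumps = rng.random(spec.n_frames)
    for t in range(1, spec.n_frames):
        # next state is OPEN with probability transition[prev, OPEN]
        states[t] = int(jumps[t] < spec.transition[states[t - 1], OPEN])

    centroids = np.stack([spec.closed_centroid, spec.open_centroid])
    noise = rng.normal(0.0, spec.sigma, size=(spec.n_frames, base.n_atoms, 3))
    coords = centroids[states] + noise
    traj = Trajectory(base.topology, coords, frame_interval=spec.frame_interval)
    occ = np.bincount(states, minlength=2) / spec.n_frames
    logger.debug("simulated %d frames: closed %.3f / open %.3f (stationary %.3f/%.3f)",
                 spec.n_frames, occ[0], occ[1], pi[0], pi[1])
    return TwoStateResult(traj, states, pi)


def ground_truth_table(states: np.ndarray) -> pd.DataFrame:
    """Per-frame true state labels for scoring recovery, as a tidy table."""
    states = np.asarray(states, dtype=int)
    return pd.DataFrame({"frame": np.arange(len(states)),
                         "true_state": [STATE_NAMES[s] for s in states]})


def ground_truth_occupancies(states: np.ndarray) -> dict[str, float]:
    """Realized per-state occupancy of a ground-truth state sequence."""
    states = np.asarray(states, dtype=int)
    if len(states) == 0:
        return {name: 0.0 for name in STATE_NAMES.values()}
    counts = np.bincount(states, minlength=2) / len(states)
    return {STATE_NAMES[s]: float(counts[s]) for s in (CLOSED, OPEN)}
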