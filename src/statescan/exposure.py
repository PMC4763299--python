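"""Nucleotide exposure (Shrake–Rupley SASA) and polar-contact detection.

SASA uses a deterministic golden-spiral point set on each probe-expanded
atom sphere; a point is accessible when it lies outside every occluder's
expanded sphere.  Contact detectors (heavy-atom H-bond, salt bridge,
water-mediated bridge) are plain distance criteria, since trajectory
snapshots may lack hydrogens.  A catalytic-site report aggregates the
distance/angle monitors of the glutamine–arginine-finger arrangement and
their contact occupancies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DistanceSeries, angle_series, pair_distance_series
from .io import StructureModel, Trajectory
from .selection import Selection, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "RadiusSet",
    "SASAResult",
    "ContactEvent",
    "CatalyticSiteConfig",
    "CatalyticReport",
    "sphere_points",
    "shrake_rupley_sasa",
    "ligand_sasa_series",
    "percent_change",
    "detect_hbonds",
    "detect_salt_bridges",
    "water_mediated_bridges",
    "catalytic_site_report",
]

# Bondi-style van der Waals radii, Å, keyed by element symbol
_DEFAULT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CL": 1.75, "F": 1.47,
}


@dataclass(frozen=True)
class RadiusSet:
    """Van der Waals radii by element plus the solvent probe radius."""

    radii: dict = field(default_factory=lambda: dict(_DEFAULT_RADII))
    probe_radius: float = 1.4
    default_radius: float | None = 1.7

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            if self.default_radius is None:
                raise KeyError(f"no van der Waals radius for element {element!r}")
            return self.default_radius
        return r


@dataclass
class SASAResult:
    """Per-atom SASA (Å²) of the target atoms; total is their plain sum."""

    atom_indices: np.ndarray
    per_atom: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _resolve(obj, sel) -> np.ndarray:
    if sel is None:
        return np.array([], dtype=int)
    if isinstance(sel, (Selection, str)):
        return select_atoms(obj, sel)
    return np.asarray(sel, dtype=int)


def shrake_rupley_sasa(model: StructureModel,
                       radii: RadiusSet | None = None,
                       n_points: int = 960,
                       context_sel: Selection | str | np.ndarray | None = None,
                       target_sel: Selection | str | np.ndarray = "all",
                       ) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area of the target atoms.

    For each target atom, ``n_points`` golden-spiral points are placed at
    radius ``r_atom + probe``; a point counts as accessible if it lies
    outside the expanded sphere of every occluder.  Occluders are the union
    of target and context atoms (minus the atom itself), so target atoms
    shadow one another; with an empty context the result is the isolated
    SASA of the target group.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12 for a usable quadrature")
    radii = radii or RadiusSet()
    target = _resolve(model, target_sel)
    if target.size == 0:
        raise ValueError("target selection is empty")
    context = _resolve(model, context_sel)

    occluders = np.union1d(target, context)
    r_all = np.array([radii.radius_of(e) for e in model.topology.elements[occluders]])
    occ_coords = model.coords[occluders]
    occ_expanded = r_all + radii.probe_radius
    unit = sphere_points(n_points)

    per_atom = np.zeros(target.size)
    pos_in_occ = {int(a): k for k, a in enumerate(occluders)}
    for t_pos, a in enumerate(target):
        r_a = radii.radius_of(str(model.topology.elements[a])) + radii.probe_radius
        pts = model.coords[a] + r_a * unit
        # occluders within reach of this atom's surface shell
        d_center = np.linalg.norm(occ_coords - model.coords[a], axis=1)
        near = np.flatnonzero(d_center < r_a + occ_expanded)
        near = near[near != pos_in_occ[int(a)]]
        if near.size == 0:
            accessible = n_points
        else:
            d2 = np.sum((pts[:, None, :] - occ_coords[near][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < occ_expanded[near][None, :] ** 2, axis=1)
            accessible = int(n_points - buried.sum())
        per_atom[t_pos] = 4.0 * np.pi * r_a * r_a * accessible / n_points
    return SASAResult(target, per_atom)


def ligand_sasa_series(traj: Trajectory,
                       radii: RadiusSet | None = None,
                       ligand_sel: Selection | str | np.ndarray = "hetero and not water",
                       context_sel: Selection | str | np.ndarray | None = "protein",
                       n_points: int = 960,
                       frames: np.ndarray | None = None) -> DistanceSeries:
    """Per-frame total SASA (Å²) of a bound ligand, occluded by the protein.

    Waters/ions are excluded from the default context: solvent must not
    occlude solvent accessibility.  ``frames`` restricts evaluation to a
    subset of frame indices (the series is indexed by those frames).
    """
    radii = radii or RadiusSet()
    frame_idx = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    values = np.empty(frame_idx.size)
    for k, f in enumerate(frame_idx):
        res = shrake_rupley_sasa(traj[int(f)], radii, n_points,
                                 context_sel=context_sel, target_sel=ligand_sel)
        values[k] = res.total
    return DistanceSeries("ligand_sasa", values, frames=frame_idx)


def percent_change(series: DistanceSeries | np.ndarray,
                   baseline: DistanceSeries | np.ndarray) -> float:
    """Percent change of one series' mean relative to a baseline series' mean."""
    v = series.values if isinstance(series, DistanceSeries) else np.asarray(series, float)
    b = baseline.values if isinstance(baseline, DistanceSeries) else np.asarray(baseline, float)
    base = float(np.mean(b))
    if base == 0.0:
        raise ZeroDivisionError("baseline mean is zero")
    return 100.0 * (float(np.mean(v)) - base) / base


@dataclass(frozen=True)
class ContactEvent:
    """One detected polar contact in one frame."""

    frame: int
    kind: str                      # hbond | salt_bridge | water_bridge
    atom_a: int                    # atom index of the first partner
    atom_b: int
    distance: float                # Å; for bridges, the longer leg
    water: int | None = None       # bridging water oxygen index


def _atom_label(model: StructureModel, i: int) -> str:
    t = model.topology
    return f"{t.residue_names[i]}{t.residue_seqs[i]}:{t.names[i]}"


def _pair_contacts(model: StructureModel, sel_a, sel_b, cutoff: float,
                   kind: str, frame: int) -> list[ContactEvent]:
    ia = _resolve(model, sel_a)
    ib = _resolve(model, sel_b)
    if ia.size == 0 or ib.size == 0:
        return []
    diff = model.coords[ia][:, None, :] - model.coords[ib][None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=2))
    events = []
    for p, q in zip(*np.nonzero(dist <= cutoff)):
        if ia[p] == ib[q]:
            continue
        events.append(ContactEvent(frame, kind, int(ia[p]), int(ib[q]),
                                   float(dist[p, q])))
    return events


def detect_hbonds(model: StructureModel,
                  donors: Selection | str | np.ndarray,
                  acceptors: Selection | str | np.ndarray,
                  cutoff: float = 3.5,
                  frame: int = 0) -> list[ContactEvent]:
    """Heavy-atom hydrogen bonds: donor–acceptor pairs within ``cutoff`` Å.

    A pure distance criterion (no angle term), applicable to hydrogen-free
    snapshots.
    """
    return _pair_contacts(model, donors, acceptors, cutoff, "hbond", frame)


def detect_salt_bridges(model: StructureModel,
                        basic_sel: Selection | str | np.ndarray,
                        acidic_sel: Selection | str | np.ndarray,
                        cutoff: float = 4.0,
                        frame: int = 0) -> list[ContactEvent]:
    """Salt bridges: charged nitrogen–oxygen pairs within ``cutoff`` Å (4.0 default)."""
    return _pair_contacts(model, basic_sel, acidic_sel, cutoff, "salt_bridge", frame)


def water_mediated_bridges(model: StructureModel,
                           site_a: Selection | str | np.ndarray,
                           site_b: Selection | str | np.ndarray,
                           water_sel: Selection | str | np.ndarray = "water and name O",
                           cutoff: float = 3.5,
                           frame: int = 0) -> list[ContactEvent]:
    """Water oxygens bridging two sites: both legs within ``cutoff`` Å."""
    ia = _resolve(model, site_a)
    ib = _resolve(model, site_b)
    iw = _resolve(model, water_sel)
    events = []
    for w in iw:
        da = np.linalg.norm(model.coords[ia] - model.coords[w], axis=1) if ia.size else np.array([])
        db = np.linalg.norm(model.coords[ib] - model.coords[w], axis=1) if ib.size else np.array([])
        if da.size and db.size and da.min() <= cutoff and db.min() <= cutoff:
            pa = int(ia[np.argmin(da)])
            pb = int(ib[np.argmin(db)])
            events.append(ContactEvent(frame, "water_bridge", pa, pb,
                                       float(max(da.min(), db.min())), water=int(w)))
    return events


@dataclass(frozen=True)
class CatalyticSiteConfig:
    """Named selections for the catalytic-competence monitors.

    Defaults follow glutamine at position 61 (OE1/NE2) and an
    arginine-finger residue 789 on a separate chain; a histidine variant is
    expressed by overriding the two side-chain selections (ND1/NE2).
    """

    q61_carbonyl: str = "resseq 61 and name OE1"      # H-extraction oxygen (ND1 for His)
    q61_amide: str = "resseq 61 and name NE2"
    arg_nh: str = "resseq 789 and name NH1,NH2"
    gamma_p: str = "name PG and hetero"
    alpha_oxygens: str = "name O1A,O2A and hetero"
    gamma_oxygens: str = "name O1G,O2G,O3G and hetero"
    waters: str = "water and name O"
    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    contact_cutoff: float = 4.5    # occupancy cutoff for the Q61–Pγ monitor


@dataclass
class CatalyticReport:
    """Per-frame catalytic monitors and their contact occupancies."""

    q61_pg_distance: DistanceSeries
    arg_alpha_distance: DistanceSeries        # min over NH1/NH2 × α-oxygens
    arg_gamma_distance: DistanceSeries        # min over NH1/NH2 × γ-oxygens
    q61_angle: DistanceSeries                 # NE2–(carbonyl O)–Pγ, degrees
    occupancies: dict

    def to_frame_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.q61_pg_distance.frames,
            "q61_pg_A": self.q61_pg_distance.values,
            "arg_alpha_A": self.arg_alpha_distance.values,
            "arg_gamma_A": self.arg_gamma_distance.values,
            "q61_angle_deg": self.q61_angle.values,
        })


def _min_group_distance(traj: Trajectory, sel_a, sel_b) -> np.ndarray:
    ia = _resolve(traj, sel_a)
    ib = _resolve(traj, sel_b)
    if ia.size == 0 or ib.size == 0:
        missing = []
        if ia.size == 0:
            missing.append(repr(sel_a))
        if ib.size == 0:
            missing.append(repr(sel_b))
        raise ValueError(f"unresolved catalytic-site selections: {', '.join(missing)}")
    diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
    return np.sqrt(np.sum(diff ** 2, axis=3)).min(axis=(1, 2))


def catalytic_site_report(traj: Trajectory,
                          site: CatalyticSiteConfig | None = None) -> CatalyticReport:
    """Distance/angle monitors of the Q61/arginine-finger arrangement.

    Reports per frame: carbonyl-O(61)–Pγ distance, minimum arginine
    NH1/NH2 distance to the α- and γ-phosphate oxygens, and the
    NE2–O(carbonyl)–Pγ angle (vertex at the middle-listed atom).
    Occupancies are fractions of frames with each contact under its cutoff,
    plus the water-bridge occupancy between the carbonyl oxygen and the
    γ-oxygens.
    """
    site = site or CatalyticSiteConfig()
    q61_pg = pair_distance_series(traj, site.q61_carbonyl, site.gamma_p, label="q61_pg")
    arg_alpha = DistanceSeries("arg_alpha", _min_group_distance(traj, site.arg_nh, site.alpha_oxygens))
    arg_gamma = DistanceSeries("arg_gamma", _min_group_distance(traj, site.arg_nh, site.gamma_oxygens))
    angle = angle_series(traj, site.q61_amide, site.q61_carbonyl, site.gamma_p,
                         label="q61_angle")

    water_idx = _resolve(traj, site.waters)
    bridge_frames = 0
    if water_idx.size:
        for f in range(traj.n_frames):
            events = water_mediated_bridges(traj[f], site.q61_carbonyl,
                                            site.gamma_oxygens, site.waters,
                                            cutoff=site.hbond_cutoff, frame=f)
            bridge_frames += bool(events)

    n = traj.n_frames
    occupancies = {
        "q61_pg_contact": float(np.mean(q61_pg.values <= site.contact_cutoff)),
        "arg_alpha_salt_bridge": float(np.mean(arg_alpha.values <= site.salt_bridge_cutoff)),
        "arg_gamma_salt_bridge": float(np.mean(arg_gamma.values <= site.salt_bridge_cutoff)),
        "catalytic_water_bridge": bridge_frames / n if water_idx.size else 0.0,
    }
    return CatalyticReport(q61_pg, arg_alpha, arg_gamma, angle, occupancies)
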