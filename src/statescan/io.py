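"""Multi-model PDB ensembles and the in-memory types all analyses consume.

A conformational ensemble is held as a :class:`Trajectory`: one shared
:class:`Topology` (atom names, residues, chains, elements) plus a dense
``(n_frames, n_atoms, 3)`` coordinate array in Å.  Individual conformers are
exposed as :class:`StructureModel` views.  The only on-disk trajectory format
is the multi-model PDB (fixed-width v3 records, one MODEL/ENDMDL block per
frame); parsing and serialization are delegated to :mod:`biotite`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Topology",
    "StructureModel",
    "Trajectory",
    "StructureIOError",
    "PDBParseError",
    "TopologyMismatchError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]


class StructureIOError(Exception):
    """Base class for ensemble I/O failures."""


class PDBParseError(StructureIOError):
    """A PDB record could not be parsed (malformed coordinates or fields)."""


class TopologyMismatchError(StructureIOError):
    """Models of one ensemble do not share a single topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one conformer, in PDB v3 naming conventions."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    element: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} {self.name!r}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.name:
            raise ValueError("atom name must be non-empty")


class Topology:
    """Per-atom identity shared by every model of a trajectory.

    Stored as parallel numpy arrays so selections and metrics vectorize.
    """

    __slots__ = ("serials", "names", "residue_names", "chain_ids",
                 "residue_seqs", "elements", "is_hetero")

    def __init__(self, serials, names, residue_names, chain_ids,
                 residue_seqs, elements, is_hetero):
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype="U6")
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.chain_ids = np.asarray(chain_ids, dtype="U2")
        self.residue_seqs = np.asarray(residue_seqs, dtype=int)
        self.elements = np.asarray(elements, dtype="U2")
        self.is_hetero = np.asarray(is_hetero, dtype=bool)
        n = len(self.names)
        for attr in self.__slots__:
            if len(getattr(self, attr)) != n:
                raise ValueError("topology annotation arrays must have equal length")
        if len(np.unique(self.serials)) != n:
            raise ValueError("atom serials must be unique within a model")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return all(np.array_equal(getattr(self, a), getattr(other, a))
                   for a in self.__slots__)

    @classmethod
    def from_records(cls, records: list[AtomRecord]) -> "Topology":
        return cls(
            [r.serial for r in records],
            [r.name for r in records],
            [r.residue_name for r in records],
            [r.chain_id for r in records],
            [r.residue_seq for r in records],
            [r.element for r in records],
            [r.is_hetero for r in records],
        )


@dataclass
class StructureModel:
    """A single conformer: one topology plus one coordinate set (Å)."""

    topology: Topology
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.topology
        return [
            AtomRecord(int(t.serials[i]), str(t.names[i]), str(t.residue_names[i]),
                       str(t.chain_ids[i]), int(t.residue_seqs[i]), self.coords[i],
                       str(t.elements[i]), bool(t.is_hetero[i]))
            for i in range(len(t))
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped to ``R x + t``."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(self.topology, new, self.model_id)

    def copy(self) -> "StructureModel":
        return StructureModel(self.topology, self.coords.copy(), self.model_id)


@dataclass
class Trajectory:
    """An ordered ensemble of topology-identical conformers."""

    topology: Topology
    coords: np.ndarray                      # (n_frames, n_atoms, 3), Å
    frame_interval: float | None = None     # time per frame in ps, if known

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1 \
                or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError("trajectory coords must have shape (n_frames>=1, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __getitem__(self, frame: int) -> StructureModel:
        if not -len(self) <= frame < len(self):
            raise IndexError(f"frame {frame} out of range for {len(self)} frames")
        return StructureModel(self.topology, self.coords[frame], model_id=frame % len(self) + 1)

    def __iter__(self):
        for f in range(len(self)):
            yield self[f]

    @property
    def models(self) -> list[StructureModel]:
        return [self[f] for f in range(len(self))]

    @classmethod
    def from_models(cls, models: list[StructureModel],
                    frame_interval: float | None = None) -> "Trajectory":
        if not models:
            raise ValueError("a trajectory requires at least one model")
        top = models[0].topology
        for m in models[1:]:
            if m.topology != top:
                raise TopologyMismatchError(
                    f"model {m.model_id} differs in topology from model {models[0].model_id}")
        coords = np.stack([m.coords for m in models])
        return cls(top, coords, frame_interval)

    def strided(self, stride: int) -> "Trajectory":
        """Every ``stride``-th frame, keeping metadata; stride in frames."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        interval = None if self.frame_interval is None else self.frame_interval * stride
        return Trajectory(self.topology, self.coords[::stride].copy(), interval)

    def ps_to_frame(self, time_ps: float) -> int:
        """Convert a time in ps to a frame index using ``frame_interval``."""
        if self.frame_interval is None:
            raise ValueError("frame_interval is unset; cannot convert ps to frames")
        return int(round(time_ps / self.frame_interval))


def _scan_model_atom_counts(path: str) -> list[int]:
    """Atom-record counts per MODEL block (single implicit model allowed)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:        # MODEL without ENDMDL terminator
        counts.append(current)
    return counts


def read_multimodel_pdb(path: str | os.PathLike) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    ATOM and HETATM records are both retained.  Alternate locations keep the
    first altloc only.  Raises :class:`FileNotFoundError` for a missing file,
    :class:`TopologyMismatchError` when MODEL blocks disagree in atom count and
    :class:`PDBParseError` for malformed records.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such PDB file: {path}")

    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        raise TopologyMismatchError(
            f"{path}: MODEL blocks have differing atom counts {sorted(set(counts))}")
    if not counts or counts[0] == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    try:
        pdbfile = _pdb.PDBFile.read(path)
        stack = pdbfile.get_structure(model=None, altloc="first",
                                      extra_fields=["atom_id"])
    except StructureIOError:
        raise
    except Exception as exc:  # biotite raises library-specific errors
        raise PDBParseError(f"{path}: could not parse PDB records ({exc})") from exc

    coords = np.asarray(stack.coord, dtype=float)
    n_models, n_atoms = coords.shape[0], coords.shape[1]
    elements = stack.element if "element" in stack.get_annotation_categories() else [""] * n_atoms
    topology = Topology(
        serials=stack.atom_id,
        names=stack.atom_name,
        residue_names=stack.res_name,
        chain_ids=stack.chain_id,
        residue_seqs=stack.res_id,
        elements=elements,
        is_hetero=stack.hetero,
    )
    logger.debug("read %s: %d models, %d atoms", path, n_models, n_atoms)
    return Trajectory(topology, coords)


def write_multimodel_pdb(traj: Trajectory | StructureModel,
                         path: str | os.PathLike,
                         remarks: list[str] | None = None) -> None:
    """Write an ensemble as a standard multi-model PDB (fixed-width v3).

    One MODEL/ENDMDL block per frame; hetero records serialized as HETATM;
    coordinates at 3-decimal fixed width.  Optional REMARK lines (e.g. the
    provenance stamp of a pipeline run) are prepended to the header.
    """
    if isinstance(traj, StructureModel):
        traj = Trajectory(traj.topology, traj.coords[None, :, :])
    top = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = top.chain_ids.astype("U4")
    stack.res_id = top.residue_seqs.copy()
    stack.res_name = top.residue_names.astype("U5")
    stack.atom_name = top.names.astype("U6")
    stack.element = top.elements.astype("U2")
    stack.hetero = top.is_hetero.copy()
    stack.set_annotation("atom_id", top.serials.copy())
    stack.set_annotation("ins_code", np.array([""] * traj.n_atoms, dtype="U1"))

    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(stack)
    if traj.n_frames == 1 and not any(l.startswith("MODEL") for l in pdbfile.lines):
        # one MODEL/ENDMDL block per frame, also for single-conformer files
        first_atom = next(i for i, l in enumerate(pdbfile.lines)
                          if l.startswith(("ATOM", "HETATM")))
        last_atom = max(i for i, l in enumerate(pdbfile.lines)
                        if l.startswith(("ATOM", "HETATM", "TER")))
        pdbfile.lines = (pdbfile.lines[:first_atom] + ["MODEL        1"]
                         + pdbfile.lines[first_atom:last_atom + 1] + ["ENDMDL"]
                         + pdbfile.lines[last_atom + 1:])
    if remarks:
        header = [f"REMARK   3 {text}"[:80] for text in remarks]
        pdbfile.lines = header + pdbfile.lines
    if pdbfile.lines and pdbfile.lines[-1].strip() != "END":
        pdbfile.lines.append("END")
    pdbfile.write(os.fspath(path))
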