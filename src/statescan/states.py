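"""Two-distance active/inactive state diagnostic for GTPase switch regions.

The diagnostic distances are d1, from the switch-II glycine Cα (G60 in
K-Ras numbering) to the nucleotide Pβ atom, and d2, from the switch-I
threonine Cα (T35) to Pβ.  Conformers with d1 in [5.8, 8.0) Å keep both
switch regions coupled to the γ-phosphate (the active state); conformers
with d1 in [8.0, 10.0) Å have lost only the G60–γ-phosphate coupling
(inactive substate 3).  Intervals are half-open so the shared 8.0 Å bound
assigns unambiguously, and all bounds are configurable so the classifier
works for any two-distance scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DistanceSeries, pair_distance_series
from .io import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "StateDefinition",
    "DistanceHistogram",
    "StateAssignment",
    "compute_d1_d2",
    "histogram_density",
    "assign_states",
    "occupancy_report",
    "ACTIVE", "INACTIVE3", "UNASSIGNED",
]

ACTIVE = "active"
INACTIVE3 = "inactive_substate3"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class StateDefinition:
    """Atom pairs and half-open d1/d2 intervals defining the state scheme.

    ``d2_interval`` is an optional extra gate on the active state (used in
    GAP-bound context, where d2 confines to 6.0–8.0 Å); it is off by
    default because state calls hinge on d1.
    """

    d1_atom_a: str = "resseq 60 and name CA and protein"
    d1_atom_b: str = "name PB and hetero"
    d2_atom_a: str = "resseq 35 and name CA and protein"
    d2_atom_b: str = "name PB and hetero"
    active_d1: tuple[float, float] = (5.8, 8.0)
    inactive3_d1: tuple[float, float] = (8.0, 10.0)
    d2_interval: tuple[float, float] | None = None   # e.g. (6.0, 8.0) when gating

    def __post_init__(self) -> None:
        for lo, hi in (self.active_d1, self.inactive3_d1):
            if not lo < hi:
                raise ValueError("interval bounds must satisfy lower < upper")
        a, b = sorted([self.active_d1, self.inactive3_d1])
        if a[1] > b[0]:
            raise ValueError("active and inactive d1 intervals must not overlap")
        if self.d2_interval is not None and not self.d2_interval[0] < self.d2_interval[1]:
            raise ValueError("d2 interval bounds must satisfy lower < upper")


@dataclass
class DistanceHistogram:
    """Normalized probability density over distance bins (1/Å)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density must have one entry per bin")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left_A": self.bin_edges[:-1],
                             "bin_right_A": self.bin_edges[1:],
                             "density_per_A": self.density})


@dataclass
class StateAssignment:
    """Per-frame d1/d2 values and state labels, with occupancy estimates."""

    d1: np.ndarray
    d2: np.ndarray
    labels: np.ndarray               # strings in {active, inactive_substate3, unassigned}
    definition: StateDefinition

    def __len__(self) -> int:
        return len(self.labels)

    def occupancies(self) -> dict[str, float]:
        n = len(self.labels)
        return {lab: float(np.sum(self.labels == lab)) / n
                for lab in (ACTIVE, INACTIVE3, UNASSIGNED)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self)), "d1_A": self.d1,
                             "d2_A": self.d2, "label": self.labels})


def compute_d1_d2(traj: Trajectory, sdef: StateDefinition | None = None,
                  ) -> tuple[DistanceSeries, DistanceSeries]:
    """The two diagnostic distance series for every frame of a trajectory."""
    sdef = sdef or StateDefinition()
    d1 = pair_distance_series(traj, sdef.d1_atom_a, sdef.d1_atom_b, label="d1")
    d2 = pair_distance_series(traj, sdef.d2_atom_a, sdef.d2_atom_b, label="d2")
    return d1, d2


def histogram_density(series: DistanceSeries | np.ndarray,
                      bin_width: float = 0.1,
                      range_: tuple[float, float] = (4.0, 14.0)) -> DistanceHistogram:
    """Probability density of a distance sample on a fixed grid.

    Values outside ``range_`` are excluded from the density and counted in a
    logged overflow tally, so the in-range density always integrates to 1.
    """
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = range_
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    in_range = (values >= edges[0]) & (values < edges[-1])
    n_overflow = int(values.size - in_range.sum())
    if n_overflow:
        logger.warning("histogram: %d of %d values outside [%g, %g) excluded",
                       n_overflow, values.size, edges[0], edges[-1])
    if in_range.sum() == 0:
        raise ValueError("all values fall outside the histogram range")
    counts, _ = np.histogram(values[in_range], bins=edges)
    density = counts / (in_range.sum() * bin_width)
    return DistanceHistogram(edges, density, n_overflow)


def _in(values: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (values >= lo) & (values < hi)


def assign_states(d1: DistanceSeries | np.ndarray,
                  d2: DistanceSeries | np.ndarray,
                  sdef: StateDefinition | None = None) -> StateAssignment:
    """Label every frame from its (d1, d2) pair; half-open interval convention.

    A frame is *active* when d1 falls in ``active_d1`` (and d2 in
    ``d2_interval`` when that gate is enabled), *inactive_substate3* when d1
    falls in ``inactive3_d1``, otherwise *unassigned*.  Unassigned frames are
    retained in the occupancy accounting, never dropped.
    """
    sdef = sdef or StateDefinition()
    v1 = d1.values if isinstance(d1, DistanceSeries) else np.asarray(d1, float)
    v2 = d2.values if isinstance(d2, DistanceSeries) else np.asarray(d2, float)
    if len(v1) != len(v2):
        raise ValueError(f"d1 ({len(v1)}) and d2 ({len(v2)}) series differ in length")

    labels = np.full(len(v1), UNASSIGNED, dtype=object)
    active = _in(v1, sdef.active_d1)
    if sdef.d2_interval is not None:
        active &= _in(v2, sdef.d2_interval)
    labels[active] = ACTIVE
    labels[~active & _in(v1, sdef.inactive3_d1)] = INACTIVE3
    return StateAssignment(v1, v2, labels, sdef)


def occupancy_report(assign: StateAssignment) -> pd.DataFrame:
    """Per-label occupancy with counts and binomial standard errors."""
    if len(assign) == 0:
        raise ValueError("empty state assignment")
    n = len(assign)
    rows = []
    for label in (ACTIVE, INACTIVE3, UNASSIGNED):
        count = int(np.sum(assign.labels == label))
        p = count / n
        rows.append({"label": label, "count": count, "fraction": p,
                     "binomial_se": float(np.sqrt(p * (1.0 - p) / n))})
    return pd.DataFrame(rows)
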