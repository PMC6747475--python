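"""Core in-memory model for confined-water trajectory analysis.

Everything downstream operates on two light containers — :class:`AtomTable`
(static topology: names, elements, residues, bonds, van der Waals radii) and
:class:`Trajectory` (time-ordered coordinates with box information) — plus a
handful of small result records.  Units are Å for lengths and ps for times
throughout; readers are responsible for converting whatever the source format
uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Residue names recognised as water across common force fields.
WATER_RESNAMES = frozenset({"SOL", "HOH", "WAT", "TIP3"})

#: Bondi (1964) van der Waals radii, Å.  Used by the pore-radius estimator;
#: overridable per run.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
}

DEFAULT_VDW = 1.70


@dataclass
class AtomTable:
    """Static per-atom topology.

    Parameters
    ----------
    names : array of str
        Atom names (e.g. ``CA``, ``OD1``, ``OW``).
    elements : array of str
        Element symbols, upper-case.
    resnames : array of str
        Three-letter residue codes.
    resnums : array of int
        Residue sequence numbers.
    chains : array of str
        Chain / subunit identifiers (may be empty strings).
    bonds : (n_bonds, 2) int array
        Pairs of atom indices.  May be empty; hydrogens are then attached
        to heavy atoms by distance when needed.
    vdw_radii : (n_atoms,) float array
        Per-atom van der Waals radii in Å.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    chains: np.ndarray
    bonds: np.ndarray
    vdw_radii: np.ndarray
    domains: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resnames", "resnums", "chains", "vdw_radii"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch with names ({n})")
        self.bonds = np.asarray(self.bonds, dtype=np.intp).reshape(-1, 2)
        if np.any(np.asarray(self.vdw_radii, float) <= 0):
            raise ValueError("vdW radii must be positive")
        if self.domains is None:
            self.domains = np.full(n, "other", dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_water(self) -> np.ndarray:
        """Boolean mask of atoms belonging to water molecules."""
        return np.isin(self.resnames, sorted(WATER_RESNAMES))

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.elements == "H"

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygen atoms (one per molecule, the reference
        point for every water-position computation)."""
        return np.flatnonzero(self.is_water & (self.elements == "O"))

    def protein_heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_water & ~self.is_hydrogen)

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> bonded hydrogen indices (from the bond
        list)."""
        out: dict[int, list[int]] = {}
        heavy = ~self.is_hydrogen
        for a, b in self.bonds:
            if self.is_hydrogen[a] and heavy[b]:
                out.setdefault(int(b), []).append(int(a))
            elif self.is_hydrogen[b] and heavy[a]:
                out.setdefault(int(a), []).append(int(b))
        return out


@dataclass
class Trajectory:
    """Time-ordered coordinates, Å and ps.

    ``coords`` has shape (n_frames, n_atoms, 3); ``box`` holds per-frame
    orthorhombic box edge lengths (n_frames, 3) or ``None`` for a
    non-periodic system.  Frame times must be uniformly spaced.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times / coords frame count mismatch")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], atol=1e-6):
                raise ValueError("frame times must be uniformly spaced")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing, ps."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class GroupSpec:
    """A protein heavy atom with its attached hydrogens.

    The central atom defines the group's position (r = 0 of its radial
    distribution; the centre of its 3.5 Å hydration shell).  Polarity is
    element based: N/O polar (charged groups included), C/S nonpolar.
    """

    group_id: str
    central_atom: int
    hydrogens: tuple[int, ...]
    polarity: str
    domain: str
    chain: str = ""


@dataclass
class DomainConfig:
    """Named residue ranges and the residues whose Cα atoms define the
    pore-axis origin.

    Defaults are the TRPV1 analysis domains: extracellular loops 604–625,
    selectivity filter 642–646, pore 670–680, vestibule 681–692 and TRP
    helix 693–711; the axis origin is the centre of mass of Cα atoms of
    residues 642–645, 671, 675, 676, 679, 680, 683, 686 and 687.
    """

    domains: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {
            "loops": [(604, 625)],
            "filter": [(642, 646)],
            "pore": [(670, 680)],
            "vestibule": [(681, 692)],
            "TRP": [(693, 711)],
        }
    )
    pore_axis_residues: list[int] = field(
        default_factory=lambda: [642, 643, 644, 645, 671, 675, 676, 679, 680, 683, 686, 687]
    )

    def __post_init__(self) -> None:
        for name, ranges in self.domains.items():
            spans = sorted((int(a), int(b)) for a, b in ranges)
            for (a1, b1), (a2, _) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping ranges in domain {name!r}")
            self.domains[name] = spans

    def domain_of(self, resnum: int) -> str:
        for name, ranges in self.domains.items():
            for a, b in ranges:
                if a <= resnum <= b:
                    return name
        return "other"


@dataclass
class PoreAxis:
    """Pore coordinate system: per-frame origin on the laboratory z axis.

    ``origin`` has shape (n_frames, 3); the axis direction is the +z unit
    vector (the membrane normal).  The analysis cylinder has the given
    radius and axial extent relative to the origin.
    """

    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    cylinder_radius: float = 15.0
    z_range: tuple[float, float] = (-50.0, 50.0)

    def __post_init__(self) -> None:
        self.origin = np.atleast_2d(np.asarray(self.origin, float))
        self.direction = np.asarray(self.direction, float)
        if not np.isclose(np.linalg.norm(self.direction), 1.0):
            raise ValueError("axis direction must be a unit vector")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def axial_radial(self, positions: np.ndarray, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate z and radial distance of positions for a frame."""
        rel = positions - self.origin[min(frame, len(self.origin) - 1)]
        z = rel @ self.direction
        radial = np.linalg.norm(rel - np.outer(z, self.direction), axis=-1)
        return z, radial


@dataclass
class AxialProfile:
    """A per-z-bin statistic (pore radius, linear density or D)."""

    z_edges: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    n_frames: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.z_edges = np.asarray(self.z_edges, float)
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.z_edges) - 1:
            raise ValueError("values must have one entry per z bin")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
            if np.any(self.sd[np.isfinite(self.sd)] < 0):
                raise ValueError("sd must be non-negative")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dz(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    def to_frame(self):
        import pandas as pd

        data = {"z_center_A": self.z_centers, "value": self.values}
        if self.sd is not None:
            data["sd"] = self.sd
        data["n_frames"] = self.n_frames
        return pd.DataFrame(data)


@dataclass
class SurvivalCurve:
    """Survival time correlation function N_α(t) of a hydration shell.

    ``values[0]`` is the coordination number N_α(0), the mean instantaneous
    shell occupancy.
    """

    lags: np.ndarray
    values: np.ndarray
    group_id: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if len(self.lags) != len(self.values):
            raise ValueError("lags / values length mismatch")
        if np.any(self.values < -1e-12):
            raise ValueError("survival values must be non-negative")

    @property
    def N0(self) -> float:
        """Coordination number: mean shell occupancy."""
        return float(self.values[0])


@dataclass
class BiExpFit:
    """Double-exponential fit n(t) = n_f e^{-t/τ_f} + n_s e^{-t/τ_s} with
    τ_f ≤ τ_s, and the derived residence time."""

    n_f: float
    tau_f: float
    n_s: float
    tau_s: float
    fit_window: tuple[float, float]
    tau_res: float
    converged: bool
    group_id: str = ""
    N0: float = float("nan")


@dataclass
class DomainStats:
    """Residence-time distribution summary for one (domain, polarity) cell."""

    domain: str
    polarity: str
    tau_res_samples: np.ndarray
    median: float
    iqr: tuple[float, float]

    def __post_init__(self) -> None:
        self.tau_res_samples = np.asarray(self.tau_res_samples, float)
        lo, hi = self.iqr
        if not (lo - 1e-12 <= self.median <= hi + 1e-12):
            raise ValueError("median must lie within the interquartile range")


@dataclass(frozen=True)
class HBondRecord:
    """One water–protein hydrogen bond in one frame."""

    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    water_molecule: int
    distance_DA: float
    angle_DHA: float
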