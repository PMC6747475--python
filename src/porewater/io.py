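"""Reading topology/trajectory files and classifying protein groups.

File handling is delegated to MDAnalysis (PDB/GRO topologies; XTC/TRR/DCD
coordinates); this module converts into the package's in-memory model with
Å/ps units, classifies every protein heavy atom into a polar or nonpolar
group, and assigns residues to named analysis domains.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .model import (
    AtomTable,
    DEFAULT_VDW,
    DomainConfig,
    GroupSpec,
    Trajectory,
    VDW_RADII,
    WATER_RESNAMES,
)

log = logging.getLogger(__name__)

_POLAR_ELEMENTS = frozenset({"N", "O"})
_NONPOLAR_ELEMENTS = frozenset({"C", "S"})


class FormatError(RuntimeError):
    """A file could not be read under its declared format."""


class ConsistencyError(RuntimeError):
    """Topology and trajectory disagree (e.g. atom counts)."""


class ClassificationError(RuntimeError):
    """An atom could not be assigned a polarity class."""


def guess_element(name: str) -> str:
    """Element symbol from an atom name (PDB-style heuristics).

    Leading digits are skipped (``1HB`` is hydrogen); two-letter symbols are
    only produced for common ions/halogens to avoid mistaking ``CA`` (alpha
    carbon) for calcium in a protein context.
    """
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ClassificationError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if upper[:2] in {"CL", "BR", "NA", "MG", "ZN"} and len(upper) == 2:
        return upper[:2]
    return upper[0]


def atoms_from_universe(u, vdw_table: dict[str, float] | None = None) -> AtomTable:
    """Build an :class:`AtomTable` from an ``MDAnalysis.Universe``."""
    table = dict(VDW_RADII)
    if vdw_table:
        table.update({k.upper(): float(v) for k, v in vdw_table.items()})
    names = u.atoms.names.astype(object)
    if hasattr(u.atoms, "elements") and all(e for e in u.atoms.elements):
        elements = np.array([e.upper() for e in u.atoms.elements], dtype=object)
    else:
        elements = np.array([guess_element(n) for n in names], dtype=object)
    try:
        bonds = u.atoms.bonds.to_indices()
    except Exception:
        bonds = np.empty((0, 2), dtype=np.intp)
    try:
        chains = u.atoms.segids.astype(object)
    except Exception:
        chains = np.full(len(names), "", dtype=object)
    vdw = np.array([table.get(e, DEFAULT_VDW) for e in elements], dtype=float)
    return AtomTable(
        names=names,
        elements=elements,
        resnames=u.atoms.resnames.astype(object),
        resnums=u.atoms.resnums.astype(int),
        chains=chains,
        bonds=np.asarray(bonds, dtype=np.intp),
        vdw_radii=vdw,
    )


def load_system(
    topology_path: str,
    trajectory_path: str | None = None,
    vdw_table: dict[str, float] | None = None,
) -> tuple[AtomTable, Trajectory]:
    """Read a topology (PDB/GRO) and optional trajectory (XTC/TRR/DCD).

    Coordinates are returned in Å and times in ps regardless of the source
    dialect (MDAnalysis performs the nm→Å conversion for GROMACS formats).
    Water molecules are identified by residue name
    (``SOL``/``HOH``/``WAT``/``TIP3``).
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(topology_path)
            else:
                u = mda.Universe(topology_path, trajectory_path)
    except (OSError, ValueError, IndexError, KeyError) as exc:
        raise FormatError(f"could not read {topology_path!r}/{trajectory_path!r}: {exc}") from exc

    atoms = atoms_from_universe(u, vdw_table)
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, atoms.n_atoms, 3), dtype=np.float32)
    times = np.empty(n_frames)
    boxes = np.empty((n_frames, 3))
    periodic = True
    for i, ts in enumerate(u.trajectory):
        if ts.n_atoms != atoms.n_atoms:
            raise ConsistencyError(
                f"trajectory frame has {ts.n_atoms} atoms, topology has {atoms.n_atoms}"
            )
        coords[i] = ts.positions
        times[i] = ts.time
        if ts.dimensions is None or np.all(ts.dimensions[:3] == 0):
            periodic = False
        else:
            boxes[i] = ts.dimensions[:3]
    if n_frames > 1 and np.allclose(np.diff(times), 0):
        # Some writers drop time metadata; fall back to unit spacing.
        times = np.arange(n_frames, dtype=float)
    traj = Trajectory(times=times, coords=coords, box=boxes if periodic else None)
    return atoms, traj


def _hydrogen_attachment(atoms: AtomTable, coords0: np.ndarray | None) -> dict[int, list[int]]:
    """Heavy atom -> hydrogens, from bonds or (fallback) nearest heavy atom
    within 1.3 Å in the first frame."""
    attached = atoms.bonded_hydrogens()
    claimed = {h for hs in attached.values() for h in hs}
    free_h = [i for i in np.flatnonzero(atoms.is_hydrogen) if i not in claimed]
    if free_h and coords0 is not None:
        from scipy.spatial import cKDTree

        heavy = np.flatnonzero(~atoms.is_hydrogen)
        tree = cKDTree(coords0[heavy])
        dist, idx = tree.query(coords0[free_h], k=1)
        for h, d, j in zip(free_h, dist, idx):
            if d <= 1.3:
                attached.setdefault(int(heavy[j]), []).append(int(h))
    return attached


def classify_groups(
    atoms: AtomTable,
    coords0: np.ndarray | None = None,
    domain_config: DomainConfig | None = None,
) -> list[GroupSpec]:
    """One :class:`GroupSpec` per protein heavy atom.

    Polarity is element based — N/O polar (charged groups included), C/S
    nonpolar — and hydrogens belong to the heavy atom they are bonded to.
    ``coords0`` (first-frame coordinates) enables distance-based hydrogen
    attachment when the topology carries no bonds.
    """
    attached = _hydrogen_attachment(atoms, coords0)
    cfg = domain_config or DomainConfig()
    groups: list[GroupSpec] = []
    for i in atoms.protein_heavy_indices():
        el = atoms.elements[i]
        if el in _POLAR_ELEMENTS:
            polarity = "polar"
        elif el in _NONPOLAR_ELEMENTS:
            polarity = "nonpolar"
        else:
            raise ClassificationError(
                f"atom {i} ({atoms.resnames[i]}{atoms.resnums[i]}:{atoms.names[i]}) "
                f"has unclassifiable element {el!r}"
            )
        domain = atoms.domains[i] if atoms.domains[i] != "other" else cfg.domain_of(int(atoms.resnums[i]))
        groups.append(
            GroupSpec(
                group_id=f"{atoms.resnames[i]}{atoms.resnums[i]}:{atoms.names[i]}",
                central_atom=int(i),
                hydrogens=tuple(sorted(attached.get(int(i), []))),
                polarity=polarity,
                domain=domain,
                chain=str(atoms.chains[i]),
            )
        )
    return groups


def assign_domains(atoms: AtomTable, config: DomainConfig) -> AtomTable:
    """Label every atom with its analysis domain ("other" outside all
    configured ranges).  Returns the same table, modified in place."""
    atoms.domains = np.array([config.domain_of(int(r)) for r in atoms.resnums], dtype=object)
    return atoms


def write_profile_csv(profile, path) -> None:
    """Write an axial profile as CSV with unit-bearing headers."""
    profile.to_frame().to_csv(path, index=False)
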