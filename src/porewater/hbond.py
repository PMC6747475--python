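"""Water–protein hydrogen bond detection by geometric criteria.

A bond is recorded when the donor–acceptor heavy-atom distance is at most
3.5 Å and the D–H–A angle lies within 30° of linear (i.e. ≥ 150°).  Both
directions are scanned: water as donor to protein N/O acceptors, and
protein N/O–H donors to the water oxygen.  Distances honour the minimum
image convention for periodic systems.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomTable, HBondRecord

log = logging.getLogger(__name__)


def _min_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def _dha_angle(d_pos, h_pos, a_pos, box) -> np.ndarray:
    """D–H–A angle in degrees (180° = linear)."""
    v1 = _min_image(d_pos - h_pos, box)
    v2 = _min_image(a_pos - h_pos, box)
    cosang = np.einsum("...i,...i", v1, v2) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _donor_table(atoms: AtomTable, coords0: np.ndarray | None):
    """(donor heavy atom, hydrogen) pairs for every N/O with bonded H."""
    from .io import _hydrogen_attachment

    attached = _hydrogen_attachment(atoms, coords0)
    pairs = []
    for heavy, hs in attached.items():
        if atoms.elements[heavy] in ("N", "O"):
            for h in hs:
                pairs.append((heavy, h))
    return pairs


def detect_hbonds(
    frame_coords: np.ndarray,
    atoms: AtomTable,
    frame: int = 0,
    box: np.ndarray | None = None,
    dist_cut: float = 3.5,
    angle_tol: float = 30.0,
    donor_pairs: list[tuple[int, int]] | None = None,
) -> list[HBondRecord]:
    """All water↔protein hydrogen bonds in one frame.

    ``donor_pairs`` (precomputed by :func:`donor_acceptor_tables`) avoids
    re-deriving hydrogen attachment per frame.  Nominal donors without a
    hydrogen are skipped with a logged warning at table-build time.
    """
    if donor_pairs is None:
        donor_pairs, _ = donor_acceptor_tables(atoms, frame_coords)
    water = atoms.is_water
    no_elem = np.isin(atoms.elements, ("N", "O"))
    acceptors = np.flatnonzero(no_elem)
    water_mol = _water_molecule_ids(atoms)

    records: list[HBondRecord] = []
    if not donor_pairs or not len(acceptors):
        return records
    donors = np.array([d for d, _ in donor_pairs])
    hydrogens = np.array([h for _, h in donor_pairs])

    acc_pos = frame_coords[acceptors]
    don_pos = frame_coords[donors]
    if box is not None:
        acc_pos = np.mod(acc_pos, box)
        don_pos = np.mod(don_pos, box)
    acc_tree = cKDTree(acc_pos, boxsize=box if box is not None else None)
    near = acc_tree.query_ball_point(don_pos, r=dist_cut)
    for k, acc_list in enumerate(near):
        d, h = int(donors[k]), int(hydrogens[k])
        for j in acc_list:
            a = int(acceptors[j])
            if a == d:
                continue
            if water[d] == water[a]:
                continue  # water↔protein pairing only
            if water[d] and water[a] and water_mol[d] == water_mol[a]:
                continue
            dvec = _min_image(frame_coords[a] - frame_coords[d], box)
            dist = float(np.linalg.norm(dvec))
            if dist > dist_cut:
                continue
            ang = float(_dha_angle(frame_coords[d], frame_coords[h], frame_coords[a], box))
            if ang < 180.0 - angle_tol:
                continue
            records.append(
                HBondRecord(
                    frame=frame,
                    donor=d,
                    hydrogen=h,
                    acceptor=a,
                    water_molecule=int(water_mol[d] if water[d] else water_mol[a]),
                    distance_DA=dist,
                    angle_DHA=ang,
                )
            )
    return records


def donor_acceptor_tables(atoms: AtomTable, coords0: np.ndarray | None = None):
    """Precompute (donor, hydrogen) pairs and N/O acceptor indices."""
    pairs = _donor_table(atoms, coords0)
    acceptors = np.flatnonzero(np.isin(atoms.elements, ("N", "O")))
    return pairs, acceptors


def _water_molecule_ids(atoms: AtomTable) -> np.ndarray:
    """Per-atom water molecule id (residue number for waters, -1 otherwise)."""
    ids = np.full(atoms.n_atoms, -1, dtype=int)
    w = atoms.is_water
    ids[w] = atoms.resnums[w]
    return ids


def detect_hbonds_trajectory(
    atoms: AtomTable,
    traj,
    dist_cut: float = 3.5,
    angle_tol: float = 30.0,
) -> list[list[HBondRecord]]:
    """Per-frame H-bond records for a whole trajectory."""
    donor_pairs, _ = donor_acceptor_tables(atoms, traj.coords[0])
    out = []
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        out.append(
            detect_hbonds(
                traj.coords[f].astype(float), atoms, frame=f, box=box,
                dist_cut=dist_cut, angle_tol=angle_tol, donor_pairs=donor_pairs,
            )
        )
    return out


def bound_water_ids(records: list[HBondRecord]) -> set[int]:
    """Distinct water molecules with at least one bond in a record set."""
    return {r.water_molecule for r in records}


def records_to_frame(records: list[HBondRecord]):
    """Flatten records into a DataFrame for CSV streaming."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "frame": r.frame,
                "donor": r.donor,
                "hydrogen": r.hydrogen,
                "acceptor": r.acceptor,
                "water_molecule": r.water_molecule,
                "distance_DA_A": r.distance_DA,
                "angle_DHA_deg": r.angle_DHA,
            }
            for r in records
        ]
    )
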