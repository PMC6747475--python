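"""Shared fixtures: small hand-built systems with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from porewater.model import AtomTable, DomainConfig, Trajectory


def build_atoms(rows, bonds=()):
    """AtomTable from (name, element, resname, resnum, chain) tuples."""
    names, elements, resnames, resnums, chains = zip(*rows)
    from porewater.model import VDW_RADII, DEFAULT_VDW

    return AtomTable(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resnums=np.array(resnums, dtype=int),
        chains=np.array(chains, dtype=object),
        bonds=np.array(bonds, dtype=np.intp).reshape(-1, 2),
        vdw_radii=np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]),
    )


def single_frame(coords, box=None):
    coords = np.asarray(coords, dtype=np.float32)[None]
    b = None if box is None else np.asarray([box], dtype=float)
    return Trajectory(times=np.array([0.0]), coords=coords, box=b)


@pytest.fixture
def asn_water_system():
    """An ASN676 side-chain fragment plus two waters, bonds included.

    Water 1 donates a near-linear H-bond to OD1 at 2.8 Å; water 2 sits
    4.5 Å away (outside the distance criterion).
    """
    rows = [
        ("CG", "C", "ASN", 676, "A"),
        ("OD1", "O", "ASN", 676, "A"),
        ("ND2", "N", "ASN", 676, "A"),
        ("HD21", "H", "ASN", 676, "A"),
        ("HD22", "H", "ASN", 676, "A"),
        ("OW", "O", "SOL", 2001, "W"),
        ("HW1", "H", "SOL", 2001, "W"),
        ("HW2", "H", "SOL", 2001, "W"),
        ("OW", "O", "SOL", 2002, "W"),
        ("HW1", "H", "SOL", 2002, "W"),
        ("HW2", "H", "SOL", 2002, "W"),
    ]
    bonds = [(0, 1), (0, 2), (2, 3), (2, 4), (5, 6), (5, 7), (8, 9), (8, 10)]
    atoms = build_atoms(rows, bonds)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],     # CG
            [1.2, 0.0, 0.0],     # OD1
            [-0.7, 1.1, 0.0],    # ND2
            [-1.7, 1.1, 0.0],    # HD21
            [-0.3, 2.0, 0.0],    # HD22
            [4.0, 0.0, 0.0],     # OW (2.8 from OD1)
            [3.05, 0.0, 0.0],    # HW1 pointing at OD1
            [4.4, 0.93, 0.0],    # HW2
            [5.7, 0.0, 0.0],     # OW2 (4.5 from OD1)
            [5.2, 0.8, 0.0],
            [6.3, -0.7, 0.0],
        ]
    )
    return atoms, coords


@pytest.fixture
def domain_config():
    return DomainConfig()
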