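"""Pore coordinate system and radius profile from solvent-accessible volume.

The pore axis is the laboratory z direction (the membrane normal); its
per-frame origin is the unweighted centre of the Cα atoms of the configured
axis residues.  The radius profile R(z) is the radius of the cylinder with
the same solvent-accessible volume per axial slab: points inside the
analysis cylinder count as accessible when a probe sphere (1.4 Å) centred
there clears every protein atom's van der Waals surface, and
R(z) = sqrt(⟨V(z)⟩ / (π·dz)).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomTable, AxialProfile, DomainConfig, PoreAxis, Trajectory


class ConfigurationError(RuntimeError):
    pass


def compute_pore_axis(
    atoms: AtomTable,
    traj: Trajectory,
    config: DomainConfig | None = None,
    cylinder_radius: float = 15.0,
    z_range: tuple[float, float] = (-50.0, 50.0),
    ca_name: str = "CA",
) -> PoreAxis:
    """Per-frame pore origin from the centre of the configured Cα atoms.

    Falls back to the centre of all non-water atoms when the system has no
    atoms named ``CA`` among the configured residues (synthetic walls).
    """
    config = config or DomainConfig()
    sel = np.flatnonzero(
        (atoms.names == ca_name) & np.isin(atoms.resnums, config.pore_axis_residues)
    )
    if len(sel) == 0:
        sel = np.flatnonzero(~atoms.is_water)
        if len(sel) == 0:
            raise ConfigurationError(
                f"no {ca_name} atoms among axis residues {config.pore_axis_residues} "
                "and no protein atoms to fall back on"
            )
    origin = traj.coords[:, sel, :].mean(axis=1)
    return PoreAxis(origin=origin, cylinder_radius=cylinder_radius, z_range=z_range)


def _slab_grid(axis: PoreAxis, z_edges: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample points covering every slab of the analysis cylinder.

    Returns (points relative to origin, slab index per point).  One xy grid
    layer per slab when dz ≤ pitch, otherwise multiple layers per slab.
    """
    R = axis.cylinder_radius
    xs = np.arange(-R + pitch / 2, R, pitch)
    X, Y = np.meshgrid(xs, xs)
    inside = X**2 + Y**2 <= R**2
    xy = np.column_stack([X[inside], Y[inside]])

    dz = z_edges[1] - z_edges[0]
    n_layers = max(1, int(np.floor(dz / pitch)))
    offsets = (np.arange(n_layers) + 0.5) * (dz / n_layers)
    pts, slab_idx = [], []
    for k in range(len(z_edges) - 1):
        for off in offsets:
            z = z_edges[k] + off
            pts.append(np.column_stack([xy, np.full(len(xy), z)]))
            slab_idx.append(np.full(len(xy), k, dtype=np.intp))
    return np.concatenate(pts), np.concatenate(slab_idx)


def pore_radius_profile(
    atoms: AtomTable,
    traj: Trajectory,
    axis: PoreAxis,
    dz: float = 0.25,
    probe_radius: float = 1.4,
    grid_pitch: float = 0.5,
    frame_stride: int = 1,
    occluder_mask: np.ndarray | None = None,
) -> AxialProfile:
    """Pore radius R(z) from per-slab solvent-accessible volume.

    Only protein (non-water) atoms occlude.  The accessible volume of each
    axial slab is estimated on a uniform grid of the given pitch inside the
    analysis cylinder; a point is accessible when its distance to every
    occluding atom i exceeds ``vdw_radius_i + probe_radius``.  R(z) is the
    frame-averaged V(z) converted to an equivalent cylinder radius.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    z_lo, z_hi = axis.z_range
    n_bins = int(round((z_hi - z_lo) / dz))
    z_edges = z_lo + np.arange(n_bins + 1) * dz
    pts_rel, slab_idx = _slab_grid(axis, z_edges, grid_pitch)
    n_pts_per_slab = np.bincount(slab_idx, minlength=n_bins)
    slab_volume = np.pi * axis.cylinder_radius**2 * dz
    point_volume = slab_volume / n_pts_per_slab.max()

    if occluder_mask is None:
        occluder_mask = ~atoms.is_water
    occ_idx = np.flatnonzero(occluder_mask)
    radii = atoms.vdw_radii[occ_idx] + probe_radius
    max_r = radii.max() if len(radii) else 0.0

    frames = range(0, traj.n_frames, frame_stride)
    acc_counts = np.zeros(n_bins)
    n_used = 0
    for f in frames:
        pts = pts_rel + axis.origin[min(f, len(axis.origin) - 1)]
        accessible = np.ones(len(pts), dtype=bool)
        if len(occ_idx):
            tree = cKDTree(pts)
            atom_pos = traj.coords[f, occ_idx].astype(float)
            # Group atoms by (binned) radius so each query uses one ball size.
            order = np.argsort(radii)
            groups = np.split(order, np.flatnonzero(np.diff(radii[order]) > 1e-9) + 1)
            for g in groups:
                hit = tree.query_ball_point(atom_pos[g], r=radii[g[0]], workers=-1)
                for lst in hit:
                    accessible[lst] = False
        acc_counts += np.bincount(slab_idx[accessible], minlength=n_bins)
        n_used += 1
    mean_volume = acc_counts / n_used * point_volume
    R = np.sqrt(mean_volume / (np.pi * dz))
    return AxialProfile(z_edges=z_edges, values=R, n_frames=n_used, label="R")


def accessible_volume(
    atoms: AtomTable,
    coords: np.ndarray,
    axis: PoreAxis,
    frame: int = 0,
    probe_radius: float = 1.4,
    grid_pitch: float = 0.5,
) -> float:
    """Total solvent-accessible volume of the whole analysis cylinder in one
    frame (single-pass estimate used as an additivity cross-check)."""
    z_lo, z_hi = axis.z_range
    prof = pore_radius_profile(
        atoms,
        Trajectory(times=np.array([0.0]), coords=coords[None] if coords.ndim == 2 else coords),
        axis,
        dz=(z_hi - z_lo),
        probe_radius=probe_radius,
        grid_pitch=grid_pitch,
    )
    return float(prof.values[0] ** 2 * np.pi * (z_hi - z_lo))
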