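"""Axial water profiles: linear density ρ_ln(z) and the translational
dynamics coefficient D(z).

Both are computed for water oxygens inside the analysis cylinder, binned by
axial coordinate relative to the per-frame pore origin.  D(z) is the local
mean squared displacement over a short lag (1 ps by default) divided by six
times the lag; in bulk it equals the water model's self-diffusion
coefficient, while inside the pore it maps the local heterogeneity of water
mobility.  Slab membership is decided at the lag interval's start frame.
"""

from __future__ import annotations

import numpy as np

from .model import AtomTable, AxialProfile, PoreAxis, Trajectory


def _z_edges(axis: PoreAxis, dz: float) -> np.ndarray:
    z_lo, z_hi = axis.z_range
    n = int(round((z_hi - z_lo) / dz))
    return z_lo + np.arange(n + 1) * dz


def slab_assignment(
    traj: Trajectory,
    axis: PoreAxis,
    dz: float,
    oxygen_indices: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame slab index of each water oxygen.

    Returns (slab, inside): integer slab indices (n_frames, n_waters) and a
    boolean mask of molecules inside the analysis cylinder and z range.
    Molecules outside are unassigned (mask False).
    """
    edges = _z_edges(axis, dz)
    n_bins = len(edges) - 1
    n_frames = traj.n_frames
    slab = np.full((n_frames, len(oxygen_indices)), -1, dtype=np.int32)
    inside = np.zeros((n_frames, len(oxygen_indices)), dtype=bool)
    for f in range(n_frames):
        z, radial = axis.axial_radial(traj.coords[f, oxygen_indices].astype(float), f)
        ok = (radial <= axis.cylinder_radius) & (z >= edges[0]) & (z < edges[-1])
        idx = np.clip(((z - edges[0]) / dz).astype(np.int32), 0, n_bins - 1)
        slab[f, ok] = idx[ok]
        inside[f] = ok
    return slab, inside


def linear_density(
    atoms: AtomTable,
    traj: Trajectory,
    axis: PoreAxis,
    dz: float = 0.25,
    subset: str = "all",
    bound_ids_per_frame: list[set[int]] | None = None,
) -> AxialProfile:
    """Water linear density ρ_ln(z), molecules per Å of pore axis.

    ``subset="bound"`` restricts the count to waters hydrogen-bonded to the
    protein in each frame (``bound_ids_per_frame`` holds the per-frame sets
    of bound water residue numbers from the H-bond stage).
    """
    if subset not in ("all", "bound"):
        raise ValueError("subset must be 'all' or 'bound'")
    ow = atoms.water_oxygen_indices()
    resnums = atoms.resnums[ow]
    edges = _z_edges(axis, dz)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    slab, inside = slab_assignment(traj, axis, dz, ow)
    for f in range(traj.n_frames):
        sel = inside[f]
        if subset == "bound":
            if bound_ids_per_frame is None:
                raise ValueError("subset='bound' requires bound_ids_per_frame")
            bound = bound_ids_per_frame[f]
            sel = sel & np.isin(resnums, sorted(bound))
        counts += np.bincount(slab[f, sel], minlength=n_bins)
    rho = counts / traj.n_frames / dz
    return AxialProfile(z_edges=edges, values=rho, n_frames=traj.n_frames, label=f"rho_ln_{subset}")


def translational_dynamics(
    atoms: AtomTable,
    traj: Trajectory,
    axis: PoreAxis,
    dz: float = 0.25,
    lag: float = 1.0,
) -> AxialProfile:
    """Translational dynamics coefficient D(z), Å²/ps.

    For every frame t, molecules located in slab [z, z+dz) at t contribute
    their squared displacement over the lag; the per-frame molecule mean is
    then averaged over frames and divided by 6·lag.  Displacements use the
    minimum image convention (safe for lags whose displacements are well
    under half the box).  Slabs never occupied are reported as NaN.
    """
    dt = traj.dt
    lag_frames = lag / dt if dt > 0 else 0
    if abs(lag_frames - round(lag_frames)) > 1e-9 or round(lag_frames) < 1:
        raise ValueError(f"lag {lag} ps is not a positive multiple of the frame spacing {dt} ps")
    lf = int(round(lag_frames))
    if lf >= traj.n_frames:
        raise ValueError("lag exceeds the trajectory length")

    ow = atoms.water_oxygen_indices()
    edges = _z_edges(axis, dz)
    n_bins = len(edges) - 1
    slab, inside = slab_assignment(traj, axis, dz, ow)

    sum_means = np.zeros(n_bins)
    n_contrib = np.zeros(n_bins, dtype=np.int64)
    for f in range(traj.n_frames - lf):
        disp = traj.coords[f + lf, ow].astype(float) - traj.coords[f, ow].astype(float)
        if traj.box is not None:
            disp -= traj.box[f] * np.round(disp / traj.box[f])
        sq = np.einsum("ij,ij->i", disp, disp)
        sel = inside[f]
        if not np.any(sel):
            continue
        s = slab[f, sel]
        sums = np.bincount(s, weights=sq[sel], minlength=n_bins)
        cnts = np.bincount(s, minlength=n_bins)
        occ = cnts > 0
        sum_means[occ] += sums[occ] / cnts[occ]
        n_contrib[occ] += 1
    with np.errstate(invalid="ignore"):
        D = np.where(n_contrib > 0, sum_means / np.maximum(n_contrib, 1) / (6.0 * lag), np.nan)
    return AxialProfile(z_edges=edges, values=D, n_frames=traj.n_frames, label="D")


def bulk_dynamics_coefficient(
    traj_oxygen_coords: np.ndarray,
    dt: float,
    lag: float = 1.0,
    box: np.ndarray | None = None,
) -> float:
    """The same 1 ps estimator pooled over all molecules of a homogeneous
    box: MSD(lag)/(6·lag), averaging per-frame molecule means over frames.

    ``traj_oxygen_coords`` has shape (n_frames, n_molecules, 3); pass
    unwrapped coordinates, or wrapped ones with ``box`` for minimum-image
    displacements.
    """
    lf = int(round(lag / dt))
    if lf < 1 or abs(lf * dt - lag) > 1e-9:
        raise ValueError("lag must be a positive multiple of dt")
    disp = traj_oxygen_coords[lf:] - traj_oxygen_coords[:-lf]
    if box is not None:
        disp = disp - box * np.round(disp / box)
    msd = np.einsum("fij,fij->fi", disp, disp).mean(axis=1).mean()
    return float(msd / (6.0 * lag))


def aggregate_profiles(profiles: list[AxialProfile]) -> AxialProfile:
    """Per-bin mean and population standard deviation across replicate
    trajectories (identical z grids required)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    edges = profiles[0].z_edges
    for p in profiles[1:]:
        if len(p.z_edges) != len(edges) or not np.allclose(p.z_edges, edges):
            raise ValueError("profiles have mismatching z grids")
    stack = np.vstack([p.values for p in profiles])
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    return AxialProfile(
        z_edges=edges,
        values=mean,
        sd=sd,
        n_frames=sum(p.n_frames for p in profiles),
        label=profiles[0].label,
    )
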