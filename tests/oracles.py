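"""Independent brute-force oracles used by the tests.

These deliberately re-derive each quantity by direct enumeration or
Monte-Carlo sampling, sharing no code path with the package's optimized
implementations.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# hydrogen bonds: O(N^2) all-pairs scan
# ---------------------------------------------------------------------------

def _min_image(v, box):
    if box is None:
        return v
    return v - box * np.round(v / box)


def brute_force_hbonds(coords, atoms, box=None, dist_cut=3.5, angle_tol=30.0):
    """Set of (donor, hydrogen, acceptor) water<->protein H-bond triples."""
    is_water = atoms.is_water
    is_h = atoms.is_hydrogen
    # hydrogen -> bonded heavy atom, straight from the bond list
    h_parent = {}
    for a, b in atoms.bonds:
        if is_h[a] and not is_h[b]:
            h_parent[int(a)] = int(b)
        elif is_h[b] and not is_h[a]:
            h_parent[int(b)] = int(a)
    donors = [(d, h) for h, d in h_parent.items() if atoms.elements[d] in ("N", "O")]
    acceptors = [int(i) for i in range(atoms.n_atoms) if atoms.elements[i] in ("N", "O") and not is_h[i]]

    found = set()
    for d, h in donors:
        for a in acceptors:
            if a == d or is_water[d] == is_water[a]:
                continue
            dv = _min_image(coords[a] - coords[d], box)
            dist = np.sqrt((dv**2).sum())
            if dist > dist_cut:
                continue
            v1 = _min_image(coords[d] - coords[h], box)
            v2 = _min_image(coords[a] - coords[h], box)
            cosang = (v1 @ v2) / np.sqrt((v1**2).sum() * (v2**2).sum())
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= 180.0 - angle_tol:
                found.add((d, h, a))
    return found


# ---------------------------------------------------------------------------
# survival function: direct interval enumeration
# ---------------------------------------------------------------------------

def _interval_survives(col, t_prime, lag, n0, mode):
    n_frames = len(col)
    if not col[t_prime]:
        return False
    n_exc = 0
    f = t_prime
    end = t_prime + lag
    while f <= end:
        if col[f]:
            f += 1
            continue
        # full extent of this excursion in the complete series
        e = f
        while e < n_frames and not col[e]:
            e += 1
        if e >= n_frames:
            return False  # never returns to the shell
        s = f
        while s > 0 and not col[s - 1]:
            s -= 1
        if e - s > n0:
            return False
        n_exc += 1
        f = e
    if mode == "single" and n_exc > 1:
        return False
    return True


def survival_enumeration(occ, dt, t0=2.0, mode="multi", max_lag_frames=None):
    """N(t) by scanning every (origin, water, lag) triple explicitly."""
    occ = np.asarray(occ, bool)
    n_frames, n_w = occ.shape
    n0 = int(np.floor(t0 / dt + 1e-9))
    top = n_frames - 1 if max_lag_frames is None else max_lag_frames
    values = np.empty(top + 1)
    for lag in range(top + 1):
        total = 0
        n_origins = n_frames - lag
        for t_prime in range(n_origins):
            for j in range(n_w):
                if _interval_survives(occ[:, j], t_prime, lag, n0, mode):
                    total += 1
        values[lag] = total / n_origins
    return values


# ---------------------------------------------------------------------------
# accessible volume: uniform Monte-Carlo sampling in a cylinder slab
# ---------------------------------------------------------------------------

def mc_slab_volume(atom_pos, atom_radii, probe, axis_xy, cyl_radius, z_lo, z_hi, n_samples, rng):
    """Solvent-accessible volume of one axial slab of the cylinder."""
    r = cyl_radius * np.sqrt(rng.uniform(size=n_samples))
    phi = rng.uniform(0, 2 * np.pi, n_samples)
    pts = np.column_stack(
        [axis_xy[0] + r * np.cos(phi), axis_xy[1] + r * np.sin(phi), rng.uniform(z_lo, z_hi, n_samples)]
    )
    ok = np.ones(n_samples, dtype=bool)
    for pos, rad in zip(atom_pos, atom_radii):
        d2 = ((pts - pos) ** 2).sum(axis=1)
        ok &= d2 > (rad + probe) ** 2
    slab_vol = np.pi * cyl_radius**2 * (z_hi - z_lo)
    return ok.mean() * slab_vol, ok.std(ddof=1) / np.sqrt(n_samples) * slab_vol


# ---------------------------------------------------------------------------
# residence time: numerical quadrature of the fitted bi-exponential
# ---------------------------------------------------------------------------

def tau_res_quadrature(n_f, tau_f, n_s, tau_s):
    """First moment of n(t) by adaptive quadrature on a generous interval."""
    from scipy.integrate import quad

    n = lambda t: n_f * np.exp(-t / tau_f) + n_s * np.exp(-t / tau_s)
    upper = 200 * max(tau_f, tau_s)
    num, _ = quad(lambda t: t * n(t), 0, upper, limit=400)
    den, _ = quad(n, 0, upper, limit=400)
    return num / den
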