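"""Hydration-shell residence-time analysis.

The survival time correlation function N_α(t) counts, averaged over time
origins t′, the waters that stay in group α's hydration shell (water oxygen
within 3.5 Å of the group's central atom) over the whole interval
[t′, t′+t], tolerating excursions out of the shell provided each one lasts
no longer than t₀ (2 ps by default).  N_α(0) is the coordination number —
the mean instantaneous shell occupancy.  The curve is fitted by a double
exponential n(t) = n_f·e^(−t/τ_f) + n_s·e^(−t/τ_s), and the residence time
is its normalised first moment, which has the closed form

    τ_res = (n_f·τ_f² + n_s·τ_s²) / (n_f·τ_f + n_s·τ_s).

Normalisation divides each lag by its number of valid time origins, so a
permanently resident water contributes exactly 1 at every lag.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import least_squares

from .model import AtomTable, BiExpFit, DomainStats, GroupSpec, SurvivalCurve, Trajectory

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shell occupancy and survival function
# ---------------------------------------------------------------------------

def shell_occupancy(
    atoms: AtomTable,
    traj: Trajectory,
    group: GroupSpec,
    shell_radius: float = 3.5,
) -> np.ndarray:
    """Boolean (n_frames, n_waters) matrix: water oxygen within
    ``shell_radius`` of the group's central atom (minimum image)."""
    ow = atoms.water_oxygen_indices()
    vec = traj.coords[:, ow].astype(np.float64) - traj.coords[:, group.central_atom, None].astype(np.float64)
    if traj.box is not None:
        box = traj.box[:, None, :]
        vec -= box * np.round(vec / box)
    return np.einsum("fij,fij->fi", vec, vec) <= shell_radius**2


def _excursion_runs(col: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False in a boolean series as (start, stop) with
    ``stop`` exclusive."""
    padded = np.concatenate([[True], col, [True]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == -1)
    stops = np.flatnonzero(d == 1)
    return list(zip(starts, stops))


def survival_from_occupancy(
    occ: np.ndarray,
    dt: float,
    t0: float = 2.0,
    max_lag: float | None = None,
    mode: str = "multi",
) -> SurvivalCurve:
    """Survival function from a boolean occupancy matrix.

    ``mode="multi"`` (default) tolerates any number of excursions, each of
    duration ≤ t₀; ``mode="single"`` additionally allows at most one
    excursion per interval (a stricter reading of "leaves … but returns").
    An excursion truncated by the end of the trajectory never returns and
    terminates survival regardless of its observed length.
    """
    if mode not in ("multi", "single"):
        raise ValueError("mode must be 'multi' or 'single'")
    occ = np.asarray(occ, bool)
    n_frames, n_w = occ.shape
    n0 = int(np.floor(t0 / dt + 1e-9)) if dt > 0 else 0
    max_lag_frames = n_frames - 1
    if max_lag is not None:
        want = int(round(max_lag / dt))
        if want > max_lag_frames:
            warnings.warn(
                f"max_lag {max_lag} ps exceeds trajectory extent; truncating", stacklevel=2
            )
        max_lag_frames = min(want, max_lag_frames)

    hist = np.zeros(n_frames + 1, dtype=np.int64)
    INF = n_frames + 10
    for j in range(n_w):
        col = occ[:, j]
        if not col.any():
            continue
        runs = _excursion_runs(col)
        bad = np.zeros(n_frames, dtype=bool)
        for s, e in runs:
            if (e - s) > n0 or e >= n_frames:
                bad[s:e] = True
        # first bad frame at or after each position (suffix minimum)
        marker = np.where(bad, np.arange(n_frames), INF)
        next_bad = np.concatenate([np.minimum.accumulate(marker[::-1])[::-1], [INF]])
        if mode == "single":
            # start frame of the second excursion at or after each position
            starts = np.array([s for s, e in runs if not bad[s]], dtype=np.int64)
            nxt = np.full(n_frames + 1, INF, dtype=np.int64)
            nxt2 = np.full(n_frames + 1, INF, dtype=np.int64)
            si = len(starts) - 1
            for f in range(n_frames - 1, -1, -1):
                if si >= 0 and starts[si] == f:
                    nxt2[f] = nxt[f + 1]
                    nxt[f] = f
                    si -= 1
                else:
                    nxt[f] = nxt[f + 1]
                    nxt2[f] = nxt2[f + 1]
        origins = np.flatnonzero(col)
        limit = next_bad[origins]
        if mode == "single":
            limit = np.minimum(limit, nxt2[origins])
        by_bad = np.where(limit < INF, limit - origins - 1, n_frames)
        maxlag = np.minimum(by_bad, n_frames - 1 - origins)
        hist += np.bincount(maxlag, minlength=n_frames + 1)

    counts = np.cumsum(hist[::-1])[::-1][: max_lag_frames + 1]
    denom = n_frames - np.arange(max_lag_frames + 1)
    values = counts / denom
    lags = np.arange(max_lag_frames + 1) * dt
    return SurvivalCurve(lags=lags, values=values)


def survival_correlation(
    atoms: AtomTable,
    traj: Trajectory,
    group: GroupSpec,
    shell_radius: float = 3.5,
    t0: float = 2.0,
    max_lag: float | None = None,
    mode: str = "multi",
) -> SurvivalCurve:
    """Survival time correlation function N_α(t) of one group's shell."""
    if t0 > 0 and traj.dt > 0:
        ratio = t0 / traj.dt
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(f"t0 {t0} ps is not a multiple of the frame spacing {traj.dt} ps")
    occ = shell_occupancy(atoms, traj, group, shell_radius)
    curve = survival_from_occupancy(occ, traj.dt, t0=t0, max_lag=max_lag, mode=mode)
    curve.group_id = group.group_id
    return curve


# ---------------------------------------------------------------------------
# bi-exponential fit and residence time
# ---------------------------------------------------------------------------

def _biexp(t, n_f, tau_f, n_s, tau_s):
    return n_f * np.exp(-t / tau_f) + n_s * np.exp(-t / tau_s)


def _biexp_jac(t, n_f, tau_f, n_s, tau_s):
    ef = np.exp(-t / tau_f)
    es = np.exp(-t / tau_s)
    return np.column_stack(
        [ef, n_f * ef * t / tau_f**2, es, n_s * es * t / tau_s**2]
    )


def fit_biexponential(
    curve: SurvivalCurve,
    window: tuple[float, float] = (0.25, 100.0),
    floor: float = 0.1,
    min_N0: float = 0.2,
) -> BiExpFit | None:
    """Nonlinear least-squares fit of the double exponential.

    The fit window runs from ``window[0]`` to ``window[1]`` ps but is
    truncated at the first lag where the curve drops below ``floor``
    (rapidly decaying shells carry no information past that point).  Groups
    with coordination number below ``min_N0`` are rejected (returns None) —
    effectively dehydrated shells are not fitted.  Non-convergent fits fall
    back to a single exponential with ``converged=False``.  Time constants
    are relabelled after fitting so that τ_f ≤ τ_s.
    """
    N0 = curve.N0
    if N0 < min_N0:
        log.info("group %s rejected: N0=%.3f < %.3f", curve.group_id, N0, min_N0)
        return None
    t_all, y_all = curve.lags, curve.values
    if t_all[-1] < window[0]:
        raise ValueError("survival curve shorter than the fit window start")
    below = np.flatnonzero(y_all < floor)
    stop_idx = below[0] if len(below) else len(t_all)
    sel = (t_all >= window[0]) & (t_all <= window[1]) & (np.arange(len(t_all)) < stop_idx)
    t, y = t_all[sel], y_all[sel]
    if len(t) < 4:
        # Too few points for 4 parameters: widen to everything ≥ window start.
        sel = t_all >= window[0]
        t, y = t_all[sel], y_all[sel]
    if len(t) < 2:
        raise ValueError("not enough points to fit")

    extent = max(t[-1], 1.0)
    # A decay constant far beyond the observed window is indistinguishable
    # from a constant; bounding it keeps the fit identifiable and τ_res
    # finite when the data are effectively single-exponential.
    tau_max = 10.0 * extent
    good_enough = 1e-10 * max(1.0, float(np.sum(y**2)))
    best = None
    for tf0 in (1.0, 5.0):
        for ts0 in (20.0, 100.0):
            x0 = np.array([N0 / 2, min(tf0, extent), N0 / 2, min(ts0, tau_max / 2)])
            try:
                res = least_squares(
                    lambda p: _biexp(t, *p) - y,
                    x0,
                    jac=lambda p: _biexp_jac(t, *p),
                    bounds=([0, 1e-4, 0, 1e-4], [np.inf, tau_max, np.inf, tau_max]),
                    method="trf",
                    max_nfev=600,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < good_enough:
                break
        if best is not None and best.cost < good_enough:
            break
    converged = best is not None and best.success and np.isfinite(best.cost)
    if best is None:
        converged = False
        n_f = float(y[0]) if len(y) else N0
        tau = max(float(t[-1]) / 3.0, 1e-3)
        params = np.array([n_f, tau, 0.0, tau])
    else:
        params = best.x
        # Significance screen: an amplitude below the residual noise level is
        # not distinguishable from zero, yet τ_res weights it by τ² — collapse
        # such fits to a single exponential.
        sigma = np.sqrt(2.0 * best.cost / max(len(t) - 4, 1))
        if min(params[0], params[2]) < 2.0 * sigma:
            single = _fit_single_exponential(t, y, N0, tau_max)
            if single is not None:
                params = single
    n_f, tau_f, n_s, tau_s = map(float, params)
    # drop numerically absent components so τ_res reflects the visible decay
    total = n_f + n_s
    if total > 0 and n_s < 1e-6 * total:
        n_s, tau_s = 0.0, tau_f
    if total > 0 and n_f < 1e-6 * total:
        n_f, tau_f = 0.0, tau_s
    if tau_f > tau_s:
        n_f, tau_f, n_s, tau_s = n_s, tau_s, n_f, tau_f
    fit = BiExpFit(
        n_f=n_f,
        tau_f=tau_f,
        n_s=n_s,
        tau_s=tau_s,
        fit_window=(float(t[0]), float(t[-1])),
        tau_res=float("nan"),
        converged=bool(converged),
        group_id=curve.group_id,
        N0=N0,
    )
    fit.tau_res = residence_time(fit)
    return fit


def _fit_single_exponential(t, y, N0, tau_max):
    """n·e^{-t/τ} fallback; returned in 4-parameter form with n_s = 0."""
    best = None
    for tau0 in (2.0, 10.0, 50.0):
        try:
            res = least_squares(
                lambda p: p[0] * np.exp(-t / p[1]) - y,
                np.array([max(N0, y[0]), min(tau0, tau_max / 2)]),
                bounds=([0, 1e-4], [np.inf, tau_max]),
                method="trf",
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    n, tau = best.x
    return np.array([n, tau, 0.0, tau])


def residence_time(fit: BiExpFit) -> float:
    """Residence time: the normalised first moment ⟨t⟩ of the fitted
    double exponential, in closed form."""
    denom = fit.n_f * fit.tau_f + fit.n_s * fit.tau_s
    if denom <= 0:
        raise ValueError("residence time undefined: both amplitudes vanish")
    return (fit.n_f * fit.tau_f**2 + fit.n_s * fit.tau_s**2) / denom


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def average_survival(curves: list[SurvivalCurve], group_id: str = "") -> SurvivalCurve:
    """Pointwise mean of survival curves over subunits / trajectories
    (common lag grid required; curves are truncated to the shortest)."""
    if not curves:
        raise ValueError("no curves to average")
    n = min(len(c.lags) for c in curves)
    lags = curves[0].lags[:n]
    for c in curves[1:]:
        if not np.allclose(c.lags[:n], lags):
            raise ValueError("curves have mismatching lag grids")
    values = np.mean([c.values[:n] for c in curves], axis=0)
    return SurvivalCurve(lags=lags, values=values, group_id=group_id or curves[0].group_id)


def domain_statistics(
    samples: list[tuple[str, str, float]],
    merge_pore_filter: bool = True,
) -> list[DomainStats]:
    """Distribution summaries of residence times per (domain, polarity).

    ``samples`` holds one (domain, polarity, τ_res) entry per accepted fit
    — one sample per group × subunit × trajectory.  The pore and filter
    domains are merged into a single ``pore+filter`` cell by default (they
    have few hydrated groups individually).  Empty cells are omitted with a
    warning.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for domain, polarity, tau in samples:
        if merge_pore_filter and domain in ("pore", "filter"):
            domain = "pore+filter"
        cells.setdefault((domain, polarity), []).append(float(tau))
    out = []
    for (domain, polarity), taus in sorted(cells.items()):
        if not taus:
            warnings.warn(f"empty cell {domain}/{polarity}", stacklevel=2)
            continue
        arr = np.asarray(taus)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out.append(
            DomainStats(
                domain=domain,
                polarity=polarity,
                tau_res_samples=arr,
                median=float(med),
                iqr=(float(q1), float(q3)),
            )
        )
    return out


def fits_to_frame(entries: list[tuple[GroupSpec, BiExpFit]]):
    """Per-group fit table (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group": g.group_id,
                "chain": g.chain,
                "domain": g.domain,
                "polarity": g.polarity,
                "N0": f.N0,
                "n_f": f.n_f,
                "tau_f_ps": f.tau_f,
                "n_s": f.n_s,
                "tau_s_ps": f.tau_s,
                "tau_res_ps": f.tau_res,
                "converged": f.converged,
            }
            for g, f in entries
        ]
    )
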