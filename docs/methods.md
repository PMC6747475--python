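# Methods

This note records the definitions, conventions and numerical choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate system and units

All internal coordinates are Å and times ps; readers convert from the
source dialect (GROMACS nm → Å via MDAnalysis). The pore axis is the
laboratory z direction — the membrane normal in the usual channel set-up —
and its origin is recomputed per frame as the unweighted centre of the Cα
atoms of the configured axis residues (for TRPV1: 642–645, 671, 675, 676,
679, 680, 683, 686, 687, i.e. the S6 helices and selectivity filter).
Unweighted rather than mass-weighted is immaterial here because all the
selected atoms are carbons. Per-frame origin recomputation absorbs the
protein's translational drift; no rotational alignment is applied (the
axis is always laboratory z), which is adequate for membrane-embedded
channels whose tilt fluctuations are small on the analysed timescales.
Water positions are always represented by the water oxygen.

## Protein groups and polarity

A *group* is one protein heavy atom plus its bonded hydrogens. Polarity
is element-based: N and O are polar (charged groups are included in the
polar class), C and S nonpolar; any other element raises an error rather
than being silently classified. Hydrogens attach through the topology's
bond list, with a 1.3 Å nearest-heavy-atom fallback when bonds are absent
(PDB topologies). Identical subunits yield distinct groups (chain-tagged);
averaging across subunits is an explicit post-processing step
(`average_survival`), never implicit.

## Pore radius

R(z) = √(⟨V(z)⟩/(π·dz)). V(z) is estimated by a uniform grid (default
pitch 0.5 Å, configurable; one grid layer per slab when dz ≤ pitch): a
point is accessible when its distance to every protein atom i exceeds
vdw_i + probe (probe 1.4 Å; Bondi element radii by default, overridable).
Only protein atoms occlude — water and lipids do not. A fully occluded
slab legitimately gives R = 0 (gates can close). The estimator's bias is
set by the grid pitch; halving the pitch quarters the area quantisation
error. Note that the analysis cylinder must be chosen inside the protein
wall: volume outside a hollow wall would otherwise count as accessible.

## Hydrogen bonds

Donor–acceptor (heavy-atom) distance ≤ 3.5 Å and D–H–A angle ≥ 150°
(i.e. 180° ± 30°). Any N/O with a bonded hydrogen may donate; any N/O may
accept; only water↔protein pairs are recorded, in both directions.
Minimum-image distances are used throughout; candidate pairs come from a
periodic KD-tree on acceptors, and the accelerated path is tested for
exact set equality against an all-pairs scan.

## Axial profiles

Slab membership (width dz, default 0.25 Å) is decided by the water
oxygen's axial coordinate relative to the per-frame origin, restricted to
the analysis cylinder (default radius 15 Å). ρ_ln(z) is the time-averaged
count per slab divided by dz. D(z) uses a 1 ps lag: molecules located in
a slab at frame t contribute |r(t+Δ)−r(t)|² (minimum image per lag step —
safe because 1 ps displacements are far below half a box length); the
per-frame molecule mean is averaged over frames, then divided by 6Δ.
Molecules are included if inside the cylinder at the interval's start,
wherever they end. Never-occupied slabs are NaN, not zero. Replicate
profiles aggregate as per-bin mean and population standard deviation.

## Survival function and residence time

For group α, the occupancy matrix marks waters within the 3.5 Å shell of
the central atom. N_α(t) averages, over time origins t′, the number of
waters continuously resident over [t′, t′+t] — where an excursion out of
the shell is tolerated if its *entire* duration is ≤ t₀ (default 2 ps;
8 frames at 0.25 ps, so a 2.00 ps excursion survives and a 2.25 ps one
does not). An excursion truncated by the end of the trajectory never
returns and terminates residency. By default any number of short
excursions is allowed; `mode="single"` restricts to at most one per
interval. Each lag is normalised by its number of valid time origins, so
a permanently resident water contributes exactly 1 at every lag and
N_α(0) equals the mean shell occupancy (the coordination number). One
consequence: the *survivor count* is rigorously non-increasing in lag,
but the normalised curve can tick up at sparsely-sampled tail lags where
few origins remain — curves should be truncated (`max_lag`) well inside
the trajectory length.

The curve is fitted by n(t) = n_f·e^(−t/τ_f) + n_s·e^(−t/τ_s) with
trust-region least squares (analytic Jacobian, non-negative amplitudes,
multi-start over τ initialisations), on the window 0.25–100 ps truncated
at the first lag where N_α < 0.1. Groups with N_α(0) < 0.2 are rejected
as effectively dehydrated. Two identifiability guards matter in practice:

* τ is bounded above by 10× the fitted window's extent — a slower decay
  is indistinguishable from a constant within the window;
* a component whose amplitude is below twice the fit's residual noise
  level is collapsed to a single exponential. Because
  τ_res = (n_f τ_f² + n_s τ_s²)/(n_f τ_f + n_s τ_s) weights components by
  n·τ², a statistically meaningless tail amplitude at a large τ would
  otherwise dominate the residence time.

After fitting, components are relabelled so τ_f ≤ τ_s. τ_res is the
closed-form first moment above (verified against adaptive quadrature to
1e-9 relative). Domain summaries emit one τ_res sample per
(group, subunit, trajectory) fit and report median and interquartile
range per (domain, polarity) cell; the pore and filter domains are merged
by default since each alone has few hydrated groups.

## Distributions

g(r) is the shell-volume-normalised histogram of water-oxygen distances
from the group's central atom, divided by a reference density (default:
mean water-oxygen density of the box; for confined systems pass the
analysis-region density explicitly — the choice scales g but not the
reported coordination number, which is the direct mean count within
3.5 Å). Pooling over groups concatenates histograms before normalising.
Density maps are per-voxel time-averaged counts (default 1 Å voxels);
H-bond density is placed at the bound water's oxygen so the water and
H-bond grids stay co-registered (donor–acceptor midpoint placement is
available). Grids export as OpenDX.

## Synthetic generators

All generators are seed-deterministic, store frames at 0.25 ps, and write
PDB + DCD + a JSON ground-truth sidecar.

* **Brownian bulk** — independent Gaussian walks (per-axis step variance
  2·D·dt) in a periodic box; the 1 ps MSD equals 6D·(1 ps) exactly in
  expectation.
* **Pore** — immobile wall pseudo-atoms (default vdW 1.5 Å, spacing
  0.8 Å) realising a known radius; solvent reflected at the wall surface;
  optional sticky polar sites hold one water each with exponential escape
  (rate k_exit) and optional brief-return excursions of configured
  duration, exercising the t₀ rule. Wall interactions are purely
  reflective — enough for excluded-volume structure, no energetics.
* **Shell telegraph** — waters toggle in/out of one group's shell as a
  two-state Markov process (rates k_exit, k_entry; stationary initial
  state). With the brief-return tolerance, an exit is rescued with
  probability p = 1 − e^(−k_entry·t₀), so the survival decays at the
  thinned rate k_exit·(1−p) — the analytic oracle used in tests.

What the generators do **not** emulate: water–water structure and
hydrogen-bond networks, rotational dynamics, electrostatics, lipids, and
protein flexibility. Passing recovery tests therefore demonstrates the
*estimators* are correct and unbiased at realistic sampling, not that the
physics of a real channel is reproduced; on real trajectories the inputs
are as good as the underlying simulation.

## Bulk-water validation engine

`watersim` is a compact NVT engine for rigid 3-site TIP3P water used to
check the dynamics estimator against a real water model: velocity-Verlet
with RATTLE constraints (O–H 0.9572 Å, H–O–H 104.52°), Lennard-Jones on
oxygen pairs, Coulomb with reaction-field correction (conducting
boundary) under a molecule-based cutoff of 0.9 nm keyed on the O–O
distance, and the Bussi stochastic velocity-rescaling thermostat
(τ_t = 0.1 ps, the common production setting; the group-based truncation
injects a slow heating that a weaker coupling does not fully remove, so
production runs sit ≈1–3 K above the set point). Default state: 216
molecules at 0.982 g/cm³ and 310 K, 2 fs steps, a gentle small-step start
from a randomly oriented lattice, 10 ps equilibration and 200 ps
production with unwrapped oxygen positions stored every 0.25 ps — sized
so the pooled 1 ps displacement statistics are converged to a few
percent. The 1 ps estimator on this run lands near the TIP3P
self-diffusion coefficient at 310 K (≈0.65 Å²/ps); expect a few-percent
high bias from the slight overheating and cutoff electrostatics, and
finite-size suppression of similar magnitude in the other direction.

## Default problem sizes

Tests validate at desk scale: 1000 walkers × 1 ns for diffusion recovery
(5% per-slab tolerance), 400 waters × 1 ns for residence recovery (10%),
50 frames × 200 waters for H-bond oracle equality (exact), 216 water
molecules × 200 ps for the TIP3P check (±15%, dominated by thermostat and
sampling noise). These sizes were chosen as the smallest at which the
quoted tolerances are comfortably above sampling error.

## Known limitations

* Straight, z-aligned pore axes only; no HOLE-style curved pathfinding.
* No rotational (dipole/OH) correlation functions or jump-model
  decomposition; translational observables only.
* Ion effects are out of scope; waters and protein only.
* The per-lag-normalised survival tail is noisy where origins are few;
  fit windows should stay well inside the trajectory length.
* `watersim` is deliberately minimal (no Ewald, no barostat, no
  neighbour lists); it is for validating estimators on bulk water, not
  for production simulation.
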