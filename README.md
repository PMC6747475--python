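# porewater

Analysis of confined water in ion-channel pores from molecular-dynamics
trajectories: axial density and mobility profiles, pore geometry from
solvent-accessible volume, water–protein hydrogen bonds, radial and spatial
water distributions, and hydration-shell residence times.

The package targets systems like the TRPV1 transmembrane pore — a
nanometre-scale, strongly amphiphilic water volume bounded by the
selectivity filter (the upper gate) and the S6 bundle crossing (the lower
gate) — where water behaves very differently from bulk: it localises near
polar side chains, slows down several-fold, and partially dewets
hydrophobic constrictions. It is written for structural biophysicists who
have topology + trajectory files (PDB/GRO + XTC/TRR/DCD) and want the
standard confined-water observables with tested, reproducible definitions.

## What it computes

With the pore axis **z** (the membrane normal, origin at the centre of
mass of configured Cα atoms) and an analysis cylinder around it:

* **Pore radius** — R(z) = √(⟨V(z)⟩ / (π·dz)), where ⟨V(z)⟩ is the
  trajectory-averaged solvent-accessible volume of the axial slab
  [z, z+dz): the set of points where a 1.4 Å probe-sphere centre fits
  without overlapping any protein atom's van der Waals sphere.
* **Linear density** — ρ_ln(z): time-averaged water molecules per Å of
  axis, for all waters and for waters hydrogen-bonded to the protein.
* **Translational dynamics coefficient** —
  D(z) = ⟨|r(t+Δ) − r(t)|²⟩ / (6Δ) with Δ = 1 ps, averaged over the
  molecules occupying each slab at t and then over frames. In bulk, D
  equals the water model's self-diffusion coefficient; inside the pore it
  maps local mobility.
* **Hydrogen bonds** — geometric criterion: donor–acceptor distance
  ≤ 3.5 Å and D–H–A angle within 180° ± 30°, both directions
  (water↔protein), minimum-image aware.
* **Distributions** — g(r) of water oxygens around any protein group's
  central atom (N/O for polar groups, C for nonpolar), and 3-D density
  grids (water, protein, H-bonded water) exported as OpenDX for viewers.
* **Residence times** — the survival correlation function N_α(t): the
  average number of waters that stay within 3.5 Å of group α over a lag t,
  tolerating excursions of at most t₀ = 2 ps each. N_α(0) is the
  coordination number. N_α(t) is fitted by
  n(t) = n_f·e^(−t/τ_f) + n_s·e^(−t/τ_s), and the residence time is the
  normalised first moment

      τ_res = (n_f·τ_f² + n_s·τ_s²) / (n_f·τ_f + n_s·τ_s),

  with per-domain polar/nonpolar distribution summaries (median, IQR).

A synthetic-trajectory module generates systems with exact ground truth —
free Brownian diffusion, cylindrical pores with sticky polar sites, and
two-state shell-occupancy (telegraph) processes — so every stage is
validated against known answers. A compact rigid-TIP3P NVT simulator
(`porewater.watersim`) provides a real-water check of the dynamics
estimator.

## Worked example

Recover a known residence time from a synthetic shell-kinetics trajectory
(waters enter and leave one group's hydration shell with exponential
dwells, mean 1/k_exit = 20 ps):

```python
from porewater import (GeneratorConfig, gen_shell_telegraph, classify_groups,
                       survival_correlation, fit_biexponential)

cfg = GeneratorConfig(seed=7, dt=0.25, n_frames=4000, n_waters=200,
                      k_exit=0.05, k_entry=0.01)
occ, atoms, traj = gen_shell_telegraph(cfg)
(group,) = classify_groups(atoms, traj.coords[0].astype(float))
curve = survival_correlation(atoms, traj, group, shell_radius=3.5, t0=2.0,
                             max_lag=150.0)
fit = fit_biexponential(curve)
print(f"group {group.group_id}: N0 = {curve.N0:.2f}")
print(f"residence time tau_res = {fit.tau_res:.1f} ps")
```

Output:

```
group ASN676:OD1: N0 = 34.17
residence time tau_res = 20.5 ps
```

`N0` is the mean shell occupancy (here ≈200 waters × the stationary
in-shell probability), and the fitted τ_res recovers the generator's 20 ps
mean dwell within a few percent.

The command line drives the same machinery on files:

```bash
porewater synth --scenario pore --seed 1 --out mypore     # PDB+DCD+truth
porewater all --topology mypore.pdb --trajectory mypore.dcd --out results/
```

producing `profiles.csv` (z, R, ρ_ln, D), `hbonds.csv`,
`residence_fits.csv`, `residence_domains.json`, OpenDX density grids and a
`manifest.json` with the configuration hash.

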