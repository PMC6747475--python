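"""Run configuration: analysis defaults and config-file loading.

Every cutoff has a single authoritative default here: axial bin width
0.25 Å, hydration-shell radius 3.5 Å, brief-return tolerance t₀ = 2 ps,
probe radius 1.4 Å, H-bond criteria 3.5 Å / 180°±30°, bi-exponential fit
window 0.25–100 ps with floor 0.1 and minimum coordination number 0.2,
analysis cylinder ø30 × 100 Å for axial profiles and ø30 × 50 Å for
density maps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import DomainConfig


@dataclass
class RunConfig:
    topology: str = ""
    trajectory: str = ""
    output_dir: str = "porewater_out"
    # geometry
    dz_A: float = 0.25
    cylinder_radius_A: float = 15.0
    z_min_A: float = -50.0
    z_max_A: float = 50.0
    probe_radius_A: float = 1.4
    grid_pitch_A: float = 0.5
    # dynamics
    lag_ps: float = 1.0
    # H-bonds
    hb_dist_A: float = 3.5
    hb_angle_tol_deg: float = 30.0
    # residence
    shell_radius_A: float = 3.5
    t0_ps: float = 2.0
    fit_window_ps: tuple[float, float] = (0.25, 100.0)
    fit_floor: float = 0.1
    min_N0: float = 0.2
    # density maps (ø30 × 50 Å cylinder-covering box)
    density_spacing_A: float = 1.0
    density_radius_A: float = 15.0
    density_half_length_A: float = 25.0
    # RDF
    rdf_r_max_A: float = 8.0
    rdf_dr_A: float = 0.1
    domains: DomainConfig = field(default_factory=DomainConfig)
    vdw_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in (
            "dz_A", "cylinder_radius_A", "grid_pitch_A", "shell_radius_A",
            "hb_dist_A", "density_spacing_A", "rdf_dr_A", "lag_ps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.probe_radius_A < 0 or self.t0_ps < 0:
            raise ValueError("probe_radius_A and t0_ps must be non-negative")
        if self.z_min_A >= self.z_max_A:
            raise ValueError("z range is empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["domains"] = {
            "domains": {k: [list(r) for r in v] for k, v in self.domains.domains.items()},
            "pore_axis_residues": list(self.domains.pore_axis_residues),
        }
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML config file; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    raw = dict(raw or {})
    dom = raw.pop("domains", None)
    cfg_kwargs = {}
    valid = {f for f in RunConfig.__dataclass_fields__}
    for k, v in raw.items():
        if k not in valid:
            raise ValueError(f"unknown config key {k!r}")
        cfg_kwargs[k] = tuple(v) if k == "fit_window_ps" else v
    cfg = RunConfig(**cfg_kwargs)
    if dom:
        cfg.domains = DomainConfig(
            domains={k: [tuple(r) for r in v] for k, v in dom.get("domains", {}).items()},
            pore_axis_residues=list(dom.get("pore_axis_residues", DomainConfig().pore_axis_residues)),
        )
    cfg.validate()
    return cfg
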