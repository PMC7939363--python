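"""Configuration objects and YAML round-trip.

All tunable constants of the simulator, the random-mechanism generator, and
the screening protocols live here, with defaults chosen so that a flat sheet
is quiescent and a desk-scale simulation (sheet_rings=3, a few hundred nodes)
finishes in well under a second.  Length unit: the resting epithelial cell
spacing is 1 (p_EQD = 0.5).  Time unit: set by unit mobility (velocity =
force); stiffnesses are chosen so mechanical relaxation times are O(1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SimConfig:
    """Integration, noise, caps, and stop conditions for one simulation."""

    seed: int = 0
    sheet_rings: int = 3
    n_genes: int = 10
    gradient_gene: int = 0
    #: the gradient gene is a clamped maternal input: not regulated, not
    #: degraded; its pattern persists and anchors downstream territories.
    clamp_gradient_gene: bool = True

    # integrator (4th-order Runge-Kutta with step-doubling error control)
    dt_init: float = 0.1
    dt_min: float = 1e-4
    dt_max: float = 0.12
    rk_tolerance: float = 2e-2
    #: run the step-doubling error estimate every this many steps (the
    #: dynamics change slowly relative to the step, so the step size is
    #: re-assessed periodically rather than every step)
    adapt_every: int = 4
    max_steps: int = 300
    max_nodes: int = 5000

    # noise: per-step isotropic Gaussian displacement of every node
    noise_amplitude: float = 0.01

    # mechanics
    #: node speed cap (length/time): keeps the overdamped dynamics
    #: well-posed when nodes crowd into dense folds
    max_speed: float = 2.0
    k_repulsion: float = 10.0
    k_adhesion: float = 2.0
    k_spring: float = 5.0
    k_bending: float = 0.5     # scales p_ERP orthogonality restoring force
    k_torsion: float = 0.15    # scales p_EST neighbor-axis alignment force
    activation: str = "saturating"  # or "rectifier"

    # behaviors
    min_radius: float = 0.1        # apoptosis removal threshold on p_EQD
    division_offset: float = 0.2   # daughter in-plane displacement
    p_eqd_max: float = 1.2
    p_add_max: float = 1.5

    # stop conditions
    steady_window: int = 12
    steady_pos_tol: float = 0.05   # max noise-free node speed (length/time)
    steady_expr_tol: float = 0.005  # max expression rate (conc./time)
    aberrance_check_every: int = 10
    rupture_multiple: float = 5.0
    antialign_threshold: float = -0.5
    #: aberrant when more than this fraction of contacting cell pairs have
    #: anti-aligned axes (tight folds legitimately produce a few)
    antialign_max_fraction: float = 0.5

    record_every: int = 0  # 0: record only initial and final snapshots

    def validate(self) -> None:
        if self.max_nodes <= 0 or self.max_steps <= 0:
            raise ValueError("caps must be positive")
        if self.sheet_rings < 1:
            raise ValueError("sheet_rings must be >= 1")
        if self.dt_min <= 0 or self.dt_max < self.dt_min:
            raise ValueError("invalid dt bounds")
        if self.rk_tolerance <= 0:
            raise ValueError("rk_tolerance must be positive")
        if self.activation not in ("saturating", "rectifier"):
            raise ValueError("activation must be saturating|rectifier")
        if not 0 <= self.gradient_gene < self.n_genes:
            raise ValueError("gradient_gene out of range")


@dataclass
class EnsembleConfig:
    """Random-mechanism sampling and the two-stage ensemble protocol."""

    n_genes: int = 10
    p_interact: float = 0.2     # per ordered gene pair (self-pairs included)
    p_couple: float = 0.5       # per gene: chance of one behavior coupling
    t_max: float = 1.0          # regulatory strengths uniform on (0, t_max)
    p_diffusible: float = 0.5
    diffusion_range: tuple[float, float] = (0.2, 2.0)
    degradation_range: tuple[float, float] = (0.1, 1.0)
    # coupling strengths: log-uniform for rates, uniform (signed) for
    # mechanical properties
    rate_coupling_range: tuple[float, float] = (1e-3, 1e-1)
    property_coupling_range: tuple[float, float] = (-0.02, 0.02)
    default_division_rate: float = 0.002
    #: a signaling-only run passes when it reaches a steady state whose
    #: expression pattern differs from the initial one beyond this threshold
    pattern_change_threshold: float = 0.05
    signaling_max_steps: int = 400
    #: broad-ensemble variant: behaviors attached before any screen
    broad: bool = False
    max_attempts_factor: int = 80

    def validate(self) -> None:
        for p in (self.p_interact, self.p_couple, self.p_diffusible):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class ScreenConfig:
    """Pruning, one-mutant neighborhoods, and iso-morphological walks."""

    n_twins: int = 10             # twins per mutant in IS screens / pruning
    cmd_margin: float = 0.01      # acceptance margin over parental instability
    prune_stop_rejections: int = 40
    max_prune_trials: int | None = None  # overall cap on deletion attempts
    is_magnitudes: tuple[int, ...] = (-80, -60, -40, -20, 20, 40, 60, 80)
    max_parameters: int | None = None  # cap parameters screened (None: all)
    walk_count: int = 10
    walk_steps: int = 200
    walk_twins: int = 5
    walk_eligibility_emd: float = 0.3
    #: walks compound: each step perturbs the current value by +-2x the
    #: *parental* value of that parameter
    walk_step_factor: float = 2.0

    def validate(self) -> None:
        if self.n_twins < 2:
            raise ValueError("n_twins must be >= 2")
        if any(mg == 0 for mg in self.is_magnitudes):
            raise ValueError("IS magnitudes never 0")


@dataclass
class Config:
    sim: SimConfig = field(default_factory=SimConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def validate(self) -> None:
        self.sim.validate()
        self.ensemble.validate()
        self.screen.validate()


def _from_mapping(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key: {path}{key}")
        ftype = fields[key].type
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> Config:
    """Load a YAML config; unknown keys are rejected, defaults fill gaps."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    cfg = Config()
    for section in ("sim", "ensemble", "screen"):
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ValueError(f"section {section} must be a mapping")
            cls = type(getattr(cfg, section))
            setattr(cfg, section, _from_mapping(cls, sub, section + "."))
    if data:
        raise ValueError(f"unknown config key: {sorted(data)[0]}")
    cfg.validate()
    return cfg


def save_config(cfg: Config, path) -> None:
    def clean(obj):
        d = dataclasses.asdict(obj)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}

    with open(path, "w") as fh:
        yaml.safe_dump({"sim": clean(cfg.sim), "ensemble": clean(cfg.ensemble),
                        "screen": clean(cfg.screen)}, fh, sort_keys=True)
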