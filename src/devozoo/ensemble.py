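"""Random developmental mechanisms and the two-stage ensemble protocol.

Mechanisms are sampled as random gene networks: every ordered gene pair
(self-pairs included) receives an interaction with probability
``p_interact``, signed activator/inhibitor with equal chance and magnitude
uniform on (0, t_max).  Each gene is extracellularly diffusible with
probability one half, and gene 1 is constrained to directly activate a
diffusible gene product.  Behaviors are then attached: each gene has a
``p_couple`` chance of regulating one uniformly chosen cell behavior or
mechanical property.

The default protocol is the *signaling ensemble*: a sampled network first
runs with all motion and behaviors frozen (cell signaling only) and is kept
only if it reaches a temporally stable expression pattern that differs from
the initial one -- a stable pattern transformation.  Only then are behaviors
attached and the full mechanical simulation run.  The *broad* variant
(behaviors attached with no screen) is available behind a config flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, EnsembleConfig, SimConfig
from .core import (BEHAVIOR_TARGETS, Coupling, DevMechanism, GeneSpec,
                   Morphology, RATE_LIKE_TARGETS, build_initial_morphology)
from .morphometrics import ComplexityScore, complexity
from .seeding import derive_seed as _derive_seed
from .simulator import Trajectory, run_development


def sample_network(n_genes: int, p_interact: float, t_max: float,
                   rng: np.random.Generator,
                   cfg: EnsembleConfig | None = None) -> DevMechanism:
    """Sample a random gene network (no behavior couplings yet)."""
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    cfg = cfg or EnsembleConfig()
    present = rng.random((n_genes, n_genes)) < p_interact
    signs = np.where(rng.random((n_genes, n_genes)) < 0.5, 1.0, -1.0)
    magnitude = rng.uniform(0.0, t_max, (n_genes, n_genes))
    T = np.where(present, signs * magnitude, 0.0)

    diffusible = rng.random(n_genes) < cfg.p_diffusible
    # gene 1 (index 0) must directly activate a diffusible gene product
    candidates = [g for g in range(1, n_genes) if diffusible[g]]
    if not candidates:
        g = int(rng.integers(1, n_genes))
        diffusible[g] = True
        candidates = [g]
    target = int(candidates[rng.integers(len(candidates))])
    if T[0, target] <= 0.0:
        T[0, target] = rng.uniform(0.0, t_max)

    specs = []
    for g in range(n_genes):
        D = rng.uniform(*cfg.diffusion_range) if diffusible[g] else 0.0
        mu = rng.uniform(*cfg.degradation_range)
        specs.append(GeneSpec(bool(diffusible[g]), float(D), float(mu)))
    return DevMechanism(n_genes=n_genes, T=T, gene_specs=specs)


def sample_coupling(gene: int, rng: np.random.Generator,
                    cfg: EnsembleConfig) -> Coupling:
    """One random behavior/property coupling for a gene.

    Rate-like behaviors (division, apoptosis, ECM secretion, EMT) get
    log-uniform positive strengths; mechanical properties get uniform signed
    strengths (contraction vs growth, stiffening vs softening).
    """
    target = BEHAVIOR_TARGETS[rng.integers(len(BEHAVIOR_TARGETS))]
    if target in RATE_LIKE_TARGETS:
        lo, hi = cfg.rate_coupling_range
        strength = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        strength = float(rng.uniform(*cfg.property_coupling_range))
    return Coupling(gene=gene, target=target, strength=strength)


def attach_behaviors(mech: DevMechanism, p_couple: float,
                     rng: np.random.Generator,
                     cfg: EnsembleConfig | None = None) -> DevMechanism:
    """Attach behavior couplings; returns a new mechanism.

    Each gene is independently coupled with probability ``p_couple`` to one
    uniformly chosen behavior or mechanical property, and every cell gets
    the default small division rate.
    """
    cfg = cfg or EnsembleConfig()
    out = mech.copy()
    for g in range(mech.n_genes):
        if rng.random() < p_couple:
            out.couplings.append(sample_coupling(g, rng, cfg))
    out.default_division_rate = cfg.default_division_rate
    return out


@dataclass
class ScreenOutcome:
    passed: bool
    reason: str
    trajectory: Trajectory

    @property
    def final_pattern(self) -> np.ndarray:
        return self.trajectory.final.expr


def signaling_only_screen(mech: DevMechanism, initial: Morphology,
                          sim_cfg: SimConfig,
                          ens_cfg: EnsembleConfig | None = None
                          ) -> ScreenOutcome:
    """Run the signaling-only protocol and judge pattern transformation.

    Cells are not allowed to move, grow or divide; only signaling runs.  The
    mechanism passes iff the expression dynamics reach a steady state whose
    pattern differs from the initial one beyond the configured threshold --
    i.e. a temporally stable pattern *transformation* occurred.
    """
    ens_cfg = ens_cfg or EnsembleConfig()
    import dataclasses
    cfg = dataclasses.replace(sim_cfg, max_steps=ens_cfg.signaling_max_steps)
    traj = run_development(mech, initial, cfg, freeze_motion=True)
    if traj.termination_reason != "steady":
        return ScreenOutcome(False, "not_steady", traj)
    change = float(np.mean(np.abs(traj.final.expr - initial.expr)))
    if change < ens_cfg.pattern_change_threshold:
        return ScreenOutcome(False, "no_transformation", traj)
    return ScreenOutcome(True, "stable_transformation", traj)


@dataclass
class EnsembleMember:
    index: int
    seed: int
    mechanism: DevMechanism
    morphology: Morphology
    scores: ComplexityScore
    termination_reason: str


def generate_ensemble(n_mechanisms: int, config: Config, seed: int,
                      progress=None) -> list[EnsembleMember]:
    """Build an ensemble of random developmental mechanisms.

    Repeats sample -> signaling-only screen -> attach behaviors -> full
    development until ``n_mechanisms`` non-aberrant members are collected
    (or the attempt cap is reached).  Every member records the seed of its
    attempt, so it can be regenerated bit-identically.
    """
    if n_mechanisms < 1:
        raise ValueError("n_mechanisms must be >= 1")
    config.validate()
    members: list[EnsembleMember] = []
    max_attempts = config.ensemble.max_attempts_factor * n_mechanisms
    for attempt in range(max_attempts):
        member = build_member(config, _derive_seed(seed, attempt))
        if member is not None:
            member.index = len(members)
            members.append(member)
            if progress is not None:
                progress(len(members))
            if len(members) >= n_mechanisms:
                break
    return members


def build_member(config: Config, attempt_seed: int
                 ) -> EnsembleMember | None:
    """One ensemble attempt from its seed; None if screened out or aberrant.

    ``build_member(config, member.seed)`` regenerates a member exactly.
    """
    import dataclasses
    rng = np.random.default_rng(np.random.SeedSequence(attempt_seed))
    ens, sim = config.ensemble, config.sim
    initial = build_initial_morphology(sim.sheet_rings, sim.gradient_gene,
                                       ens.n_genes)
    mech = sample_network(ens.n_genes, ens.p_interact, ens.t_max, rng, ens)
    if not ens.broad:
        outcome = signaling_only_screen(mech, initial, sim, ens)
        if not outcome.passed:
            return None
    mech = attach_behaviors(mech, ens.p_couple, rng, ens)
    run_cfg = dataclasses.replace(sim, seed=_derive_seed(attempt_seed, 1))
    traj = run_development(mech, initial, run_cfg)
    if traj.aberrant:
        return None
    final = traj.final
    if not final.epithelial_mask.any() or final.epithelial_mask.sum() < 4:
        return None
    return EnsembleMember(index=-1, seed=attempt_seed, mechanism=mech,
                          morphology=final, scores=complexity(final),
                          termination_reason=traj.termination_reason)
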