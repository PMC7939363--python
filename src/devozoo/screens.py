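"""Mechanism-level experiments: pruning, mutant neighborhoods, iso-walks.

All screens judge morphological change against *developmental instability*:
the mean pairwise morphological distance between twins (stochastic replicates
of the same mechanism differing only in their noise seed).  A mutant counts
as "different from its parent" when the mean convexity distance (CMD)
between its twins and the parent's twins exceeds the parent's own
CMD-instability by a small margin (0.01 by default); an aberrant mutant
counts as different (an aberrant embryo is maximally changed).

- **pruning** deletes superfluous interactions: deletions that leave the
  morphology unchanged within the threshold persist, until a run of
  consecutive rejections stops the process.
- **IS one-mutant neighborhood**: per parameter, eight offspring at -80% to
  +80% of the parental value in 20% steps, each simulated as several twins.
- **T one-mutant neighborhoods**: one deletion mutant per interaction and an
  equal number of single-random-addition mutants.
- **iso-morphological random walk**: a sequence of IS-mutations (each step
  perturbs one parameter by +-2x its parental value) accepted only when the
  morphology is preserved; the accepted-step count proxies the size of the
  parameter-space region (neutral network) producing the morphology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .config import ScreenConfig, SimConfig
from .core import DevMechanism, Morphology
from .ensemble import EnsembleConfig, sample_coupling
from .morphometrics import cmd as _cmd, emd as _emd, hmd as _hmd
from .seeding import derive_seed, rng_for
from .simulator import run_development

_METRICS = {"emd": _emd, "cmd": _cmd, "hmd": _hmd}


class WalkEligibilityError(ValueError):
    """Parent too developmentally unstable for an iso-morphological walk."""


@dataclass
class MutationRecord:
    parent_id: int
    kind: str  # "IS" | "T-delete" | "T-add"
    descriptor: tuple | None  # parameter descriptor for IS mutations
    magnitude: float  # signed percent for IS, 0 for T
    twin_seeds: list[int]
    twins: list[Morphology]
    n_aberrant: int
    mechanism: DevMechanism | None = None

    def __post_init__(self):
        if self.kind == "IS" and self.magnitude not in \
                (-80, -60, -40, -20, 20, 40, 60, 80):
            raise ValueError("IS magnitude must be +-{20,40,60,80}%")


@dataclass
class WalkResult:
    parent_id: int
    walk_index: int
    steps_attempted: int
    accepted: int
    final_mechanism: DevMechanism
    accepted_mask: list[bool] = field(default_factory=list)


def simulate_twins(mech: DevMechanism, initial: Morphology, k: int,
                   sim_cfg: SimConfig, base_seed: int, *keys: int
                   ) -> tuple[list[Morphology], list[int], int]:
    """Simulate k twins; returns (non-aberrant finals, seeds, n_aberrant)."""
    twins, seeds, n_aberrant = [], [], 0
    for t in range(k):
        s = derive_seed(base_seed, *keys, t)
        cfg = dataclasses.replace(sim_cfg, seed=s)
        traj = run_development(mech, initial, cfg)
        seeds.append(s)
        if traj.aberrant:
            n_aberrant += 1
        else:
            twins.append(traj.final)
    return twins, seeds, n_aberrant


def mean_pairwise_distance(morphs: list[Morphology], metric: str) -> float:
    fn = _METRICS[metric]
    pairs = list(combinations(range(len(morphs)), 2))
    if not pairs:
        raise ValueError("need at least two morphologies")
    return float(np.mean([fn(morphs[a], morphs[b]) for a, b in pairs]))


def mean_cross_distance(set1: list[Morphology], set2: list[Morphology],
                        metric: str) -> float:
    fn = _METRICS[metric]
    if not set1 or not set2:
        raise ValueError("empty twin set")
    return float(np.mean([fn(a, b) for a in set1 for b in set2]))


def developmental_instability(mech: DevMechanism, initial: Morphology,
                              k_twins: int, metric: str, sim_cfg: SimConfig,
                              base_seed: int
                              ) -> tuple[float, list[Morphology], int]:
    """Mean pairwise twin distance under the chosen metric.

    Returns (instability, surviving twins, aberrant count).  With zero noise
    the twins are identical and the instability is exactly zero.
    """
    if k_twins < 2:
        raise ValueError("k_twins must be >= 2")
    twins, _, n_ab = simulate_twins(mech, initial, k_twins, sim_cfg,
                                    base_seed, 0)
    if len(twins) < 2:
        raise ValueError("fewer than two non-aberrant twins")
    return mean_pairwise_distance(twins, metric), twins, n_ab


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune(parent: DevMechanism, parent_twins: list[Morphology],
          initial: Morphology, sim_cfg: SimConfig, screen_cfg: ScreenConfig,
          rng: np.random.Generator, base_seed: int
          ) -> tuple[DevMechanism, int]:
    """Remove superfluous interactions from a parent mechanism.

    Iteratively deletes a randomly chosen interaction; the deletion persists
    when the mean CMD between the candidate's twins and the parent's twins
    stays within the parent's CMD-instability plus the margin.  Stops after
    the configured number of consecutive rejections or when no interactions
    remain.  Returns (pruned mechanism, number of deletions accepted).
    """
    parent_inst = mean_pairwise_distance(parent_twins, "cmd")
    threshold = parent_inst + screen_cfg.cmd_margin
    current = parent.copy()
    consecutive_rejections = 0
    accepted = 0
    trial = 0
    max_trials = screen_cfg.max_prune_trials or np.inf
    while current.n_interactions > 0 and trial < max_trials and \
            consecutive_rejections < screen_cfg.prune_stop_rejections:
        idx = int(rng.integers(current.n_interactions))
        candidate = current.without_interaction(idx)
        twins, _, n_ab = simulate_twins(candidate, initial,
                                        screen_cfg.n_twins, sim_cfg,
                                        base_seed, 1, trial)
        trial += 1
        ok = n_ab == 0 and len(twins) >= 2 and \
            mean_cross_distance(twins, parent_twins, "cmd") <= threshold
        if ok:
            current = candidate
            accepted += 1
            consecutive_rejections = 0
        else:
            consecutive_rejections += 1
    return current, accepted


# ---------------------------------------------------------------------------
# one-mutant neighborhoods
# ---------------------------------------------------------------------------

def _screened_descriptors(mech: DevMechanism, screen_cfg: ScreenConfig):
    desc = mech.parameter_descriptors()
    cap = screen_cfg.max_parameters
    if cap is not None and len(desc) > cap:
        keep = np.linspace(0, len(desc) - 1, cap).round().astype(int)
        desc = [desc[i] for i in sorted(set(int(i) for i in keep))]
    return desc


def is_neighborhood(parent: DevMechanism, initial: Morphology,
                    sim_cfg: SimConfig, screen_cfg: ScreenConfig,
                    base_seed: int, parent_id: int = 0
                    ) -> list[MutationRecord]:
    """Interaction-strength one-mutant neighborhood of a parent.

    For each (screened) parameter, eight mutants at -80..+80% of the
    parental value, each simulated as ``n_twins`` twins with distinct seeds.
    Parameters are all non-zero by construction, so a proportional mutation
    always changes the mechanism.
    """
    records = []
    for pi, desc in enumerate(_screened_descriptors(parent, screen_cfg)):
        value = parent.get_parameter(desc)
        assert value != 0.0, "parameters enumerate non-zero entries only"
        for mag in screen_cfg.is_magnitudes:
            mutant = parent.with_parameter(desc, value * (1.0 + mag / 100.0))
            twins, seeds, n_ab = simulate_twins(
                mutant, initial, screen_cfg.n_twins, sim_cfg,
                base_seed, 2, pi, mag + 100)
            records.append(MutationRecord(
                parent_id=parent_id, kind="IS", descriptor=desc,
                magnitude=mag, twin_seeds=seeds, twins=twins,
                n_aberrant=n_ab, mechanism=mutant))
    return records


def t_neighborhoods(parent: DevMechanism, initial: Morphology,
                    sim_cfg: SimConfig, screen_cfg: ScreenConfig,
                    rng: np.random.Generator, base_seed: int,
                    parent_id: int = 0,
                    ens_cfg: EnsembleConfig | None = None
                    ) -> list[MutationRecord]:
    """Topological one-mutant neighborhoods: deletions and additions.

    One deletion mutant per existing interaction, plus N_c mutants each
    adding one random new interaction drawn with the ensemble's samplers
    (resampled on collision with an existing interaction).
    """
    ens_cfg = ens_cfg or EnsembleConfig()
    records = []
    n_c = parent.n_interactions
    for idx in range(n_c):
        mutant = parent.without_interaction(idx)
        twins, seeds, n_ab = simulate_twins(mutant, initial,
                                            screen_cfg.n_twins, sim_cfg,
                                            base_seed, 3, idx)
        records.append(MutationRecord(parent_id=parent_id, kind="T-delete",
                                      descriptor=None, magnitude=0,
                                      twin_seeds=seeds, twins=twins,
                                      n_aberrant=n_ab, mechanism=mutant))
    for a in range(n_c):
        mutant = add_random_interaction(parent, rng, ens_cfg)
        twins, seeds, n_ab = simulate_twins(mutant, initial,
                                            screen_cfg.n_twins, sim_cfg,
                                            base_seed, 4, a)
        records.append(MutationRecord(parent_id=parent_id, kind="T-add",
                                      descriptor=None, magnitude=0,
                                      twin_seeds=seeds, twins=twins,
                                      n_aberrant=n_ab, mechanism=mutant))
    return records


def add_random_interaction(mech: DevMechanism, rng: np.random.Generator,
                           ens_cfg: EnsembleConfig,
                           max_tries: int = 1000) -> DevMechanism:
    """Add one random interaction, never duplicating an existing one.

    With equal chance a gene-gene interaction (uniform over currently-absent
    ordered pairs; signed, magnitude uniform on (0, t_max)) or a
    gene-behavior coupling drawn with the ensemble sampler (resampled while
    the (gene, target) slot is occupied).
    """
    out = mech.copy()
    existing = {(c.gene, c.target) for c in mech.couplings}
    for _ in range(max_tries):
        if rng.random() < 0.5:
            l = int(rng.integers(mech.n_genes))
            k = int(rng.integers(mech.n_genes))
            if out.T[l, k] != 0.0:
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.T[l, k] = sign * rng.uniform(0.0, ens_cfg.t_max)
            return out
        c = sample_coupling(int(rng.integers(mech.n_genes)), rng, ens_cfg)
        if (c.gene, c.target) in existing:
            continue
        out.couplings.append(c)
        return out
    raise RuntimeError("could not find a free interaction slot")


# ---------------------------------------------------------------------------
# iso-morphological random walks
# ---------------------------------------------------------------------------

def iso_walk(parent: DevMechanism, parent_twins: list[Morphology],
             initial: Morphology, sim_cfg: SimConfig,
             screen_cfg: ScreenConfig, base_seed: int, parent_id: int = 0
             ) -> list[WalkResult]:
    """Iso-morphological random walks through parameter space.

    Eligibility requires a developmentally stable parent (twin EMD below the
    configured cut).  Each walk perturbs one uniformly chosen parameter per
    step by +-2x its *parental* value (signs uniform; steps compound), keeps
    the step when the mean CMD between the mutant's twins and the parent's
    twins stays within the parent's CMD-instability plus the margin, and
    reverts it otherwise.  The accepted count estimates the size of the
    parameter-space region producing the parent's morphology.
    """
    emd_inst = mean_pairwise_distance(parent_twins, "emd")
    if emd_inst >= screen_cfg.walk_eligibility_emd:
        raise WalkEligibilityError(
            f"parent EMD-instability {emd_inst:.3f} >= "
            f"{screen_cfg.walk_eligibility_emd}")
    cmd_inst = mean_pairwise_distance(parent_twins, "cmd")
    threshold = cmd_inst + screen_cfg.cmd_margin
    descriptors = parent.parameter_descriptors()
    parental_values = [parent.get_parameter(d) for d in descriptors]
    results = []
    for w in range(screen_cfg.walk_count):
        rng = rng_for(base_seed, 5, w)
        current = parent.copy()
        accepted = 0
        mask = []
        for s in range(screen_cfg.walk_steps):
            pi = int(rng.integers(len(descriptors)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            desc = descriptors[pi]
            step = sign * screen_cfg.walk_step_factor * parental_values[pi]
            candidate = current.with_parameter(
                desc, current.get_parameter(desc) + step)
            twins, _, n_ab = simulate_twins(candidate, initial,
                                            screen_cfg.walk_twins, sim_cfg,
                                            base_seed, 5, w, s)
            ok = n_ab == 0 and len(twins) >= 1 and \
                mean_cross_distance(twins, parent_twins, "cmd") <= threshold
            if ok:
                current = candidate
                accepted += 1
            mask.append(ok)
        results.append(WalkResult(parent_id=parent_id, walk_index=w,
                                  steps_attempted=screen_cfg.walk_steps,
                                  accepted=accepted,
                                  final_mechanism=current,
                                  accepted_mask=mask))
    return results
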