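"""Random-mechanism sampling and the signaling-ensemble protocol."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.stats import chisquare

from devozoo.config import Config, EnsembleConfig, SimConfig
from devozoo.core import (BEHAVIOR_TARGETS, DevMechanism, GeneSpec,
                          build_initial_morphology)
from devozoo.ensemble import (attach_behaviors, build_member,
                              generate_ensemble, sample_network,
                              signaling_only_screen)
from devozoo.fixtures import fig11_cascade
from devozoo.morphometrics import count_expression_territories
from devozoo.simulator import detect_aberrant, run_development


def test_no_interactions_without_density_except_enforced_edge(rng):
    mech = sample_network(10, 0.0, 1.0, rng)
    nz = np.argwhere(mech.T != 0.0)
    assert len(nz) == 1
    l, k = nz[0]
    assert l == 0 and mech.T[0, k] > 0  # gene 1 activates ...
    assert mech.gene_specs[k].diffusible  # ... a diffusible gene


def test_interaction_density_within_binomial_error(rng):
    n_draws, n_genes, p = 500, 10, 0.2
    counts = [np.count_nonzero(sample_network(n_genes, p, 1.0, rng).T)
              for _ in range(n_draws)]
    # subtract the ~1 enforced edge; compare against 3 binomial SEs
    total = n_draws * n_genes ** 2
    se = np.sqrt(p * (1 - p) / total)
    density = (np.sum(counts) - n_draws) / total  # upper bound on extras
    assert abs(density - p) < 3 * se + 1.0 / n_genes ** 2


def test_diffusible_fraction_is_half(rng):
    draws = 2000
    frac = np.mean([[s.diffusible for s in
                     sample_network(10, 0.2, 1.0, rng).gene_specs]
                    for _ in range(draws)])
    se = np.sqrt(0.25 / (draws * 10))
    assert abs(frac - 0.5) < 3 * se + 0.01  # enforcement adds a small bias


def test_signs_are_balanced_and_magnitudes_bounded(rng):
    mech = sample_network(50, 0.5, 2.0, rng)
    vals = mech.T[mech.T != 0.0]
    assert np.all(np.abs(vals) <= 2.0)
    assert 0.3 < np.mean(vals > 0) < 0.7


def test_attach_behaviors_probability_and_uniform_targets(rng):
    base = sample_network(10, 0.2, 1.0, rng)
    assert len(attach_behaviors(base, 0.0, rng).couplings) == 0
    draws, coupled, targets = 2000, 0, []
    for _ in range(draws):
        mech = attach_behaviors(base, 0.5, rng)
        coupled += len(mech.couplings)
        targets.extend(c.target for c in mech.couplings)
    frac = coupled / (draws * 10)
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (draws * 10))
    counts = [targets.count(t) for t in BEHAVIOR_TARGETS]
    assert chisquare(counts).pvalue > 0.01


def test_rate_couplings_positive_property_couplings_signed(rng):
    from devozoo.core import RATE_LIKE_TARGETS
    base = sample_network(10, 0.2, 1.0, rng)
    rate_vals, prop_vals = [], []
    for _ in range(500):
        for c in attach_behaviors(base, 1.0, rng).couplings:
            (rate_vals if c.target in RATE_LIKE_TARGETS
             else prop_vals).append(c.strength)
    assert all(v > 0 for v in rate_vals)
    assert any(v < 0 for v in prop_vals) and any(v > 0 for v in prop_vals)


# ------------------------------------------------------ signaling screen
def test_empty_network_fails_the_screen(sheet3):
    mech = DevMechanism(10, np.zeros((10, 10)),
                        [GeneSpec(False, 0.0, 1.0)] * 10)
    cfg = dataclasses.replace(SimConfig(), seed=0)
    out = signaling_only_screen(mech, sheet3, cfg)
    assert not out.passed
    assert out.reason == "no_transformation"


def test_cascade_passes_with_three_territories(sheet3):
    cfg = dataclasses.replace(SimConfig(), seed=0)
    out = signaling_only_screen(fig11_cascade(), sheet3, cfg,
                                dataclasses.replace(EnsembleConfig(),
                                                    signaling_max_steps=700))
    assert out.passed
    final = out.trajectory.final
    assert count_expression_territories(final, genes=(3, 4, 5)) >= 3


def ring_oscillator():
    """3-stage ring oscillator driven by a self-activating gene.

    Gene 2 switches itself on (seeded by the maternal gradient); genes 3-5
    repress each other cyclically -- a repressilator that cycles instead of
    settling.
    """
    T = np.zeros((10, 10))
    T[0, 1] = 1.0
    T[1, 1] = 3.0
    # unequal stage gains break the symmetry of the all-zero start
    for (x, z), gain in zip(((2, 4), (3, 2), (4, 3)), (4.0, 4.4, 3.6)):
        T[1, x] = gain
        T[z, x] = -20.0
    specs = [GeneSpec(False, 0.0, 1.0) if g < 2 else
             GeneSpec(False, 0.0, 0.6) for g in range(10)]
    return DevMechanism(10, T, specs)


def test_oscillator_cycles_and_fails_the_screen(sheet3):
    mech = ring_oscillator()
    cfg = dataclasses.replace(SimConfig(), seed=0, max_steps=900,
                              record_every=4)
    traj = run_development(mech, sheet3, cfg, freeze_motion=True)
    # peak-counting oracle on one cell's trace confirms sustained cycling
    node = int(np.argmax(sheet3.expr[:, 0]))  # strongest gradient input
    trace = np.array([snap.expr[node, 2] for _, snap in traj.snapshots])
    peaks, _ = find_peaks(trace[len(trace) // 2:], prominence=0.05)
    assert len(peaks) >= 3
    out = signaling_only_screen(mech, sheet3, cfg,
                                dataclasses.replace(EnsembleConfig(),
                                                    signaling_max_steps=900))
    assert not out.passed
    assert out.reason == "not_steady"


# ------------------------------------------------------------- ensemble
@pytest.fixture(scope="module")
def tiny_ensemble():
    cfg = Config()
    cfg.sim = dataclasses.replace(cfg.sim, sheet_rings=2, max_steps=120)
    cfg.ensemble = dataclasses.replace(cfg.ensemble,
                                       property_coupling_range=(-0.1, 0.1),
                                       default_division_rate=0.02)
    return cfg, generate_ensemble(4, cfg, seed=123)


def test_ensemble_members_replay_bit_identically(tiny_ensemble):
    cfg, members = tiny_ensemble
    assert len(members) >= 1
    mb = members[0]
    replay = build_member(cfg, mb.seed)
    assert replay is not None
    assert np.array_equal(replay.mechanism.T, mb.mechanism.T)
    assert replay.mechanism.couplings == mb.mechanism.couplings
    assert np.array_equal(replay.morphology.pos, mb.morphology.pos)
    assert replay.scores == mb.scores


def test_ensemble_members_are_never_aberrant(tiny_ensemble):
    cfg, members = tiny_ensemble
    for mb in members:
        assert not detect_aberrant(mb.morphology, cfg.sim)[0]
        assert mb.scores.av >= 0.0 and mb.scores.opc >= 0


def test_broad_variant_skips_the_signaling_screen():
    """With the broad flag, behaviors are attached with no screening: a
    config whose screen can never pass still yields ensemble members."""
    import dataclasses
    cfg = Config()
    cfg.sim = dataclasses.replace(cfg.sim, sheet_rings=1, max_steps=15)
    strict = dataclasses.replace(cfg.ensemble,
                                 pattern_change_threshold=1e9,
                                 signaling_max_steps=60,
                                 max_attempts_factor=8)
    cfg.ensemble = strict
    assert generate_ensemble(1, cfg, seed=3) == []
    cfg.ensemble = dataclasses.replace(strict, broad=True)
    assert len(generate_ensemble(1, cfg, seed=3)) == 1
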