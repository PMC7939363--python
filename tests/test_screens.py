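"""Mutational screens: instability, pruning, neighborhoods, iso-walks."""

import dataclasses

import numpy as np
import pytest

from devozoo.config import ScreenConfig, SimConfig
from devozoo.core import (Coupling, DevMechanism, GeneSpec,
                          build_initial_morphology)
from devozoo.ensemble import EnsembleConfig, sample_network
from devozoo.screens import (WalkEligibilityError, add_random_interaction,
                             developmental_instability, is_neighborhood,
                             iso_walk, mean_cross_distance,
                             mean_pairwise_distance, prune, simulate_twins,
                             t_neighborhoods)
from devozoo.seeding import rng_for


@pytest.fixture(scope="module")
def sheet2():
    return build_initial_morphology(2)


def smoke_sim(**kw):
    kw.setdefault("max_steps", 100)
    kw.setdefault("sheet_rings", 2)
    return dataclasses.replace(SimConfig(), **kw)


def smoke_screen(**kw):
    kw.setdefault("n_twins", 2)
    kw.setdefault("prune_stop_rejections", 6)
    kw.setdefault("walk_count", 1)
    kw.setdefault("walk_steps", 8)
    kw.setdefault("walk_twins", 2)
    return dataclasses.replace(ScreenConfig(), **kw)


def contraction_mech(strength=-0.1):
    mech = DevMechanism(10, np.zeros((10, 10)),
                        [GeneSpec(False, 0.0, 1.0)] * 10)
    mech.couplings.append(Coupling(0, "contraction_apical", strength))
    return mech


def inert_mech():
    return DevMechanism(10, np.zeros((10, 10)),
                        [GeneSpec(False, 0.0, 1.0)] * 10)


def serialized(mech, tmp_path, name):
    path = tmp_path / name
    mech.save(path)
    return path.read_text()


# ----------------------------------------------------------- instability
def test_zero_noise_means_zero_instability(sheet2):
    cfg = smoke_sim(noise_amplitude=0.0)
    inst, twins, n_ab = developmental_instability(
        contraction_mech(), sheet2, 3, "emd", cfg, base_seed=7)
    assert inst == pytest.approx(0.0, abs=1e-12)
    assert n_ab == 0 and len(twins) == 3


def test_instability_nondecreasing_in_noise(sheet2):
    vals = []
    for amp in (0.002, 0.01, 0.05):
        cfg = smoke_sim(noise_amplitude=amp)
        inst, _, _ = developmental_instability(
            contraction_mech(), sheet2, 4, "emd", cfg, base_seed=3)
        vals.append(inst)
    assert vals[0] < vals[1] < vals[2]


def test_instability_rejects_single_twin(sheet2):
    with pytest.raises(ValueError):
        developmental_instability(inert_mech(), sheet2, 1, "emd",
                                  smoke_sim(), 0)


# ---------------------------------------------------------------- prune
def test_inert_network_prunes_to_nothing(sheet2):
    # a network with zero behavior couplings never changes the morphology,
    # so every deletion is accepted and pruning empties the network
    mech = sample_network(10, 0.3, 1.0, np.random.default_rng(2))
    cfg = smoke_sim()
    scr = smoke_screen()
    twins, _, _ = simulate_twins(mech, sheet2, scr.n_twins, cfg, 11, 0)
    pruned, n_del = prune(mech, twins, sheet2, cfg, scr,
                          rng_for(11, 99), base_seed=11)
    assert pruned.n_interactions == 0
    assert n_del == mech.n_interactions


def test_pruning_never_adds_and_respects_essential_chain(sheet2, tmp_path):
    # chain: gradient gene drives gene 2 (T edge), gene 2 drives apical
    # contraction -- both interactions are essential; a spurious extra edge
    # into an unused gene is not
    mech = DevMechanism(10, np.zeros((10, 10)),
                        [GeneSpec(False, 0.0, 1.0)] * 10)
    mech.T[0, 1] = 8.0
    mech.T[0, 5] = 0.5  # superfluous: gene 6 regulates nothing
    mech.couplings.append(Coupling(1, "contraction_apical", -0.15))
    cfg = smoke_sim(max_steps=150)
    scr = smoke_screen(n_twins=3, prune_stop_rejections=8)
    twins, _, _ = simulate_twins(mech, sheet2, scr.n_twins, cfg, 21, 0)
    parent_inst = mean_pairwise_distance(twins, "cmd")

    # exhaustive single-deletion oracle
    essential = set()
    for idx in range(mech.n_interactions):
        cand = mech.without_interaction(idx)
        ctwins, _, n_ab = simulate_twins(cand, sheet2, 3, cfg, 77, idx)
        changed = n_ab > 0 or mean_cross_distance(
            ctwins, twins, "cmd") > parent_inst + scr.cmd_margin
        if changed:
            essential.add(idx)
    assert 0 in essential or 2 in essential  # the chain matters
    assert 1 not in essential               # the dangling edge does not

    pruned, _ = prune(mech, twins, sheet2, cfg, scr, rng_for(21, 99), 21)
    assert pruned.n_interactions <= mech.n_interactions
    # chain preserved: the T[0,1] edge and the contraction coupling remain
    assert pruned.T[0, 1] == mech.T[0, 1]
    assert any(c.target == "contraction_apical" for c in pruned.couplings)
    assert pruned.T[0, 5] == 0.0  # superfluous edge removed


# -------------------------------------------------------- neighborhoods
def test_is_neighborhood_size_and_single_parameter_difference(
        sheet2, tmp_path):
    mech = contraction_mech()
    mech.T[0, 1] = 2.0
    cfg = smoke_sim(max_steps=40)
    scr = smoke_screen()
    records = is_neighborhood(mech, sheet2, cfg, scr, base_seed=5)
    k = len(mech.parameter_descriptors())
    assert len(records) == 8 * k
    ref = serialized(mech, tmp_path, "parent.txt")
    for rec in records:
        assert rec.magnitude in (-80, -60, -40, -20, 20, 40, 60, 80)
        assert len(rec.twins) + rec.n_aberrant == scr.n_twins
        mut = serialized(rec.mechanism, tmp_path, "mut.txt")
        # exactly one line differs between parent and mutant files
        diff = [a for a, b in zip(ref.splitlines(), mut.splitlines())
                if a != b]
        assert len(diff) == 1
        value = mech.get_parameter(rec.descriptor)
        assert rec.mechanism.get_parameter(rec.descriptor) == pytest.approx(
            value * (1 + rec.magnitude / 100.0))


def test_t_neighborhood_counts_and_no_duplicate_additions(sheet2):
    mech = contraction_mech()
    mech.T[0, 1] = 2.0
    mech.T[1, 2] = -1.0
    n_c = mech.n_interactions
    cfg = smoke_sim(max_steps=30)
    records = t_neighborhoods(mech, sheet2, cfg, smoke_screen(),
                              rng_for(9, 1), base_seed=9)
    dels = [r for r in records if r.kind == "T-delete"]
    adds = [r for r in records if r.kind == "T-add"]
    assert len(dels) == n_c and len(adds) == n_c
    for r in dels:
        assert r.mechanism.n_interactions == n_c - 1
    for r in adds:
        assert r.mechanism.n_interactions == n_c + 1


def test_addition_resamples_on_collision(rng):
    # nearly full interaction matrix forces repeated collisions
    mech = sample_network(4, 1.0, 1.0, rng)  # every T entry occupied
    ens = EnsembleConfig()
    for _ in range(20):
        out = add_random_interaction(mech, rng, ens)
        new_t = np.argwhere((out.T != 0) & (mech.T == 0))
        new_c = len(out.couplings) - len(mech.couplings)
        assert len(new_t) + new_c == 1
        if new_c:
            assert len({(c.gene, c.target) for c in out.couplings}) \
                == len(out.couplings)


def test_delete_then_readd_is_morphologically_neutral(sheet2):
    mech = contraction_mech(-0.12)
    mech.T[0, 1] = 2.0
    cfg = smoke_sim(max_steps=120)
    scr = smoke_screen(n_twins=3)
    twins, _, _ = simulate_twins(mech, sheet2, scr.n_twins, cfg, 31, 0)
    inst = mean_pairwise_distance(twins, "cmd")
    # delete the T edge and re-add the identical interaction
    idx = [i for i, d in enumerate(mech.parameter_descriptors())
           if d == ("T", 0, 1)]
    assert idx
    cand = mech.without_interaction(0)  # first interaction is T[0,1]
    assert cand.T[0, 1] == 0.0
    cand.T[0, 1] = mech.T[0, 1]
    rtwins, _, _ = simulate_twins(cand, sheet2, scr.n_twins, cfg, 32, 0)
    assert mean_cross_distance(rtwins, twins, "cmd") <= inst + scr.cmd_margin


# ------------------------------------------------------------ iso-walks
def test_walk_accepts_everything_for_inert_parameters(sheet2):
    # network parameters with no route to any behavior never change the
    # morphology, so every step of the walk is accepted
    mech = sample_network(10, 0.3, 1.0, np.random.default_rng(8))
    cfg = smoke_sim(max_steps=60)
    scr = smoke_screen(walk_steps=6)
    twins, _, _ = simulate_twins(mech, sheet2, scr.n_twins, cfg, 41, 0)
    results = iso_walk(mech, twins, sheet2, cfg, scr, base_seed=41)
    assert len(results) == scr.walk_count
    for r in results:
        assert r.accepted == r.steps_attempted == scr.walk_steps


def test_knife_edge_walk_matches_exhaustive_single_step_oracle(sheet2):
    from devozoo.fixtures import knife_edge
    mech = knife_edge()
    cfg = smoke_sim(max_steps=150)
    scr = smoke_screen(walk_steps=10, walk_twins=2)
    twins, _, _ = simulate_twins(mech, sheet2, scr.walk_twins, cfg, 51, 0)
    inst = mean_pairwise_distance(twins, "cmd")
    # oracle: try every (parameter, sign) single step from the parent
    desc = mech.parameter_descriptors()
    oracle_accepts = 0
    for pi, d in enumerate(desc):
        for sign in (1.0, -1.0):
            v = mech.get_parameter(d)
            cand = mech.with_parameter(d, v + sign * 2.0 * v)
            ctwins, _, n_ab = simulate_twins(cand, sheet2, scr.walk_twins,
                                             cfg, 52, pi, int(sign > 0))
            ok = n_ab == 0 and len(ctwins) >= 1 and mean_cross_distance(
                ctwins, twins, "cmd") <= inst + scr.cmd_margin
            oracle_accepts += ok
    results = iso_walk(mech, twins, sheet2, cfg, scr, base_seed=51)
    walk_rate = results[0].accepted / results[0].steps_attempted
    oracle_rate = oracle_accepts / (2 * len(desc))
    assert oracle_rate <= 0.25  # essentially every parameter is critical
    assert abs(walk_rate - oracle_rate) <= 0.25


def test_walk_decisions_reproducible_and_bounded(sheet2):
    mech = contraction_mech(-0.1)
    cfg = smoke_sim(max_steps=80)
    scr = smoke_screen(walk_steps=5)
    twins, _, _ = simulate_twins(mech, sheet2, scr.walk_twins, cfg, 61, 0)
    r1 = iso_walk(mech, twins, sheet2, cfg, scr, base_seed=61)
    r2 = iso_walk(mech, twins, sheet2, cfg, scr, base_seed=61)
    assert [w.accepted_mask for w in r1] == [w.accepted_mask for w in r2]
    assert all(0 <= w.accepted <= w.steps_attempted for w in r1)


def test_unstable_parent_is_ineligible_for_walks(sheet2):
    mech = contraction_mech(-0.1)
    cfg = smoke_sim(noise_amplitude=0.08, max_steps=80)
    twins, _, _ = simulate_twins(mech, sheet2, 3, cfg, 71, 0)
    assert mean_pairwise_distance(twins, "emd") >= 0.3
    with pytest.raises(WalkEligibilityError):
        iso_walk(mech, twins, sheet2, cfg, smoke_screen(), base_seed=71)
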