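import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from h3graft import grafting, stem_library
from h3graft import loop_sampling as ls
from h3graft.loop_sampling import (LoopConformation, contact_count,
                                   contact_filter, cull_ensemble,
                                   minimize_loop, retain_per_stem,
                                   sample_tip, tip_window)


def test_tip_window_table():
    assert tip_window(6) == ls.TipWindow(1, 6)
    assert tip_window(7).empty
    assert tip_window(8) == ls.TipWindow(2, 6)
    assert len(tip_window(8)) == 5
    assert tip_window(9) == ls.TipWindow(3, 7)
    assert tip_window(13) == ls.TipWindow(3, 10)
    assert len(tip_window(13)) == 8
    for L in range(10, 20):
        assert tip_window(L) == ls.TipWindow(3, L - 3)
    with pytest.raises(ValueError):
        tip_window(5)


def test_sample_tip_postconditions(tip_ensemble):
    assert len(tip_ensemble.conformations) == 60
    assert all(c.closure_gap <= 0.5 for c in tip_ensemble.conformations)
    assert tip_ensemble.stage == "initial"
    # omega stays trans (within 30 degrees)
    for conf in tip_ensemble.conformations[:10]:
        om = conf.dihedrals[:, 2]
        om = om[~np.isnan(om)]
        assert (np.abs(np.abs(om) - 180.0) % 360 < 30.0).all()


def test_sample_tip_deterministic(parent_graft, tip_ensemble):
    again = sample_tip(parent_graft, n_samples=60, seed=3)
    for a, b in zip(tip_ensemble.conformations, again.conformations):
        assert np.array_equal(a.coords, b.coords)


def test_length7_passes_through_single_conformation(toy, stem_c1):
    t7 = stem_library.build_template(stem_c1, 7)
    g = grafting.graft_stem(toy, t7, "SRWGMDY")
    ens = sample_tip(g, n_samples=100, seed=0)
    assert len(ens.conformations) == 1
    assert ens.conformations[0].closure_gap == 0.0


def _naive_stat(loop_xyz, loop_el, loop_res, env_xyz, env_el):
    e = 0.0
    for i in range(len(loop_xyz)):
        for j in range(len(env_xyz)):
            d = np.linalg.norm(loop_xyz[i] - env_xyz[j])
            if d < ls.STAT_CUTOFF:
                b = min(int(d / ls.STAT_BIN), ls._N_BINS - 1)
                e += ls._STAT_TABLE[loop_el[i], env_el[j], b]
    for i in range(len(loop_xyz)):
        for j in range(i + 1, len(loop_xyz)):
            if abs(loop_res[i] - loop_res[j]) < 2:
                continue
            d = np.linalg.norm(loop_xyz[i] - loop_xyz[j])
            if d < ls.STAT_CUTOFF:
                b = min(int(d / ls.STAT_BIN), ls._N_BINS - 1)
                e += ls._STAT_TABLE[loop_el[i], loop_el[j], b]
    return e


def test_stat_potential_matches_naive_oracle():
    rng = np.random.default_rng(6)
    loop_xyz = rng.normal(size=(20, 3)) * 4
    env_xyz = rng.normal(size=(40, 3)) * 6
    loop_el = rng.integers(0, 4, 20)
    env_el = rng.integers(0, 4, 40)
    loop_res = np.repeat(np.arange(5), 4)
    fast = ls.stat_potential_arrays(loop_xyz, loop_el, loop_res,
                                    env_xyz, env_el)
    slow = _naive_stat(loop_xyz, loop_el, loop_res, env_xyz, env_el)
    assert fast == pytest.approx(slow, abs=1e-9)


def test_stat_potential_cutoff_and_determinism(tip_ensemble):
    conf = tip_ensemble.conformations[1]
    env = tip_ensemble.environment
    e1 = ls.stat_potential(conf, env)
    e2 = ls.stat_potential(conf.copy(), env)
    assert e1 == e2
    # a loop displaced far from everything scores only its internal pairs
    far = conf.copy()
    far.coords = far.coords + 500.0
    ctx = ls._StatContext(env)
    internal_only = ls.stat_potential_arrays(
        far.coords, ctx.loop_el, ctx.loop_res,
        np.zeros((0, 3)), np.zeros(0, int))
    assert ls.stat_potential(far, env) == pytest.approx(internal_only)


def test_cull_keeps_best_rescored(tip_ensemble):
    culled = cull_ensemble(tip_ensemble, keep_rescore=40, keep_top=12)
    assert culled.stage == "culled"
    assert len(culled.conformations) == 12
    rescored = sorted(c.stat_energy
                      for c in tip_ensemble.conformations[:40]
                      if c.stat_energy is not None)
    kept = sorted(c.stat_energy for c in culled.conformations)
    assert kept == rescored[:12]


def test_cull_degenerate_warns(tip_ensemble):
    small = ls.replace_stage(tip_ensemble,
                             tip_ensemble.conformations[:5], "initial")
    with pytest.warns(UserWarning):
        culled = cull_ensemble(small, keep_rescore=5, keep_top=250)
    assert len(culled.conformations) == 5


def test_contact_count_threshold():
    a = LoopConformation(np.array([[0.0, 0, 0]]), np.zeros((1, 3)), 0.0,
                         "c1")
    assert contact_count(a, np.array([[4.4, 0, 0]])) == 1
    assert contact_count(a, np.array([[4.6, 0, 0]])) == 0
    assert contact_count(a, np.zeros((0, 3))) == 0


@given(st.integers(0, 300))
def test_contact_count_brute_force_and_symmetry(seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 12, size=(25, 3))
    B = rng.uniform(0, 12, size=(25, 3))
    brute = sum(1 for a in A for b in B
                if np.linalg.norm(a - b) <= 4.5)
    assert contact_count(A, B) == brute
    assert contact_count(B, A) == brute
    assert contact_count(A, B, cutoff=6.0) >= brute


def test_contact_filter_median_rule(tip_ensemble):
    def fake(counts):
        confs = []
        for c in counts:
            conf = tip_ensemble.conformations[0].copy()
            conf.contact_count = c
            confs.append(conf)
        return ls.replace_stage(tip_ensemble, confs, "culled")

    ref = fake([2, 4, 6, 8, 10])
    cand = fake([5])
    assert len(contact_filter(cand, ref).conformations) == 0
    ref0 = fake([0, 0, 0, 10, 10])
    all_zero = fake([0, 0])
    assert len(contact_filter(all_zero, ref0).conformations) == 2


def test_minimize_loop_contracts(staged):
    filt = staged["filtered"]
    conf = filt.conformations[0].copy()
    env = filt.environment
    out = minimize_loop(conf, env, max_iter=500)
    assert out.min_energy is not None
    again = minimize_loop(out, env, max_iter=500)
    # near a stationary point a further pass barely improves
    assert again.min_energy <= out.min_energy
    assert out.min_energy - again.min_energy < 1.0
    # the environment is never touched
    cx0 = ls.apply_conf(env, conf.coords)
    cx1 = ls.apply_conf(env, out.coords)
    loop = set(env.h3_index_map)
    for a, b in zip(cx0.atoms, cx1.atoms):
        if (a.chain_id, a.residue_label) not in loop:
            assert (a.position == b.position).all()


def _fake_min_ens(base, n, stem, offset=0.0):
    confs = []
    for k in range(n):
        c = base.conformations[0].copy()
        c.stem_of_origin = stem
        c.min_energy = offset + k
        confs.append(c)
    ens = ls.replace_stage(base, confs, "culled")
    ens.environments = {stem: base.environment}
    return ens


def test_retain_per_stem_counts(tip_ensemble):
    two = {"s1": _fake_min_ens(tip_ensemble, 12, "s1"),
           "s2": _fake_min_ens(tip_ensemble, 12, "s2", offset=100)}
    merged = retain_per_stem(two, keep=5)
    assert len(merged.conformations) == 10
    by_stem = {}
    for c in merged.conformations:
        by_stem.setdefault(c.stem_of_origin, []).append(c.min_energy)
    assert sorted(by_stem["s1"]) == [0, 1, 2, 3, 4]
    assert sorted(by_stem["s2"]) == [100, 101, 102, 103, 104]
    one = {"s1": _fake_min_ens(tip_ensemble, 3, "s1")}
    assert len(retain_per_stem(one, keep=5).conformations) == 3


def test_refine_window_and_incumbent(staged):
    final = staged["final"]
    assert final.stage == "final"
    totals = [c.total_energy for c in final.conformations]
    best = min(totals)
    assert all(t <= best + 5.0 for t in totals)
    # refinement never loses the incumbent: the final best is at least as
    # good as the best minimized input
    merged = staged["minimized"]
    from h3graft import scoring
    scorer = scoring.ConformerScorer(merged)
    inputs = [scorer.total_energy(c) for c in merged.conformations]
    assert best <= min(inputs) + 1e-9


def test_refine_zero_window_keeps_only_ties(staged):
    merged = staged["minimized"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = ls.refine_ensemble(
            ls.replace_stage(merged, [c.copy() for c in
                                      merged.conformations[:3]],
                             "minimized"),
            1, 1, window=0.0, seed=5)
    best = min(c.total_energy for c in out.conformations)
    assert all(c.total_energy == best for c in out.conformations)


def test_stage_order_is_monotone(tip_ensemble):
    with pytest.raises(ValueError):
        ls.replace_stage(
            ls.replace_stage(tip_ensemble, tip_ensemble.conformations,
                             "final"),
            tip_ensemble.conformations, "culled")
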