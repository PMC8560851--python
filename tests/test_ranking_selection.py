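import numpy as np
import pytest

from h3graft import fixtures, geometry, model_io, ranking_selection as rs
from h3graft.scoring import ScoreRecord


def _records_from_table(tab):
    return [ScoreRecord(r.id, int(r.length), float(r.total_energy),
                        float(r.interaction_energy), 5)
            for r in tab.itertuples()]


def _records(rows):
    return [ScoreRecord(cid, L, t, i, 1) for cid, L, t, i in rows]


def test_stratum_median_z_is_zero():
    tab = fixtures.make_score_table(fixtures.FixtureSpec(seed=9,
                                                         library_size=60))
    z = rs.stratified_z(_records_from_table(tab))
    by_len = {}
    for r in z:
        by_len.setdefault(r.h3_length, []).append(r)
    for group in by_len.values():
        assert np.median([r.z_total for r in group]) == pytest.approx(
            0.0, abs=1e-9)
        assert np.median([r.z_interaction for r in group]) == \
            pytest.approx(0.0, abs=1e-9)
        for r in group:
            assert r.z_composite == pytest.approx(
                (r.z_total + r.z_interaction) / 2)


def test_candidate_at_stratum_medians_scores_zero():
    rows = [("a", 12, -10.0, -3.0), ("b", 12, -12.0, -5.0),
            ("c", 12, -8.0, -1.0)]
    z = {r.candidate_id: r for r in rs.stratified_z(_records(rows))}
    assert z["a"].z_composite == pytest.approx(0.0, abs=1e-12)


def test_z_affine_invariance():
    tab = fixtures.make_score_table(fixtures.FixtureSpec(seed=10,
                                                         library_size=40))
    recs = _records_from_table(tab)
    z0 = rs.stratified_z(recs)
    scaled = [ScoreRecord(r.candidate_id, r.h3_length,
                          3.0 * r.avg_total - 7.0,
                          0.5 * r.avg_interaction + 2.0, r.n_conformers)
              for r in recs]
    z1 = rs.stratified_z(scaled)
    for a, b in zip(z0, z1):
        assert a.z_total == pytest.approx(b.z_total, abs=1e-9)
        assert a.z_interaction == pytest.approx(b.z_interaction, abs=1e-9)


def test_ranks_are_dense():
    tab = fixtures.make_score_table(fixtures.FixtureSpec(seed=11,
                                                         library_size=30))
    z = rs.stratified_z(_records_from_table(tab))
    scorable = [r for r in z if r.scorable]
    ranks = [r.rank_composite for r in scorable]
    values = [r.z_composite for r in scorable]
    # dense: ranks are 1..k for k distinct values, ties share a rank
    assert sorted(set(ranks)) == list(range(1, len(set(values)) + 1))
    order = sorted(zip(values, ranks))
    for (v1, r1), (v2, r2) in zip(order, order[1:]):
        assert r1 <= r2
        assert (r1 == r2) == (v1 == v2)
    assert min(r.rank_total for r in scorable) == 1


def test_singleton_stratum_flagged_unscorable():
    rows = [("a", 12, -10.0, -3.0), ("b", 12, -12.0, -5.0),
            ("lone", 16, -30.0, -9.0)]
    z = {r.candidate_id: r for r in rs.stratified_z(_records(rows))}
    assert not z["lone"].scorable
    assert "lone" not in rs.apply_cutoff(list(z.values()), cutoff=10.0)


def test_length_bias_property():
    """With a positive size bias, pooled Z-scores select only long loops;
    length-stratified Z-scores spread the selection across lengths."""
    tab = fixtures.make_score_table(
        fixtures.FixtureSpec(seed=12, library_size=100,
                             length_bias_slope=1.0))
    recs = _records_from_table(tab)
    pooled = [ScoreRecord(r.candidate_id, 0, r.avg_total,
                          r.avg_interaction, r.n_conformers) for r in recs]
    zg = rs.stratified_z(pooled)
    length_of = {r.candidate_id: r.h3_length for r in recs}
    top10_global = sorted(zg, key=lambda r: r.z_composite)[:10]
    assert min(length_of[r.candidate_id] for r in top10_global) >= 13
    zs = rs.stratified_z(recs)
    top10_strat = sorted((r for r in zs if r.scorable),
                         key=lambda r: r.z_composite)[:10]
    assert len({r.h3_length for r in top10_strat}) >= 3


def test_apply_cutoff_boundary_and_empty():
    rows = [("edge", 12, 0.0, 0.0)]
    z = rs.ZRecord("edge", 12, -1.5, -1.5, -1.5)
    assert rs.apply_cutoff([z]) == {"edge"}
    z.z_composite = -1.49
    assert rs.apply_cutoff([z]) == set()
    assert rs.apply_cutoff([]) == set()


def test_planted_binder_recovered_from_score_table():
    """A strong binder planted among size-biased decoys must survive the
    length-stratified Z cutoff."""
    tab = fixtures.make_score_table(
        fixtures.FixtureSpec(seed=13, library_size=80))
    recs = _records_from_table(tab)
    stratum = [r for r in recs if r.h3_length == 13]
    planted = ScoreRecord(
        "planted", 13,
        min(r.avg_total for r in stratum) - 8.0,
        min(r.avg_interaction for r in stratum) - 3.0, 5)
    z = rs.stratified_z(recs + [planted])
    assert "planted" in rs.apply_cutoff(z)


def _peptide(dihedrals, res_name="ALA"):
    phis = [d[0] for d in dihedrals]
    psis = [d[1] for d in dihedrals]
    N, CA, C = geometry.build_chain(len(dihedrals), phis, psis)
    atoms = []
    for i in range(len(dihedrals)):
        o = (geometry.place_carbonyl_oxygen(CA[i], C[i], N[i + 1])
             if i + 1 < len(dihedrals)
             else geometry.terminal_oxygen(N[i], CA[i], C[i]))
        for name, p in (("N", N[i]), ("CA", CA[i]), ("C", C[i]),
                        ("O", o)):
            atoms.append(model_io.AtomRecord(
                "H", str(i + 1), res_name, name, name[0],
                np.array(p, float)))
    ann = {("H", str(i + 1)): "FR" for i in range(len(dihedrals))}
    return model_io.AntibodyComplex(
        atoms, model_io.RegionAnnotation(ann), check_h3=False)


def test_ramachandran_helix_passes():
    cx = _peptide([(-57.0, -47.0)] * 8)
    ok, offenders = rs.ramachandran_check(
        cx, segment_keys=cx.residue_keys())
    assert ok and offenders == []


def test_ramachandran_flags_disallowed_residue():
    dihedrals = [(-57.0, -47.0)] * 8
    dihedrals[4] = (0.0, 0.0)
    cx = _peptide(dihedrals)
    ok, offenders = rs.ramachandran_check(
        cx, segment_keys=cx.residue_keys())
    assert not ok
    assert ("H", "5") in offenders
    # terminal residues (undefined phi or psi) are skipped, not offenders
    assert ("H", "1") not in offenders and ("H", "8") not in offenders


def test_ramachandran_missing_backbone_errors(toy):
    cx = toy.copy()
    key = cx.h3_index_map[4]
    cx.atoms = [a for a in cx.atoms
                if not ((a.chain_id, a.residue_label) == key
                        and a.atom_name == "CA")]
    cx._reindex()
    with pytest.raises(ValueError):
        rs.ramachandran_check(cx, segment_keys=[key])


def _hb_pair(separated=False):
    """Serine donor (chain S) facing an aspartate acceptor (chain G)."""
    from h3graft import residues as R
    N, CA, C = geometry.build_chain(1, [-120.0], [135.0])
    O = geometry.terminal_oxygen(N[0], CA[0], C[0])
    sc = R.build_side_chain("SER", N[0], CA[0], C[0])
    atoms = [model_io.AtomRecord("S", "1", "SER", n, n[0], p)
             for n, p in (("N", N[0]), ("CA", CA[0]), ("C", C[0]),
                          ("O", O), ("CB", sc["CB"]), ("OG", sc["OG"]))]
    u = sc["OG"] - sc["CB"]
    u /= np.linalg.norm(u)
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)
    shift = 8.0 if separated else 0.0
    od1 = sc["OG"] + (2.9 + shift) * u
    od2 = od1 + 0.9 * v
    base = od1 + u * 1.4
    for name, p in (("CG", base), ("OD1", od1), ("OD2", od2),
                    ("CB", base + u), ("CA", base + 2 * u),
                    ("N", base + 2 * u + [1.4, 0, 0]),
                    ("C", base + 2 * u + [0, 1.4, 0]),
                    ("O", base + 2 * u + [0, 2.6, 0])):
        atoms.append(model_io.AtomRecord("G", "1", "ASP", name, name[0],
                                         np.array(p, float)))
    ann = {("S", "1"): "FR", ("G", "1"): "ANTIGEN"}
    return model_io.AntibodyComplex(
        atoms, model_io.RegionAnnotation(ann), check_h3=False)


def test_hb_screen_identity_and_lost_bond():
    bound = _hb_pair()
    apart = _hb_pair(separated=True)
    ok, e_b, _f = rs.hb_screen(bound, bound)
    assert ok
    assert e_b < -0.5
    ok_lost, e_a, _f = rs.hb_screen(apart, bound)
    assert e_a > e_b
    # the candidate lost hydrogen bonding worth more than the tolerance
    assert not ok_lost
    # a candidate better than its parent always passes
    ok_gain, *_ = rs.hb_screen(bound, apart)
    assert ok_gain


def test_curation_parent_self_pass(toy):
    cur = rs.curation_checks(toy, toy)
    assert cur["shared_epitope"] and cur["salt_bridge"] \
        and cur["no_buried_charge"]
    assert cur["shared_fraction"] == 1.0


def test_curation_translated_loop_fails_shared_epitope(toy):
    moved = toy.copy()
    h3 = set(moved.h3_index_map)
    for a in moved.atoms:
        if (a.chain_id, a.residue_label) in h3:
            a.position = a.position + np.array([20.0, 0.0, 0.0])
    cur = rs.curation_checks(moved, toy)
    assert not cur["shared_epitope"]
    assert cur["reasons"]


def test_curation_salt_bridge_distance_rule(toy):
    broken = toy.copy()
    s2 = broken.h3_index_map[1]
    for a in broken.atoms:
        if ((a.chain_id, a.residue_label) == s2
                and a.atom_name in ("NE", "NH1", "NH2", "CZ")):
            a.position = a.position + np.array([0.0, 0.0, 8.0])
    cur = rs.curation_checks(broken, toy)
    assert not cur["salt_bridge"]


def test_select_cascade_and_monotonicity(toy, screen_result):
    complexes = {cid: r.best_complex
                 for cid, r in screen_result.candidates.items()}
    permissive = rs.SelectionConfig(
        z_cutoff=1e9, enable_ramachandran=False, enable_hbond=False,
        enable_curation=False)
    report, outcomes = rs.select(screen_result.zrecords, complexes, toy,
                                 permissive)
    scorable = {z.candidate_id for z in screen_result.zrecords
                if z.scorable}
    assert {o.candidate_id for o in outcomes.values()
            if o.selected} == scorable
    # report ordered by composite Z ascending
    assert list(report.z_composite) == sorted(report.z_composite)
    # relaxing thresholds never removes a selected candidate
    strict = rs.SelectionConfig()
    relaxed = rs.SelectionConfig(z_cutoff=0.0,
                                 shared_epitope_threshold=0.0,
                                 hb_tolerance=100.0)
    _rep_s, out_s = rs.select(screen_result.zrecords, complexes, toy,
                              strict)
    _rep_r, out_r = rs.select(screen_result.zrecords, complexes, toy,
                              relaxed)
    sel_s = {cid for cid, o in out_s.items() if o.selected}
    sel_r = {cid for cid, o in out_r.items() if o.selected}
    assert sel_s <= sel_r
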