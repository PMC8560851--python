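import numpy as np
import pandas as pd
import pytest

from h3graft import analysis_report as ar
from h3graft import data, scoring


def test_per_region_rmsd_self_is_zero(toy):
    tab = ar.per_region_rmsd(toy, toy).set_index("region")
    for region in ("H1", "H2", "H3", "L1", "L2", "L3", "FR", "ANTIGEN"):
        assert tab.loc[region, "rmsd_heavy"] == pytest.approx(0.0,
                                                              abs=1e-9)
        assert tab.loc[region, "brmsd_backbone"] == pytest.approx(0.0,
                                                                  abs=1e-9)


def test_per_region_rmsd_detects_known_perturbation(toy):
    model = toy.copy()
    h3 = set(model.h3_index_map)
    for a in model.atoms:
        if (a.chain_id, a.residue_label) in h3:
            a.position = a.position + np.array([2.0, 0.0, 0.0])
    tab = ar.per_region_rmsd(model, toy).set_index("region")
    assert tab.loc["FR", "brmsd_backbone"] == pytest.approx(0.0, abs=1e-6)
    assert tab.loc["H3", "brmsd_backbone"] == pytest.approx(2.0, abs=1e-6)
    assert tab.loc["H3", "rmsd_heavy"] == pytest.approx(2.0, abs=1e-6)
    # the framework fit is shared: symmetric comparison gives the same BRMSD
    rev = ar.per_region_rmsd(toy, model).set_index("region")
    assert rev.loc["H3", "brmsd_backbone"] == pytest.approx(2.0, abs=1e-6)


def test_per_region_rmsd_antigen_motion_localized(toy):
    model = toy.copy()
    for a in model.atoms:
        if model.region(a.chain_id, a.residue_label) == "ANTIGEN":
            a.position = a.position + np.array([0.0, 3.0, 0.0])
    tab = ar.per_region_rmsd(model, toy).set_index("region")
    assert tab.loc["ANTIGEN", "brmsd_backbone"] == pytest.approx(3.0,
                                                                 abs=1e-6)
    for region in ("H1", "H2", "H3", "L1", "L2", "L3", "FR"):
        assert tab.loc[region, "rmsd_heavy"] == pytest.approx(0.0,
                                                              abs=1e-9)


def test_per_region_rmsd_refuses_unlike_h3_lengths(toy, templates_mid):
    from h3graft import grafting
    t12 = next(t for t in templates_mid
               if t.h3_length == 12 and t.cluster_id == "c1")
    model = grafting.graft_stem(toy, t12, "ARGRKYSSSFDY").complex
    tab = ar.per_region_rmsd(model, toy).set_index("region")
    assert np.isnan(tab.loc["H3", "rmsd_heavy"])
    assert tab.loc["ANTIGEN", "rmsd_heavy"] == pytest.approx(0.0,
                                                             abs=1e-9)


def test_identity_similarity_minimal_h3_anchor():
    ident, sim = ar.seq_identity_similarity(data.MINH3_H3, data.PARENT_H3)
    assert (ident, sim) == (100, 100)
    assert ar.seq_identity_similarity("SRWGMDY", "SRWGMDY") == (100, 100)
    ident, _sim = ar.seq_identity_similarity("AAAA", "GGGG")
    assert ident == 0


def test_kd_fold_table():
    records = [("minH3", 16000.0), ("parent", 100.0), ("13_0346", 80.0)]
    rows = {r.candidate_id: r
            for r in ar.kd_fold_table(records, "parent", "minH3")}
    assert rows["13_0346"].fold_vs_baseline == pytest.approx(200.0)
    assert rows["parent"].fold_vs_baseline == pytest.approx(160.0)
    assert rows["parent"].fold_vs_parent == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ar.kd_fold_table([("a", -1.0), ("parent", 1.0), ("minH3", 2.0)],
                         "parent", "minH3")


def test_kd_folds_unit_invariant():
    records = [("minH3", 16000.0), ("parent", 100.0), ("x", 80.0)]
    nm = ar.kd_fold_table(records, "parent", "minH3")
    um = ar.kd_fold_table([(c, v / 1000.0) for c, v in records],
                          "parent", "minH3")
    for a, b in zip(nm, um):
        assert a.fold_vs_parent == pytest.approx(b.fold_vs_parent)
        assert a.fold_vs_baseline == pytest.approx(b.fold_vs_baseline)


def test_favorable_count_boundaries():
    records = [("minH3", 100.0), ("parent", 10.0), ("a", 99.0),
               ("b", 100.0), ("c", 101.0)]
    assert ar.favorable_h3_count(records, "minH3", parent_id="parent") == 1
    worse = [("minH3", 100.0), ("a", 200.0), ("b", 300.0)]
    assert ar.favorable_h3_count(worse, "minH3") == 0


def test_panel_counts():
    kd = data.kd_panel()
    records = list(zip(kd.id, kd.kd_nM))
    assert ar.favorable_h3_count(records, data.MINH3_ID,
                                 parent_id=data.PARENT_ID) == 13
    assert ar.affinity_loss_count(records, data.PARENT_ID,
                                  baseline_id=data.MINH3_ID) == 3


def test_retrospective_identity_graft(toy):
    total, inter, z, info = ar.retrospective_graft(toy, toy)
    ref_total, ref_inter = scoring.single_structure_scores(toy)
    assert total == pytest.approx(ref_total, abs=1e-6)
    assert inter == pytest.approx(ref_inter, abs=1e-6)
    assert np.isnan(z)


def test_retrospective_z_from_stored_medians(toy):
    med = pd.DataFrame({
        "length": [12, 13],
        "median_total": [0.0, -100.0], "scale_total": [1.0, 10.0],
        "median_interaction": [0.0, -5.0], "scale_interaction": [1.0, 2.0],
    })
    total, inter, z, _info = ar.retrospective_graft(toy, toy, med)
    expect = ((total + 100.0) / 10.0 + (inter + 5.0) / 2.0) / 2.0
    assert z == pytest.approx(expect, abs=1e-9)


def test_retrospective_replaces_clashing_side_chain(toy):
    parent_mod = toy.copy()
    h3 = set(parent_mod.h3_index_map)
    loop_xyz = np.array([a.position for a in parent_mod.atoms
                         if (a.chain_id, a.residue_label) in h3])
    centroid = loop_xyz.mean(axis=0)
    # pick an environment residue with a side chain and push one side-chain
    # atom into the loop
    target = None
    for key in parent_mod.residue_keys():
        if key in h3 or key[0] != "H":
            continue
        names = [n for n in parent_mod.residue_atom_names(*key)
                 if n not in ("N", "CA", "C", "O")]
        if names:
            d = np.linalg.norm(
                parent_mod.get_atom(*key, names[0]).position - centroid)
            if target is None or d < target[0]:
                target = (d, key, names[0])
    _d, key, name = target
    parent_mod.get_atom(*key, name).position = centroid
    _t, _i, _z, info = ar.retrospective_graft(parent_mod, toy)
    assert key in info["replaced_side_chains"]
    out = info["complex"]
    src = toy.get_atom(*key, name)
    assert np.allclose(out.get_atom(*key, name).position, src.position,
                       atol=1e-6)
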