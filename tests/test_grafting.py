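import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from h3graft import fixtures, geometry, grafting, model_io, stem_library
from h3graft import residues as rescfg
from h3graft.grafting import graft_stem, place_side_chains, regularize, \
    superpose


def test_superpose_identity():
    pts = np.random.default_rng(0).normal(size=(8, 3))
    tr, rmsd = superpose(pts, pts)
    assert rmsd < 1e-9
    assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)


def test_superpose_recovers_known_transform():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(12, 3)) * 4
    R = Rotation.random(random_state=7).as_matrix()
    t = np.array([3.0, -2.0, 9.0])
    Q = P @ R.T + t
    tr, rmsd = superpose(P, Q)
    assert rmsd < 1e-9
    assert np.allclose(tr.rotation, R, atol=1e-6)
    assert np.allclose(tr.apply(P), Q, atol=1e-6)


def test_superpose_agrees_with_scipy_oracle():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(20, 3))
    Q = rng.normal(size=(20, 3))
    tr, rmsd = superpose(P, Q)
    rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert np.allclose(tr.rotation, rot.as_matrix(), atol=1e-8)
    assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-8)


def test_superpose_mirror_returns_proper_rotation():
    rng = np.random.default_rng(3)
    P = rng.normal(size=(10, 3))
    Q = P.copy()
    Q[:, 0] *= -1  # mirror image
    tr, rmsd = superpose(P, Q)
    assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1
    # no proper rotation can beat the returned fit (random-search oracle)
    for k in range(100):
        R = Rotation.random(random_state=k).as_matrix()
        moved = (P - P.mean(0)) @ R.T + Q.mean(0)
        alt = np.sqrt(((moved - Q) ** 2).sum(axis=1).mean())
        assert alt >= rmsd - 1e-9


def test_superpose_degenerate_inputs():
    with pytest.raises(ValueError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError):
        superpose(line, line + 1)


@given(st.integers(0, 500))
def test_superpose_rmsd_invariant_under_global_motion(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(6, 3))
    Q = rng.normal(size=(6, 3))
    _tr, rmsd0 = superpose(P, Q)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(size=3) * 5
    _tr, rmsd1 = superpose(P @ R.T + t, Q @ R.T + t)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)


def test_self_graft_is_identity(toy, parent_graft):
    region = set(toy.graft_flank) | set(toy.h3_index_map)
    pa = np.array([a.position for a in toy.atoms
                   if (a.chain_id, a.residue_label) in region])
    pb = np.array([a.position for a in parent_graft.complex.atoms
                   if (a.chain_id, a.residue_label) in region])
    assert pa.shape == pb.shape
    assert np.abs(pa - pb).max() < 1e-3
    assert parent_graft.anchor_rmsd < 1e-9


def test_graft_changes_loop_length_only(toy, stem_c1):
    t16 = stem_library.build_template(stem_c1, 16)
    res = graft_stem(toy, t16, "ARGGAVAGTGVYYFDY")
    assert res.complex.h3_length == 16
    assert res.complex.h3_sequence() == "ARGGAVAGTGVYYFDY"
    # everything outside the graft region is bitwise untouched
    region = set(toy.graft_flank) | set(toy.h3_index_map)
    outside_a = [a for a in toy.atoms
                 if (a.chain_id, a.residue_label) not in region]
    region_b = set(res.complex.graft_flank) | set(res.complex.h3_index_map)
    outside_b = [a for a in res.complex.atoms
                 if (a.chain_id, a.residue_label) not in region_b]
    assert len(outside_a) == len(outside_b)
    for x, y in zip(outside_a, outside_b):
        assert (x.position == y.position).all()
        assert x.atom_name == y.atom_name


def test_graft_length_mismatch_errors(toy, stem_c1):
    with pytest.raises(ValueError):
        graft_stem(toy, stem_c1, "SRWGMDY")


def _isolated_residue(res_name):
    N, CA, C = geometry.build_chain(1, [-120.0], [135.0])
    O = geometry.terminal_oxygen(N[0], CA[0], C[0])
    atoms = [model_io.AtomRecord("Z", "1", res_name, n, n[0], p)
             for n, p in (("N", N[0]), ("CA", CA[0]), ("C", C[0]),
                          ("O", O))]
    return model_io.AntibodyComplex(
        atoms, model_io.RegionAnnotation({("Z", "1"): "FR"}),
        check_h3=False)


def test_place_side_chains_gly_ala():
    gly = place_side_chains(_isolated_residue("GLY"), [("Z", "1")])
    assert gly.residue_atom_names("Z", "1") == ["N", "CA", "C", "O"]
    ala = place_side_chains(_isolated_residue("ALA"), [("Z", "1")])
    extra = set(ala.residue_atom_names("Z", "1")) - {"N", "CA", "C", "O"}
    assert extra == {"CB"}
    cb = ala.get_atom("Z", "1", "CB").position
    ca = ala.get_atom("Z", "1", "CA").position
    assert 1.45 < np.linalg.norm(cb - ca) < 1.60


def test_place_side_chains_leu_open_space_exhaustive():
    cx = place_side_chains(_isolated_residue("LEU"), [("Z", "1")])
    placed = {n: cx.get_atom("Z", "1", n).position
              for n in ("CB", "CG", "CD1", "CD2")}
    # zero clashes in open space, so the most frequent rotamer is chosen;
    # exhaustive enumeration finds no lower-clash rotamer
    n = cx.get_atom("Z", "1", "N").position
    ca = cx.get_atom("Z", "1", "CA").position
    c = cx.get_atom("Z", "1", "C").position
    expect = rescfg.build_side_chain("LEU", n, ca, c,
                                     rescfg.ROTAMERS["LEU"][0])
    for name in placed:
        assert np.allclose(placed[name], expect[name], atol=1e-9)


def test_place_side_chains_unknown_residue(toy):
    cx = toy.copy()
    for a in cx.atoms:
        if (a.chain_id, a.residue_label) == ("L", "1"):
            a.residue_name = "XXX"
    with pytest.raises(ValueError):
        place_side_chains(cx, [("L", "1")])


def test_regularize_stationary_after_convergence(parent_graft):
    # at the convergence tolerance (max gradient 0.1) a repeated pass
    # moves atoms by no more than the tolerance scale
    loop = parent_graft.complex.h3_index_map
    once = regularize(parent_graft.complex, loop)
    twice = regularize(once, loop)
    assert np.abs(once.coords() - twice.coords()).max() < 0.1


def test_regularize_restores_stretched_bond(parent_graft):
    cx = parent_graft.complex.copy()
    loop = cx.h3_index_map
    k1, k2 = loop[4], loop[5]
    c = cx.get_atom(*k1, "C")
    n = cx.get_atom(*k2, "N")
    u = (n.position - c.position)
    u /= np.linalg.norm(u)
    n.position = c.position + 1.8 * u
    out = regularize(cx, loop)
    d = np.linalg.norm(out.get_atom(*k2, "N").position
                       - out.get_atom(*k1, "C").position)
    assert abs(d - 1.33) < 0.05


def test_regularize_fixes_environment(parent_graft):
    cx = parent_graft.complex
    loop = set(cx.h3_index_map)
    out = regularize(cx, cx.h3_index_map)
    for a, b in zip(cx.atoms, out.atoms):
        if (a.chain_id, a.residue_label) not in loop:
            assert (a.position == b.position).all()
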