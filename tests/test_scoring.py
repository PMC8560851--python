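import numpy as np
import pytest
from hypothesis import given, strategies as st

from h3graft import model_io, scoring
from h3graft import loop_sampling as ls
from h3graft.scoring import (SIEConfig, boltzmann_average,
                             interaction_components, interaction_energy,
                             score_ensemble, shrake_rupley, total_energy)


# -- Boltzmann averaging ----------------------------------------------------


def test_boltzmann_single_and_uniform():
    assert boltzmann_average([7.5], [3.0], 1.0) == 7.5
    assert boltzmann_average([-10.0, -20.0], [5.0, 5.0], 1.0) == -15.0


def test_boltzmann_temperature_limits():
    values = [4.0, -2.0, 10.0]
    energies = [1.0, 0.2, 3.0]
    cold = boltzmann_average(values, energies, 1e-6)
    assert cold == pytest.approx(values[int(np.argmin(energies))])
    hot = boltzmann_average(values, energies, 1e6)
    assert hot == pytest.approx(np.mean(values), rel=1e-4)


def test_boltzmann_two_value_hand_arithmetic():
    v = [3.0, -1.0]
    e = [0.0, 1.5]
    w2 = np.exp(-1.5)
    expect = (v[0] + v[1] * w2) / (1 + w2)
    assert boltzmann_average(v, e, 1.0) == pytest.approx(expect, abs=1e-12)


@given(st.floats(-50, 50), st.integers(0, 200))
def test_boltzmann_shift_invariance(shift, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=5)
    e = rng.normal(size=5)
    a = boltzmann_average(v, e, 1.3)
    b = boltzmann_average(v, e + shift, 1.3)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_boltzmann_input_validation():
    with pytest.raises(ValueError):
        boltzmann_average([], [], 1.0)
    with pytest.raises(ValueError):
        boltzmann_average([1.0], [1.0], 0.0)
    with pytest.raises(ValueError):
        boltzmann_average([1.0, 2.0], [1.0], 1.0)


# -- total energy track -----------------------------------------------------


def _without_antigen(cx):
    atoms = [a.copy() for a in cx.atoms
             if cx.region(a.chain_id, a.residue_label) != "ANTIGEN"]
    ann = {k: v for k, v in cx.annotation.region_of.items()
           if v != "ANTIGEN"}
    return model_io.AntibodyComplex(atoms, model_io.RegionAnnotation(ann))


def test_total_energy_deterministic_and_separable(toy):
    assert total_energy(toy) == total_energy(toy.copy())
    far = toy.copy()
    for a in far.atoms:
        if far.region(a.chain_id, a.residue_label) == "ANTIGEN":
            a.position = a.position + np.array([500.0, 0.0, 0.0])
    isolated = _without_antigen(toy)
    assert total_energy(far) == pytest.approx(total_energy(isolated),
                                              abs=1e-9)


def test_total_energy_penalizes_overlap(toy):
    e0 = total_energy(toy)
    clashed = toy.copy()
    key = clashed.h3_index_map[5]
    target = clashed.get_atom("H", "85", "CA").position
    clashed.get_atom(*key, "CA").position = target + np.array([1.5, 0, 0])
    # moving a loop atom onto the framework must raise the energy
    assert total_energy(clashed) > e0


# -- interaction energy track ----------------------------------------------


def test_interaction_separated_equals_constant(toy):
    far = toy.copy()
    for a in far.atoms:
        if far.region(a.chain_id, a.residue_label) == "ANTIGEN":
            a.position = a.position + np.array([500.0, 0.0, 0.0])
    cfg = SIEConfig()
    assert interaction_energy(far, cfg) == pytest.approx(cfg.constant,
                                                         abs=1e-9)


def test_interaction_linearity_in_alpha(toy):
    comp = interaction_components(toy)
    cfg = SIEConfig()
    expected = cfg.alpha * (comp["vdw"] + comp["coulomb"]
                            + comp["reaction_field"]
                            + cfg.gamma * comp["dsasa"]) + cfg.constant
    assert comp["score"] == pytest.approx(expected, abs=1e-9)
    doubled = SIEConfig(alpha=2 * cfg.alpha)
    s2 = interaction_energy(toy, doubled)
    assert s2 - cfg.constant == pytest.approx(
        2 * (comp["score"] - cfg.constant), abs=1e-6)


def test_interaction_symmetric_under_body_swap(toy):
    swapped_ann = {}
    for k, v in toy.annotation.region_of.items():
        swapped_ann[k] = "FR" if v == "ANTIGEN" else "ANTIGEN"
    swapped = model_io.AntibodyComplex(
        [a.copy() for a in toy.atoms],
        model_io.RegionAnnotation(swapped_ann), check_h3=False)
    cfg = SIEConfig(constant=0.0)
    plain = model_io.AntibodyComplex(
        [a.copy() for a in toy.atoms],
        model_io.RegionAnnotation(dict(toy.annotation.region_of)),
        check_h3=False)
    assert interaction_energy(swapped, cfg) == pytest.approx(
        interaction_energy(plain, cfg), abs=1e-6)


def test_interaction_requires_antigen(toy):
    with pytest.raises(ValueError):
        interaction_energy(_without_antigen(toy))


def test_sasa_two_sphere_analytic_oracle():
    r1, r2, d = 1.7, 1.52, 2.0
    probe = 1.4
    R1, R2 = r1 + probe, r2 + probe
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    areas = shrake_rupley(coords, np.array([r1, r2]), probe=probe,
                          n_points=2000)
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    expect1 = 4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1
    expect2 = 4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2
    assert areas[0] == pytest.approx(expect1, rel=0.02)
    assert areas[1] == pytest.approx(expect2, rel=0.02)


def test_sasa_isolated_sphere():
    areas = shrake_rupley(np.zeros((1, 3)), np.array([1.7]))
    assert areas[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)


# -- ensemble scoring -------------------------------------------------------


def _sub_ensemble(base, confs):
    out = ls.replace_stage(base, [c.copy() for c in confs], base.stage)
    return out


def test_score_ensemble_single_conformer(staged):
    final = staged["final"]
    one = _sub_ensemble(final, final.conformations[:1])
    scorer = scoring.ConformerScorer(one)
    rec = score_ensemble(one, kT=1.0, scorer=scorer)
    assert rec.n_conformers == 1
    assert rec.avg_total == pytest.approx(
        scorer.total_energy(one.conformations[0]))
    assert rec.avg_interaction == pytest.approx(
        scorer.interaction_energy(one.conformations[0]), abs=1e-6)


def test_score_ensemble_bounds_permutation_and_arithmetic(staged):
    final = staged["final"]
    confs = final.conformations[:2]
    if len(confs) < 2:
        confs = final.conformations * 2
    ens = _sub_ensemble(final, confs)
    rec = score_ensemble(ens, kT=1.0)
    totals = [c.total_energy for c in ens.conformations]
    assert min(totals) - 1e-9 <= rec.avg_total <= max(totals) + 1e-9
    # permutation invariance
    rev = _sub_ensemble(final, confs[::-1])
    rec2 = score_ensemble(rev, kT=1.0)
    assert rec2.avg_total == pytest.approx(rec.avg_total, abs=1e-9)
    assert rec2.avg_interaction == pytest.approx(rec.avg_interaction,
                                                 abs=1e-6)
    # two-conformer manual arithmetic oracle
    scorer = scoring.ConformerScorer(ens)
    t = [scorer.total_energy(c) for c in ens.conformations]
    i = [scorer.interaction_energy(c) for c in ens.conformations]
    w = np.exp(-(np.array(t) - min(t)))
    assert rec.avg_total == pytest.approx(float((t @ w) / w.sum()),
                                          abs=1e-9)
    assert rec.avg_interaction == pytest.approx(float((i @ w) / w.sum()),
                                                abs=1e-6)


def test_score_ensemble_empty_errors(staged):
    final = staged["final"]
    with pytest.raises(ValueError):
        score_ensemble(_sub_ensemble(final, []))
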