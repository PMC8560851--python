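"""Two-track conformer scoring and Boltzmann-weighted ensemble averages.

The *total energy* track combines intra-loop bonded strain, loop-self and
loop-environment Lennard-Jones, screened Coulomb (eps = 4r), a hydrogen-bond
well and a backbone-propensity term; it plays the role of an all-atom total
energy including internal strain.  The *interaction energy* track is an
interaction-only, solvated-interaction-energy-style functional:

    E_int = alpha * (E_vdW + E_Coul(Din) + E_RF + gamma * dSASA) + C

with a Shrake-Rupley accessible-surface computation for the buried-area
terms.  Coefficients follow the published SIE parameterization lineage and
are configuration, not contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield, rama
from . import loop_sampling as ls
from . import residues as rescfg

RAMA_WEIGHT = 1.0
INTERFACE_CUTOFF = 7.0   # Å: atoms considered for burial bookkeeping
PAIR_CUTOFF = 12.0       # Å: intermolecular pair terms


@dataclass
class SIEConfig:
    alpha: float = 0.1048
    din: float = 2.25
    gamma: float = 0.0129     # kcal/mol/Å^2
    constant: float = -2.89   # kcal/mol
    rf_beta: float = 0.02     # kcal/mol/Å^2 per |charge|


@dataclass
class ScoreRecord:
    candidate_id: str
    h3_length: int
    avg_total: float
    avg_interaction: float
    n_conformers: int


# -- accessible surface -----------------------------------------------------


def _sphere_points(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


_SPHERE_CACHE = {}


def shrake_rupley(coords, radii, probe=1.4, n_points=100, subset=None):
    """Per-atom solvent-accessible surface areas (Å^2).

    If ``subset`` is given, only those atom indices are evaluated (the
    returned array still has one entry per subset atom, in order).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if n_points not in _SPHERE_CACHE:
        _SPHERE_CACHE[n_points] = _sphere_points(n_points)
    sphere = _SPHERE_CACHE[n_points]
    R = radii + probe
    tree = cKDTree(coords)
    idxs = np.arange(len(coords)) if subset is None else np.asarray(subset,
                                                                    int)
    areas = np.zeros(len(idxs))
    rmax = R.max() if len(R) else 0.0
    for k, i in enumerate(idxs):
        js = [j for j in tree.query_ball_point(coords[i], R[i] + rmax)
              if j != i]
        pts = coords[i] + R[i] * sphere
        if js:
            js = np.asarray(js, int)
            close = js[np.linalg.norm(coords[js] - coords[i], axis=1)
                       < R[i] + R[js]]
            if len(close):
                d = np.linalg.norm(pts[:, None] - coords[close][None],
                                   axis=2)
                exposed = ~(d < R[close][None]).any(axis=1)
            else:
                exposed = np.ones(len(pts), bool)
        else:
            exposed = np.ones(len(pts), bool)
        areas[k] = 4 * np.pi * R[i] ** 2 * exposed.mean()
    return areas


# -- total energy track -----------------------------------------------------


def total_energy(cx, loop_keys=None) -> float:
    """Total-energy score of a complex around its H3 loop (or an explicit
    residue-key region): bonded strain + nonbonded + backbone propensity."""
    keys = list(loop_keys) if loop_keys is not None else cx.h3_index_map
    system = forcefield.RegionSystem(cx, keys, nonbonded="ff")
    e = system.energy_at_input()
    return e + _rama_term(cx)


def _rama_term(cx) -> float:
    dih = ls.measure_dihedrals(cx)
    e = 0.0
    for (key, row) in zip(cx.h3_index_map, dih):
        if np.isnan(row[0]) or np.isnan(row[1]):
            continue
        e -= RAMA_WEIGHT * rama.log_propensity(row[0], row[1],
                                               cx.residue_name(*key))
    return e


# -- interaction energy track ----------------------------------------------


def _partition(cx):
    ab_idx, ag_idx = [], []
    for i, a in enumerate(cx.atoms):
        region = cx.region(a.chain_id, a.residue_label)
        if region == "ANTIGEN":
            ag_idx.append(i)
        elif region is not None:
            ab_idx.append(i)
    if not ag_idx:
        raise ValueError("annotation lacks an ANTIGEN region")
    return np.array(ab_idx, int), np.array(ag_idx, int)


def interaction_components(cx, config: SIEConfig = None,
                           n_sphere_points=100) -> dict:
    """Component breakdown of the interaction-energy functional."""
    config = config or SIEConfig()
    ab_idx, ag_idx = _partition(cx)
    xyz = cx.coords()
    radii = np.array([rescfg.radius_of(a.element) for a in cx.atoms])
    charge = np.array([rescfg.charge_of(a.residue_name, a.atom_name)
                       for a in cx.atoms])
    A, B = xyz[ab_idx], xyz[ag_idx]
    tree_b = cKDTree(B)

    # intermolecular pair terms
    e_vdw = e_coul = 0.0
    near = tree_b.query_ball_point(A, PAIR_CUTOFF)
    for ia, js in zip(ab_idx, near):
        if not js:
            continue
        js_g = ag_idx[np.asarray(js, int)]
        d = np.linalg.norm(xyz[js_g] - xyz[ia], axis=1)
        d = np.maximum(d, 0.8)
        rmin = radii[ia] + radii[js_g]
        s6 = (rmin / d) ** 6
        e_vdw += float(np.sum(np.clip(
            forcefield.LJ_EPS * (s6 ** 2 - 2 * s6), None, 10.0)))
        e_coul += float(np.sum(
            forcefield.COULOMB_CONST * charge[ia] * charge[js_g]
            / (config.din * d)))

    # burial bookkeeping on interface atoms only
    tree_a = cKDTree(A)
    near_ab = tree_b.query_ball_point(A, INTERFACE_CUTOFF)
    iface_a = ab_idx[[k for k, js in enumerate(near_ab) if js]]
    near_ba = tree_a.query_ball_point(B, INTERFACE_CUTOFF)
    iface_b = ag_idx[[k for k, js in enumerate(near_ba) if js]]
    iface = np.concatenate([iface_a, iface_b]).astype(int)
    if len(iface):
        sasa_complex = shrake_rupley(xyz, radii, subset=iface,
                                     n_points=n_sphere_points)
        # each body alone
        sasa_alone = np.empty(len(iface))
        pos_a = {int(i): k for k, i in enumerate(ab_idx)}
        sel_a = [k for k, i in enumerate(iface) if int(i) in pos_a]
        sel_b = [k for k, i in enumerate(iface) if int(i) not in pos_a]
        if sel_a:
            ra = radii[ab_idx]
            sasa_alone[sel_a] = shrake_rupley(
                A, ra, subset=[pos_a[int(iface[k])] for k in sel_a],
                n_points=n_sphere_points)
        pos_b = {int(i): k for k, i in enumerate(ag_idx)}
        if sel_b:
            rb = radii[ag_idx]
            sasa_alone[sel_b] = shrake_rupley(
                B, rb, subset=[pos_b[int(iface[k])] for k in sel_b],
                n_points=n_sphere_points)
        buried = np.maximum(sasa_alone - sasa_complex, 0.0)
        dsasa = -float(buried.sum())
        polar = np.abs(charge[iface]) > 0.25
        e_rf = config.rf_beta * float(
            (np.abs(charge[iface]) * buried)[polar].sum())
    else:
        dsasa = 0.0
        e_rf = 0.0

    score = config.alpha * (e_vdw + e_coul + e_rf
                            + config.gamma * dsasa) + config.constant
    return {"vdw": e_vdw, "coulomb": e_coul, "reaction_field": e_rf,
            "dsasa": dsasa, "score": score}


def interaction_energy(cx, config: SIEConfig = None) -> float:
    """Interaction-only binding score over the antibody/antigen partition."""
    return interaction_components(cx, config)["score"]


# -- Boltzmann averaging ----------------------------------------------------


def boltzmann_average(values, weight_energies, kT: float) -> float:
    """Sum(v_i w_i) / Sum(w_i) with w_i ∝ exp(-(E_i - E_min)/kT)."""
    values = np.asarray(values, float)
    energies = np.asarray(weight_energies, float)
    if len(values) == 0:
        raise ValueError("empty input to boltzmann_average")
    if len(values) != len(energies):
        raise ValueError("values and weight energies differ in length")
    if not kT > 0:
        raise ValueError("kT must be positive")
    w = np.exp(-(energies - energies.min()) / kT)
    return float(np.sum(values * w) / np.sum(w))


# -- ensemble scoring -------------------------------------------------------


class ConformerScorer:
    """Scores conformations of one ensemble, caching environment state."""

    def __init__(self, ens, sie_config: SIEConfig = None,
                 prescore_restraint: float = 1.0,
                 prescore_iters: int = 40):
        self.ens = ens
        self.sie_config = sie_config or SIEConfig()
        self.prescore_restraint = prescore_restraint
        self.prescore_iters = prescore_iters

    def total_energy(self, conf) -> float:
        cx = ls.apply_conf(self.ens.environment_of(conf), conf.coords)
        return total_energy(cx)

    def minimized_complex(self, conf):
        """Pre-scoring minimization: H3 heavy atoms restrained harmonically
        (1 kcal/mol/Å^2 by default), environment fixed."""
        cx = ls.apply_conf(self.ens.environment_of(conf), conf.coords)
        system = forcefield.RegionSystem(
            cx, cx.h3_index_map, nonbonded="ff",
            restraint_backbone=self.prescore_restraint,
            restraint_heavy=self.prescore_restraint)
        coords, _e0, _e1 = system.run(max_iter=self.prescore_iters,
                                      gtol=0.05)
        return forcefield.apply_mobile_coords(cx, system, coords)

    def interaction_energy(self, conf) -> float:
        return interaction_energy(self.minimized_complex(conf),
                                  self.sie_config)


def score_ensemble(ens, kT: float = 1.0, sie_config: SIEConfig = None,
                   scorer: ConformerScorer = None) -> ScoreRecord:
    """Boltzmann-averaged two-track scores for a final-stage ensemble.

    The same weight vector — derived from the total-energy track — is used
    for both averages; the interaction track is evaluated on restrained-
    minimized conformers.
    """
    if not ens.conformations:
        raise ValueError("cannot score an empty ensemble")
    scorer = scorer or ConformerScorer(ens, sie_config)
    totals = []
    inters = []
    for conf in ens.conformations:
        if conf.total_energy is None:
            conf.total_energy = scorer.total_energy(conf)
        totals.append(conf.total_energy)
        inters.append(scorer.interaction_energy(conf))
    avg_total = boltzmann_average(totals, totals, kT)
    avg_inter = boltzmann_average(inters, totals, kT)
    return ScoreRecord(ens.candidate_id, len(ens.loop_keys),
                       avg_total, avg_inter, len(ens.conformations))


def single_structure_scores(cx, sie_config: SIEConfig = None,
                            restraint: float = 1.0, max_iter: int = 400):
    """(total, interaction) for one complex: the loop is minimized in a
    fixed environment with restrained heavy atoms, then both tracks are
    evaluated on the minimized coordinates."""
    system = forcefield.RegionSystem(
        cx, cx.h3_index_map, nonbonded="ff",
        restraint_backbone=restraint, restraint_heavy=restraint)
    coords, _e0, _e1 = system.run(max_iter=max_iter, gtol=0.01)
    out = forcefield.apply_mobile_coords(cx, system, coords)
    return total_energy(out), interaction_energy(out, sie_config)
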