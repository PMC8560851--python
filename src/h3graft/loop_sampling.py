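"""Hierarchical H3 loop ensemble generation.

Stages mirror the screening protocol: propensity-guided tip sampling with
CCD closure (5000 samples at full scale), statistical-potential rescoring of
the first 1000 and retention of the best 250, an antigen-contact filter at
the median contact count of the reference population, per-conformer
minimization, retention of the top 100 per stem, and a two-round
perturb-and-reclose refinement with a 5 kcal/mol retention window on the
total-energy score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield, geometry, model_io, rama
from . import residues as rescfg

CLOSURE_TOL = 0.5       # Å
HARD_CLASH_FACTOR = 0.55
CONTACT_CUTOFF = 4.5    # Å
STAT_CUTOFF = 8.0       # Å
STAT_BIN = 0.5          # Å

STAGES = ("initial", "culled", "minimized", "refined", "final")


@dataclass
class TipWindow:
    start: int = 0
    end: int = 0
    empty: bool = False

    def __len__(self):
        return 0 if self.empty else self.end - self.start + 1


def tip_window(h3_length: int) -> TipWindow:
    """Loop-tip definition by H3 length (1-based, inclusive, s[1] ↔ H93).

    L=6: whole loop; L=7: no tip (stem clusters fix the conformation);
    L=8: s[2..L-2]; L=9: s[3..L-2]; L>=10: s[3..L-3] — always at least a
    5-residue search window for L >= 8.
    """
    L = h3_length
    if L < 6:
        raise ValueError("H3 length must be >= 6")
    if L == 6:
        return TipWindow(1, L)
    if L == 7:
        return TipWindow(empty=True)
    if L == 8:
        return TipWindow(2, L - 2)
    if L == 9:
        return TipWindow(3, L - 2)
    return TipWindow(3, L - 3)


@dataclass
class LoopConformation:
    coords: np.ndarray              # (n_loop_atoms, 3)
    dihedrals: np.ndarray           # (L, 3) phi/psi/omega, degrees
    closure_gap: float
    stem_of_origin: str
    stat_energy: float = None
    total_energy: float = None
    min_energy: float = None
    contact_count: int = None

    def copy(self):
        return replace(self, coords=np.array(self.coords, float),
                       dihedrals=np.array(self.dihedrals, float))


@dataclass
class LoopEnsemble:
    candidate_id: str
    sequence: str
    loop_keys: list
    atom_names: list                # [(res_pos, atom_name), ...]
    environments: dict              # stem cluster_id -> AntibodyComplex
    conformations: list
    stage: str = "initial"
    meta: dict = field(default_factory=dict)

    def environment_of(self, conf) -> "model_io.AntibodyComplex":
        return self.environments[conf.stem_of_origin]

    @property
    def environment(self):
        if len(self.environments) != 1:
            raise ValueError("ensemble spans multiple stem environments")
        return next(iter(self.environments.values()))


# -- helpers ----------------------------------------------------------------


def loop_atom_layout(cx):
    """(keys, [(res_pos, atom_name)], atom indices) for the H3 loop."""
    keys = cx.h3_index_map
    names, idx = [], []
    for pos, key in enumerate(keys):
        for name in cx.residue_atom_names(*key):
            names.append((pos, name))
            idx.append(cx.atom_index(*key, name))
    return keys, names, np.array(idx, int)


def loop_coords(cx):
    _keys, _names, idx = loop_atom_layout(cx)
    return cx.coords()[idx]


def apply_conf(cx, conf_coords):
    """Copy of the complex with the H3 loop atoms set to conf coordinates."""
    _keys, _names, idx = loop_atom_layout(cx)
    out = cx.copy()
    for i, p in zip(idx, conf_coords):
        out.atoms[int(i)].position = np.array(p, float)
    return out


def measure_dihedrals(cx):
    """(phi, psi, omega) per H3 loop residue (degrees; NaN where undefined)."""
    keys = cx.h3_index_map
    chain_keys = cx.chain_residues(cx.h3_chain)
    out = np.full((len(keys), 3), np.nan)
    for i, key in enumerate(keys):
        pos = chain_keys.index(key)
        prev_key = chain_keys[pos - 1] if pos > 0 else None
        next_key = chain_keys[pos + 1] if pos + 1 < len(chain_keys) else None
        N = cx.get_atom(*key, "N").position
        CA = cx.get_atom(*key, "CA").position
        C = cx.get_atom(*key, "C").position
        if prev_key and cx.has_atom(*prev_key, "C"):
            out[i, 0] = np.rad2deg(geometry.dihedral(
                cx.get_atom(*prev_key, "C").position, N, CA, C))
            if cx.has_atom(*prev_key, "CA"):
                out[i, 2] = np.rad2deg(geometry.dihedral(
                    cx.get_atom(*prev_key, "CA").position,
                    cx.get_atom(*prev_key, "C").position, N, CA))
        if next_key and cx.has_atom(*next_key, "N"):
            out[i, 1] = np.rad2deg(geometry.dihedral(
                N, CA, C, cx.get_atom(*next_key, "N").position))
    return out


# -- sampling ---------------------------------------------------------------


def sample_tip(graft, n_samples: int = 5000, seed: int = 0,
               closure_tol: float = CLOSURE_TOL,
               retry_factor: int = 20) -> LoopEnsemble:
    """Generate the initial tip-conformation ensemble for one graft."""
    cx = graft.complex
    L = cx.h3_length
    keys, atom_names, loop_idx = loop_atom_layout(cx)
    base_coords = cx.coords()[loop_idx]
    window = tip_window(L)
    base_dih = measure_dihedrals(cx)

    if window.empty:
        conf = LoopConformation(base_coords.copy(), base_dih, 0.0,
                                graft.stem_of_origin)
        return LoopEnsemble(
            candidate_id=cx.h3_sequence(), sequence=cx.h3_sequence(),
            loop_keys=keys, atom_names=atom_names,
            environments={graft.stem_of_origin: cx},
            conformations=[conf], stage="initial")

    sampler = _TipSampler(cx, window, graft.stem_of_origin)
    rng = np.random.default_rng(seed)
    # the grafted conformation itself is the first member of the ensemble
    confs = [LoopConformation(base_coords.copy(), base_dih, 0.0,
                              graft.stem_of_origin)]
    attempts = 1
    budget = max(n_samples * retry_factor, 200)
    while len(confs) < n_samples and attempts < budget:
        attempts += 1
        conf = sampler.sample(rng, closure_tol)
        if conf is not None:
            confs.append(conf)
    rate = len(confs) / max(attempts, 1)
    if rate < 0.01:
        raise RuntimeError(
            f"closure success rate {rate:.1%} below 1%: geometrically "
            "impossible graft")
    if len(confs) < n_samples:
        warnings.warn(f"only {len(confs)}/{n_samples} tip conformations "
                      "generated within the retry budget")
    return LoopEnsemble(
        candidate_id=cx.h3_sequence(), sequence=cx.h3_sequence(),
        loop_keys=keys, atom_names=atom_names,
        environments={graft.stem_of_origin: cx},
        conformations=confs, stage="initial")


class _TipSampler:
    """Shared machinery for tip resampling within a fixed graft."""

    def __init__(self, cx, window: TipWindow, stem_id):
        self.cx = cx
        self.stem_id = stem_id
        self.window = window
        keys, atom_names, loop_idx = loop_atom_layout(cx)
        self.loop_keys = keys
        self.atom_names = atom_names
        self.loop_idx = loop_idx
        self.base_coords = cx.coords()[loop_idx]
        self.base_dih = measure_dihedrals(cx)
        L = len(keys)
        a, b = window.start, window.end
        self.a, self.b, self.L = a, b, L
        self.mobile_pos = list(range(a - 1, b))  # 0-based loop positions

        chain_keys = cx.chain_residues(cx.h3_chain)
        first = chain_keys.index(keys[0])
        self.anchor_key = chain_keys[first + a - 2]
        self.after_key = (keys[b] if b < L else cx.graft_flank[3])
        self.prev_triad = tuple(
            cx.get_atom(*self.anchor_key, n).position for n in
            ("N", "CA", "C"))
        self.psi_prev = float(np.rad2deg(geometry.dihedral(
            *self.prev_triad,
            cx.get_atom(*keys[a - 1], "N").position)))
        self.target_triad = np.array(
            [cx.get_atom(*self.after_key, n).position
             for n in ("N", "CA", "C")])
        self.after_n = self.target_triad[0]
        self.res_names = [cx.residue_name(*k) for k in keys]
        self.after_name = cx.residue_name(*self.after_key)

        # fixed environment for clash checks: everything but the mobile tip;
        # the anchor carbonyl and the following amide nitrogen are bonded to
        # the rebuilt stretch and are excluded
        mobile_keys = {keys[p] for p in self.mobile_pos}
        bonded = {(self.anchor_key, "C"), (self.anchor_key, "O"),
                  (self.after_key, "N")}
        env_records = [atm for atm in cx.atoms
                       if (atm.chain_id, atm.residue_label)
                       not in mobile_keys
                       and ((atm.chain_id, atm.residue_label),
                            atm.atom_name) not in bonded]
        self.env_xyz = np.array([atm.position for atm in env_records])
        self.env_rad = np.array([rescfg.radius_of(atm.element)
                                 for atm in env_records])
        self.env_tree = cKDTree(self.env_xyz)
        # row lookup for writing coords back
        self.row_of = {(pos, name): r
                       for r, (pos, name) in enumerate(atom_names)}

    def sample(self, rng, closure_tol, base_dihedrals=None, jitter=None):
        a, b = self.a, self.b
        m = len(self.mobile_pos)
        if base_dihedrals is None:
            phis = np.empty(m + 1)
            psis = np.empty(m)
            for j, pos in enumerate(self.mobile_pos):
                phis[j], psis[j] = rama.sample(rng, self.res_names[pos])
            phis[m] = rama.sample(rng, self.after_name)[0]
        else:
            phis, psis = base_dihedrals
            phis = phis + rng.normal(0.0, jitter, size=len(phis))
            psis = psis + rng.normal(0.0, jitter, size=len(psis))
        segN, segCA, segC, gap = geometry.close_segment(
            self.prev_triad, self.psi_prev, phis, psis, self.target_triad,
            max_iter=60, tol=0.03)
        if gap > closure_tol:
            return None
        return self._finish(segN, segCA, segC, gap, rng)

    def _finish(self, segN, segCA, segC, gap, rng):
        m = len(self.mobile_pos)
        coords = self.base_coords.copy()
        # backbone + oxygens
        for j, pos in enumerate(self.mobile_pos):
            next_n = segN[j + 1] if j + 1 < m else self.after_n
            o = geometry.place_carbonyl_oxygen(segCA[j], segC[j], next_n)
            for name, p in (("N", segN[j]), ("CA", segCA[j]),
                            ("C", segC[j]), ("O", o)):
                coords[self.row_of[(pos, name)]] = p
        # quick backbone clash rejection against the fixed environment
        bb = np.concatenate([segN, segCA, segC])
        d, _ = self.env_tree.query(bb, k=1)
        if d.min() < HARD_CLASH_FACTOR * (1.55 + 1.70):
            return None
        # side chains, greedy clash-minimal rotamers
        placed_xyz = []
        placed_rad = []
        for j, pos in enumerate(self.mobile_pos):
            res_name = self.res_names[pos]
            if res_name == "GLY":
                continue
            built = self._best_rotamer(res_name, segN[j], segCA[j], segC[j],
                                       placed_xyz, placed_rad)
            if built is None:
                return None
            for name, p in built.items():
                row = self.row_of.get((pos, name))
                if row is not None:
                    coords[row] = p
                placed_xyz.append(p)
                placed_rad.append(rescfg.radius_of(name[0]))
        dih = self.base_dih.copy()
        # dihedrals of the resampled stretch, recomputed from coordinates
        for j, pos in enumerate(self.mobile_pos):
            prev_c = (segC[j - 1] if j > 0 else self.prev_triad[2])
            next_n = segN[j + 1] if j + 1 < m else self.after_n
            dih[pos, 0] = np.rad2deg(geometry.dihedral(
                prev_c, segN[j], segCA[j], segC[j]))
            dih[pos, 1] = np.rad2deg(geometry.dihedral(
                segN[j], segCA[j], segC[j], next_n))
        return LoopConformation(coords, dih, float(gap), self.stem_id)

    def _best_rotamer(self, res_name, n, ca, c, placed_xyz, placed_rad):
        best = None
        for chis in rescfg.ROTAMERS[res_name]:
            built = rescfg.build_side_chain(res_name, n, ca, c, chis)
            xyz = np.array(list(built.values()))
            rad = np.array([rescfg.radius_of(k[0]) for k in built])
            clashes = 0
            hard = False
            near = self.env_tree.query_ball_point(xyz, 2.4)
            for i, js in enumerate(near):
                for jj in js:
                    dij = np.linalg.norm(self.env_xyz[jj] - xyz[i])
                    if dij < HARD_CLASH_FACTOR * (rad[i] + self.env_rad[jj]):
                        hard = True
                    if dij < 0.6 * (rad[i] + self.env_rad[jj]):
                        clashes += 1
            if placed_xyz:
                px = np.array(placed_xyz)
                pr = np.array(placed_rad)
                dmat = np.linalg.norm(xyz[:, None] - px[None], axis=2)
                lim = 0.6 * (rad[:, None] + pr[None])
                clashes += int((dmat < lim).sum())
                if (dmat < HARD_CLASH_FACTOR
                        * (rad[:, None] + pr[None])).any():
                    hard = True
            if best is None or (hard, clashes) < (best[0], best[1]):
                best = (hard, clashes, built)
        hard, _clashes, built = best
        if hard:
            return None
        return built


# -- statistical potential --------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S")
_EL_INDEX = {e: i for i, e in enumerate(_ELEMENTS)}
_N_BINS = int(STAT_CUTOFF / STAT_BIN)


def _stat_table():
    radii = np.array([rescfg.VDW_RADII[e] for e in _ELEMENTS])
    centers = (np.arange(_N_BINS) + 0.5) * STAT_BIN
    table = np.zeros((4, 4, _N_BINS))
    for i in range(4):
        for j in range(4):
            sigma = radii[i] + radii[j]
            with np.errstate(over="ignore"):
                s4 = (sigma / centers) ** 4
                e = 0.35 * (s4 ** 2 - 2 * s4)
            e = np.clip(e, None, 3.0)
            if {_ELEMENTS[i], _ELEMENTS[j]} <= {"N", "O"}:
                e = e - 0.4 * np.exp(-((centers - 2.9) / 0.4) ** 2)
            table[i, j] = e
    return table


_STAT_TABLE = _stat_table()


def element_indices(elements):
    return np.array([_EL_INDEX.get(str(e).upper(), 0) for e in elements],
                    int)


def stat_potential_arrays(loop_xyz, loop_el, loop_res, env_xyz, env_el,
                          env_tree=None):
    """Typed distance-binned contact potential: loop-environment plus
    loop-loop (residue separation >= 2), 8 Å cutoff, 0.5 Å bins."""
    e_total = 0.0
    if env_tree is None:
        env_tree = cKDTree(env_xyz)
    near = env_tree.query_ball_point(loop_xyz, STAT_CUTOFF)
    for i, js in enumerate(near):
        if not js:
            continue
        js = np.asarray(js, int)
        d = np.linalg.norm(env_xyz[js] - loop_xyz[i], axis=1)
        bins = np.minimum((d / STAT_BIN).astype(int), _N_BINS - 1)
        e_total += float(_STAT_TABLE[loop_el[i], env_el[js], bins].sum())
    # loop-loop
    tree = cKDTree(loop_xyz)
    pairs = tree.query_pairs(STAT_CUTOFF, output_type="ndarray")
    if len(pairs):
        sep = np.abs(loop_res[pairs[:, 0]] - loop_res[pairs[:, 1]])
        keep = sep >= 2
        pairs = pairs[keep]
        if len(pairs):
            d = np.linalg.norm(loop_xyz[pairs[:, 0]]
                               - loop_xyz[pairs[:, 1]], axis=1)
            bins = np.minimum((d / STAT_BIN).astype(int), _N_BINS - 1)
            e_total += float(_STAT_TABLE[loop_el[pairs[:, 0]],
                                         loop_el[pairs[:, 1]], bins].sum())
    return e_total


def stat_potential(conf: LoopConformation, environment) -> float:
    """Statistical potential of a conformation in its environment complex."""
    ctx = _StatContext(environment)
    return ctx.score(conf)


class _StatContext:
    """Cached environment arrays for repeated stat-potential evaluation."""

    def __init__(self, cx):
        keys, atom_names, loop_idx = loop_atom_layout(cx)
        self.loop_el = element_indices(
            [cx.atoms[i].element for i in loop_idx])
        self.loop_res = np.array([pos for pos, _n in atom_names], int)
        loop_set = set(int(i) for i in loop_idx)
        env_records = [a for i, a in enumerate(cx.atoms)
                       if i not in loop_set]
        self.env_xyz = np.array([a.position for a in env_records])
        self.env_el = element_indices([a.element for a in env_records])
        self.env_tree = cKDTree(self.env_xyz)

    def score(self, conf: LoopConformation) -> float:
        return stat_potential_arrays(conf.coords, self.loop_el,
                                     self.loop_res, self.env_xyz,
                                     self.env_el, self.env_tree)


# -- staged filters ---------------------------------------------------------


def cull_ensemble(ens: LoopEnsemble, keep_rescore: int = 1000,
                  keep_top: int = 250) -> LoopEnsemble:
    """Rescore the first ``keep_rescore`` conformations (generation order)
    with the statistical potential and keep the best ``keep_top``."""
    if ens.stage != "initial":
        raise ValueError("cull_ensemble expects an initial-stage ensemble")
    ctx = {stem: _StatContext(cx) for stem, cx in ens.environments.items()}
    pool = ens.conformations[:keep_rescore]
    for conf in pool:
        if conf.stat_energy is None:
            conf.stat_energy = ctx[conf.stem_of_origin].score(conf)
    ranked = sorted(pool, key=lambda c: c.stat_energy)
    if len(ranked) < keep_top:
        warnings.warn(f"only {len(ranked)} conformations available for a "
                      f"top-{keep_top} cull; keeping all")
    kept = ranked[:keep_top]
    return replace_stage(ens, kept, "culled")


def replace_stage(ens, confs, stage):
    order = {s: i for i, s in enumerate(STAGES)}
    if order[stage] < order[ens.stage]:
        raise ValueError(f"stage may not regress: {ens.stage} -> {stage}")
    return LoopEnsemble(ens.candidate_id, ens.sequence, ens.loop_keys,
                        ens.atom_names, dict(ens.environments), list(confs),
                        stage, dict(ens.meta))


def contact_count(conf, antigen_xyz, cutoff: float = CONTACT_CUTOFF) -> int:
    """Heavy-atom contact pairs between loop and antigen within cutoff."""
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf)
    antigen_xyz = np.asarray(antigen_xyz, float)
    if len(antigen_xyz) == 0 or len(coords) == 0:
        return 0
    tree = cKDTree(antigen_xyz)
    return int(sum(len(js)
                   for js in tree.query_ball_point(coords, cutoff)))


def antigen_coords(cx) -> np.ndarray:
    xyz = [a.position for a in cx.atoms
           if cx.region(a.chain_id, a.residue_label) == "ANTIGEN"]
    return np.array(xyz) if xyz else np.zeros((0, 3))


def ensure_contact_counts(ens: LoopEnsemble, cutoff=CONTACT_CUTOFF):
    ag = {stem: antigen_coords(cx) for stem, cx in ens.environments.items()}
    for conf in ens.conformations:
        if conf.contact_count is None:
            conf.contact_count = contact_count(conf,
                                               ag[conf.stem_of_origin],
                                               cutoff)
    return ens


def contact_filter(ens: LoopEnsemble,
                   reference_population: LoopEnsemble) -> LoopEnsemble:
    """Drop conformations below the median contact count of the reference
    population (the rescored head of the initial ensemble)."""
    if not reference_population.conformations:
        raise ValueError("reference population is empty")
    ensure_contact_counts(reference_population)
    ensure_contact_counts(ens)
    threshold = float(np.median(
        [c.contact_count for c in reference_population.conformations]))
    kept = [c for c in ens.conformations if c.contact_count >= threshold]
    out = replace_stage(ens, kept, ens.stage)
    out.meta["contact_threshold"] = threshold
    n = len(ens.conformations)
    out.meta["contact_removed_fraction"] = (n - len(kept)) / n if n else 0.0
    return out


# -- minimization and refinement -------------------------------------------


def minimize_loop(conf: LoopConformation, environment,
                  max_iter: int = 80) -> LoopConformation:
    """Minimize the loop in a fixed environment (internal force field with
    Lennard-Jones, screened Coulomb eps=4r and hydrogen-bond well).  The
    returned conformation never has a higher energy than the input."""
    cx = apply_conf(environment, conf.coords)
    system = forcefield.RegionSystem(cx, cx.h3_index_map, nonbonded="ff")
    coords, e0, e1 = system.run(max_iter=max_iter, gtol=0.05)
    out_cx = forcefield.apply_mobile_coords(cx, system, coords)
    new = conf.copy()
    new.coords = loop_coords(out_cx)
    new.dihedrals = measure_dihedrals(out_cx)
    new.min_energy = e1
    return new


def retain_per_stem(ens_by_stem: dict, keep: int = 100) -> LoopEnsemble:
    """Best ``keep`` minimized conformations per stem, concatenated.

    Per-stem ensembles sit in different energetic reference frames, so the
    selection is within-stem only.
    """
    merged = None
    confs = []
    environments = {}
    for stem, ens in ens_by_stem.items():
        ranked = sorted(ens.conformations,
                        key=lambda c: (c.min_energy
                                       if c.min_energy is not None
                                       else np.inf))
        confs.extend(ranked[:keep])
        environments.update(ens.environments)
        merged = ens
    out = LoopEnsemble(merged.candidate_id, merged.sequence,
                       merged.loop_keys, merged.atom_names, environments,
                       confs, "minimized", {})
    return out


def refine_ensemble(ens: LoopEnsemble, stage1_expansions: int = 5,
                    stage2_expansions: int = 25, window: float = 5.0,
                    seed: int = 0, jitter_deg: float = 10.0,
                    scorer=None) -> LoopEnsemble:
    """Two-round perturb-and-reclose refinement over the full loop with a
    total-energy retention window applied after each round."""
    from . import scoring

    rng = np.random.default_rng(seed)
    if scorer is None:
        scorer = scoring.ConformerScorer(ens)
    samplers = {stem: _TipSampler(cx, _full_loop_window(cx), stem)
                for stem, cx in ens.environments.items()}
    confs = list(ens.conformations)
    for conf in confs:
        if conf.total_energy is None:
            conf.total_energy = scorer.total_energy(conf)
    stage_tags = ["refined", "final"]
    for expansions, tag in zip((stage1_expansions, stage2_expansions),
                               stage_tags):
        new = []
        for conf in confs:
            sampler = samplers[conf.stem_of_origin]
            base = _sampler_dihedrals(sampler, conf)
            env = ens.environments[conf.stem_of_origin]
            for _k in range(expansions):
                cand = sampler.sample(rng, CLOSURE_TOL,
                                      base_dihedrals=base,
                                      jitter=jitter_deg)
                if cand is None:
                    continue
                # reclosed variants sit at ideal-geometry starting points;
                # relax briefly before scoring
                cand = minimize_loop(cand, env, max_iter=30)
                cand.total_energy = scorer.total_energy(cand)
                new.append(cand)
        pool = confs + new
        best = min(c.total_energy for c in pool)
        confs = [c for c in pool if c.total_energy <= best + window]
        ens = replace_stage(ens, confs, tag)
    return ens


def _full_loop_window(cx):
    L = cx.h3_length
    # the first residue's N/CA hang off the fixed H92 psi; sampling starts
    # at s[1] phi
    return TipWindow(1, L)


def _sampler_dihedrals(sampler, conf):
    """(phis, psis) vectors over the sampler's mobile window taken from a
    conformation's recorded dihedrals."""
    m = len(sampler.mobile_pos)
    phis = np.empty(m + 1)
    psis = np.empty(m)
    for j, pos in enumerate(sampler.mobile_pos):
        phis[j] = conf.dihedrals[pos, 0]
        psis[j] = conf.dihedrals[pos, 1]
    last = sampler.mobile_pos[-1]
    if last + 1 < len(conf.dihedrals):
        phis[m] = conf.dihedrals[last + 1, 0]
    else:
        phis[m] = -120.0
    phis[np.isnan(phis)] = -120.0
    psis[np.isnan(psis)] = 135.0
    return phis, psis
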