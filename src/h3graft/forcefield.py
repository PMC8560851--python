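"""Internal molecular-mechanics terms used for regularization, loop
minimization and the total-energy score.

This is a deliberately small, documented force field: harmonic bonds and
angles referenced to ideal-template geometry, omega planarity, a soft-sphere
or Lennard-Jones nonbonded term, screened Coulomb with a distance-dependent
dielectric (eps = 4r), a distance-based hydrogen-bond well, and harmonic
positional restraints.  Gradients are analytic; minimization is L-BFGS with
the environment held fixed.  Nonbonded pair lists are built once from the
input coordinates (with a 1.5 Å skin) and kept fixed during a minimization.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from . import geometry
from . import residues as rescfg

K_BOND = 300.0       # kcal/mol/Å^2
K_ANGLE = 80.0       # kcal/mol/rad^2
K_OMEGA = 15.0       # kcal/mol/rad^2
K_REPULSION = 60.0   # kcal/mol/Å^2 (soft sphere)
LJ_EPS = 0.15        # kcal/mol
COULOMB_CONST = 332.0637
HB_WEIGHT = 2.0      # kcal/mol
HB_SIGMA = 0.35      # Å
HB_R0 = 2.9          # Å
NB_CUTOFF = 10.0     # Å
SKIN = 1.5           # Å


class RegionSystem:
    """Energy model for a mobile residue region inside a fixed complex."""

    def __init__(self, cx, region_keys, nonbonded="ff",
                 restraint_backbone=0.0, restraint_heavy=0.0,
                 cutoff=NB_CUTOFF):
        self.cx = cx
        region_keys = list(region_keys)
        region_set = set(region_keys)
        all_keys = cx.residue_keys()

        # mobile atoms
        mobile_idx = []
        for key in all_keys:
            if key in region_set:
                for name in cx.residue_atom_names(*key):
                    mobile_idx.append(cx.atom_index(*key, name))
        self.mobile_idx = np.array(mobile_idx, int)
        mobile_set = set(mobile_idx)

        # bonded terms (intra-region + peptide links incl. to fixed flanks)
        bonds, angles, torsions = _bonded_terms(cx, region_set)
        involved = set()
        for t in bonds:
            involved.update(t[:2])
        for t in angles:
            involved.update(t[:3])
        for t in torsions:
            involved.update(t[:4])

        # nonbonded partners
        coords_all = cx.coords()
        tree = cKDTree(coords_all)
        excl = _exclusions(bonds, angles, torsions)
        pair_i, pair_j = [], []
        neigh = tree.query_ball_point(coords_all[self.mobile_idx],
                                      cutoff + SKIN)
        for mi, js in zip(self.mobile_idx, neigh):
            for j in js:
                if j == mi:
                    continue
                if j in mobile_set and j <= mi:
                    continue  # count mobile-mobile pairs once
                a, b = (mi, j) if mi < j else (j, mi)
                if (a, b) in excl:
                    continue
                pair_i.append(mi)
                pair_j.append(j)
        pair_i = np.array(pair_i, int)
        pair_j = np.array(pair_j, int)
        involved.update(pair_i.tolist())
        involved.update(pair_j.tolist())
        involved.update(mobile_idx)

        # local indexing: mobile atoms first, then fixed participants
        fixed = sorted(involved - mobile_set)
        self.local_of = {g: i for i, g in enumerate(list(mobile_idx) + fixed)}
        self.n_mobile = len(mobile_idx)
        self.X0 = coords_all[np.array(list(mobile_idx) + fixed, int)]

        loc = self.local_of
        self.bonds = np.array([(loc[i], loc[j]) for i, j, *_ in bonds], int)
        self.bond_r0 = np.array([r0 for *_ij, r0 in bonds], float)
        self.angles = np.array([(loc[i], loc[j], loc[k])
                                for i, j, k, _t in angles], int)
        self.angle_t0 = np.deg2rad([t for *_ijk, t in angles])
        self.torsions = np.array([(loc[i], loc[j], loc[k], loc[l])
                                  for i, j, k, l, _t in torsions], int)
        self.torsion_t0 = np.deg2rad([t for *_ijkl, t in torsions])
        self.pairs = np.array([(loc[i], loc[j])
                               for i, j in zip(pair_i, pair_j)], int)
        self.nonbonded = nonbonded

        # per-pair parameters
        tabr = np.array([rescfg.radius_of(cx.atoms[i].element)
                         for i in list(mobile_idx) + fixed])
        tabq = np.array([rescfg.charge_of(cx.atoms[i].residue_name,
                                          cx.atoms[i].atom_name)
                         for i in list(mobile_idx) + fixed])
        don = np.array([rescfg.is_donor(cx.atoms[i].residue_name,
                                        cx.atoms[i].atom_name)
                        for i in list(mobile_idx) + fixed])
        acc = np.array([rescfg.is_acceptor(cx.atoms[i].residue_name,
                                           cx.atoms[i].atom_name)
                        for i in list(mobile_idx) + fixed])
        if len(self.pairs):
            pi, pj = self.pairs[:, 0], self.pairs[:, 1]
            self.pair_rsum = tabr[pi] + tabr[pj]
            self.pair_qq = tabq[pi] * tabq[pj]
            self.pair_hb = (don[pi] & acc[pj]) | (acc[pi] & don[pj])
        else:
            self.pair_rsum = np.zeros(0)
            self.pair_qq = np.zeros(0)
            self.pair_hb = np.zeros(0, bool)
        self.cutoff = cutoff

        # restraints
        self.restraint_idx = []
        self.restraint_k = []
        if restraint_backbone > 0 or restraint_heavy > 0:
            for g in mobile_idx:
                a = cx.atoms[g]
                k = restraint_backbone if a.is_backbone else restraint_heavy
                if k > 0:
                    self.restraint_idx.append(loc[g])
                    self.restraint_k.append(k)
        self.restraint_idx = np.array(self.restraint_idx, int)
        self.restraint_k = np.array(self.restraint_k, float)
        self.restraint_x0 = (self.X0[self.restraint_idx].copy()
                             if len(self.restraint_idx) else np.zeros((0, 3)))

    # -- energy -----------------------------------------------------------
    def energy_grad(self, X):
        E = 0.0
        G = np.zeros_like(X)
        if len(self.bonds):
            d = X[self.bonds[:, 0]] - X[self.bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            E += float(np.sum(K_BOND * dr ** 2))
            f = (2 * K_BOND * dr / np.maximum(r, 1e-9))[:, None] * d
            np.add.at(G, self.bonds[:, 0], f)
            np.add.at(G, self.bonds[:, 1], -f)
        if len(self.angles):
            e, g = _angle_terms(X, self.angles, self.angle_t0, K_ANGLE)
            E += e
            G += g
        if len(self.torsions):
            e, g = _torsion_terms(X, self.torsions, self.torsion_t0, K_OMEGA)
            E += e
            G += g
        if len(self.pairs):
            e, g = self._pair_terms(X)
            E += e
            G += g
        if len(self.restraint_idx):
            d = X[self.restraint_idx] - self.restraint_x0
            E += float(np.sum(self.restraint_k[:, None] * d ** 2))
            np.add.at(G, self.restraint_idx,
                      2 * self.restraint_k[:, None] * d)
        return E, G

    def _pair_terms(self, X):
        pi, pj = self.pairs[:, 0], self.pairs[:, 1]
        d = X[pi] - X[pj]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-6)
        E = 0.0
        dEdr = np.zeros_like(r)
        if self.nonbonded == "soft":
            d0 = 0.80 * self.pair_rsum
            viol = r < d0
            if viol.any():
                dr = d0[viol] - r[viol]
                E += float(np.sum(K_REPULSION * dr ** 2))
                dEdr[viol] += -2 * K_REPULSION * dr
        else:
            rmin = self.pair_rsum
            within = r < self.cutoff
            dc = 0.6 * rmin
            rr = np.maximum(r, dc)
            s6 = (rmin / rr) ** 6
            e_lj = LJ_EPS * (s6 ** 2 - 2 * s6)
            dlj = LJ_EPS * 12 * (-s6 ** 2 + s6) / rr
            # linear continuation below the softening distance
            low = r < dc
            e_lj = np.where(low, e_lj + dlj * (r - dc), e_lj)
            g_lj = np.where(low, dlj, np.where(r < self.cutoff, dlj, 0.0))
            e_lj = np.where(within, e_lj, 0.0)
            E += float(np.sum(e_lj))
            dEdr += g_lj
            # screened Coulomb, eps = 4r  ->  E = k q1 q2 / (4 r^2)
            e_c = COULOMB_CONST * self.pair_qq / (4 * r ** 2)
            e_c = np.where(within, e_c, 0.0)
            E += float(np.sum(e_c))
            dEdr += np.where(within, -2 * e_c / r, 0.0)
            # distance hydrogen-bond well
            if self.pair_hb.any():
                hb = self.pair_hb & within
                x = (r - HB_R0) / HB_SIGMA
                e_h = np.where(hb, -HB_WEIGHT * np.exp(-x ** 2), 0.0)
                E += float(np.sum(e_h))
                dEdr += np.where(hb, -e_h * 2 * x / HB_SIGMA, 0.0)
        f = (dEdr / r)[:, None] * d
        G = np.zeros_like(X)
        np.add.at(G, pi, f)
        np.add.at(G, pj, -f)
        return E, G

    # -- minimization -----------------------------------------------------
    def run(self, max_iter=500, gtol=0.1):
        """L-BFGS descent over the mobile coordinates.

        Returns (new_mobile_coords, e_initial, e_final); the final energy is
        never above the initial one.
        """
        X = self.X0.copy()
        nm = self.n_mobile

        def fun(x):
            X[:nm] = x.reshape(nm, 3)
            e, g = self.energy_grad(X)
            return e, g[:nm].ravel()

        e0, _ = self.energy_grad(self.X0)
        res = _scipy_minimize(fun, self.X0[:nm].ravel(), jac=True,
                              method="L-BFGS-B",
                              options={"maxiter": max_iter, "gtol": gtol})
        if res.fun <= e0:
            return res.x.reshape(nm, 3), e0, float(res.fun)
        return self.X0[:nm].copy(), e0, e0

    def energy_at_input(self):
        e, _ = self.energy_grad(self.X0)
        return e


def apply_mobile_coords(cx, system: RegionSystem, mobile_coords):
    """Write minimized mobile coordinates back into a copy of the complex."""
    out = cx.copy()
    for g, p in zip(system.mobile_idx, mobile_coords):
        out.atoms[int(g)].position = np.array(p, float)
    return out


# ---------------------------------------------------------------------------
# term construction


def _bonded_terms(cx, region_set):
    """Bonds, angles and omega torsions covering the region, including the
    peptide links into the fixed flanking residues."""
    bonds, angles, torsions = [], [], []
    keys = cx.residue_keys()
    for key in keys:
        if key not in region_set:
            continue
        res_name = cx.residue_name(*key)
        if res_name not in rescfg.AA3_TO_1:
            continue
        tpl_bonds, tpl_angles = rescfg.ideal_internal(res_name)
        have = {n: cx.atom_index(*key, n)
                for n in cx.residue_atom_names(*key)}
        for a, b, r0 in tpl_bonds:
            if a in have and b in have:
                bonds.append((have[a], have[b], r0))
        for a, b, c, t0 in tpl_angles:
            if a in have and b in have and c in have:
                angles.append((have[a], have[b], have[c], t0))
    # peptide links between consecutive residues where either side is mobile
    for k1, k2 in zip(keys, keys[1:]):
        if k1[0] != k2[0]:
            continue
        if k1 not in region_set and k2 not in region_set:
            continue
        need = [(k1, "C"), (k2, "N")]
        if not all(cx.has_atom(*k, n) for k, n in need):
            continue
        c1 = cx.atom_index(*k1, "C")
        n2 = cx.atom_index(*k2, "N")
        if np.linalg.norm(cx.atoms[c1].position
                          - cx.atoms[n2].position) > 2.5:
            continue  # chain break: no link terms
        bonds.append((c1, n2, geometry.BOND_C_N))
        if cx.has_atom(*k1, "CA"):
            ca1 = cx.atom_index(*k1, "CA")
            angles.append((ca1, c1, n2, geometry.ANGLE_CA_C_N))
            if cx.has_atom(*k2, "CA"):
                ca2 = cx.atom_index(*k2, "CA")
                angles.append((c1, n2, ca2, geometry.ANGLE_C_N_CA))
                omega = np.rad2deg(geometry.dihedral(
                    cx.atoms[ca1].position, cx.atoms[c1].position,
                    cx.atoms[n2].position, cx.atoms[ca2].position))
                target = 180.0 if abs(omega) > 90.0 else 0.0
                torsions.append((ca1, c1, n2, ca2, target))
        if cx.has_atom(*k1, "O"):
            angles.append((cx.atom_index(*k1, "O"), c1, n2, 123.0))
    return bonds, angles, torsions


def _exclusions(bonds, angles, torsions):
    """Pairs separated by 1, 2 or 3 bonds, as sorted index tuples."""
    adj = {}
    for i, j, *_ in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excl = set()
    for i in adj:
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
                    for l in adj[k]:
                        if l != j and l != i:
                            excl.add((min(i, l), max(i, l)))
    return excl


def _angle_terms(X, idx, t0, k):
    ri, rj, rk = X[idx[:, 0]], X[idx[:, 1]], X[idx[:, 2]]
    u = ri - rj
    v = rk - rj
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.sum(uh * vh, axis=1), -1 + 1e-9, 1 - 1e-9)
    th = np.arccos(cos)
    sin = np.sqrt(1 - cos ** 2)
    dth = th - t0
    E = float(np.sum(k * dth ** 2))
    pref = 2 * k * dth
    gi = (cos[:, None] * uh - vh) / (nu * sin)[:, None] * pref[:, None]
    gk = (cos[:, None] * vh - uh) / (nv * sin)[:, None] * pref[:, None]
    G = np.zeros_like(X)
    np.add.at(G, idx[:, 0], gi)
    np.add.at(G, idx[:, 2], gk)
    np.add.at(G, idx[:, 1], -(gi + gk))
    return E, G


def _torsion_terms(X, idx, t0, k):
    """Harmonic torsion about targets (radians), periodic-wrapped."""
    p0, p1, p2, p3 = (X[idx[:, m]] for m in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
    phi = np.arctan2(y, x)
    dphi = geometry.wrap_angle(phi - t0)
    E = float(np.sum(k * dphi ** 2))
    pref = 2 * k * dphi
    sq1 = np.sum(n1 ** 2, axis=1)
    sq2 = np.sum(n2 ** 2, axis=1)
    gi = (-nb2 / sq1)[:, None] * n1
    gl = (nb2 / sq2)[:, None] * n2
    dot12 = np.sum(b1 * b2, axis=1) / nb2 ** 2
    dot32 = np.sum(b3 * b2, axis=1) / nb2 ** 2
    gj = -(1 + dot12)[:, None] * gi + dot32[:, None] * gl
    gk = dot12[:, None] * gi - (1 + dot32)[:, None] * gl
    G = np.zeros_like(X)
    np.add.at(G, idx[:, 0], pref[:, None] * gi)
    np.add.at(G, idx[:, 1], pref[:, None] * gj)
    np.add.at(G, idx[:, 2], pref[:, None] * gk)
    np.add.at(G, idx[:, 3], pref[:, None] * gl)
    return E, G
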