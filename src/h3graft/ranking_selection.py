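"""Length-stratified consensus Z-scores and the post-ranking filter cascade.

Scoring functions favor longer loops (more atoms, more contacts), so raw
scores are converted to Z-scores within each H3 length stratum:
z = (score − median) / (1.4826 · MAD).  The composite Z is the unweighted
mean of the total-energy and interaction-energy Z's; candidates at or below
the −1.5 cutoff then pass through a backbone-quality check, an intermolecular
hydrogen-bond screen against the parental complex, and codified curation
rules (shared epitope, stem salt bridge, no buried unpaired charges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import rama
from . import residues as rescfg
from . import scoring

Z_CUTOFF = -1.5
ROBUST_SIGMA = 1.4826


@dataclass
class ZRecord:
    candidate_id: str
    h3_length: int
    z_total: float
    z_interaction: float
    z_composite: float
    rank_total: int = 0
    rank_interaction: int = 0
    rank_composite: int = 0
    scorable: bool = True


@dataclass
class FilterOutcome:
    candidate_id: str
    passed_z: bool = False
    passed_ramachandran: bool = False
    passed_hbond: bool = False
    passed_curation: bool = False
    reasons: list = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return (self.passed_z and self.passed_ramachandran
                and self.passed_hbond and self.passed_curation)


@dataclass
class SelectionConfig:
    z_cutoff: float = Z_CUTOFF
    hb_tolerance: float = 1.0
    shared_epitope_threshold: float = 0.25
    contact_cutoff: float = 4.5
    buried_sasa_threshold: float = 5.0   # Å^2
    salt_bridge_cutoff: float = 4.0      # Å
    enable_ramachandran: bool = True
    enable_hbond: bool = True
    enable_curation: bool = True


def stratum_stats(records, robust: bool = True) -> pd.DataFrame:
    """Per-length median and scale for both score tracks."""
    rows = []
    by_len = {}
    for r in records:
        by_len.setdefault(r.h3_length, []).append(r)
    for L, group in sorted(by_len.items()):
        tot = np.array([g.avg_total for g in group])
        inter = np.array([g.avg_interaction for g in group])
        rows.append((L, len(group),
                     float(np.median(tot)), _scale(tot, robust),
                     float(np.median(inter)), _scale(inter, robust)))
    return pd.DataFrame(rows, columns=[
        "length", "n", "median_total", "scale_total",
        "median_interaction", "scale_interaction"])


def _scale(x, robust=True):
    if robust:
        mad = np.median(np.abs(x - np.median(x)))
        s = ROBUST_SIGMA * mad
        if s > 0:
            return float(s)
    s = float(np.std(x))
    return s if s > 0 else 1.0


def stratified_z(records, robust: bool = True):
    """Z-scores per length stratum; single-member strata are flagged
    unscorable and excluded from ranking and selection."""
    stats = stratum_stats(records, robust).set_index("length")
    out = []
    for r in records:
        row = stats.loc[r.h3_length]
        if row["n"] < 2:
            out.append(ZRecord(r.candidate_id, r.h3_length,
                               np.nan, np.nan, np.nan, scorable=False))
            continue
        zt = (r.avg_total - row["median_total"]) / row["scale_total"]
        zi = (r.avg_interaction - row["median_interaction"]) \
            / row["scale_interaction"]
        out.append(ZRecord(r.candidate_id, r.h3_length, float(zt),
                           float(zi), float((zt + zi) / 2.0)))
    _assign_ranks(out, records)
    return out


def _dense_ranks(values):
    order = {}
    for v in sorted(set(values)):
        order[v] = len(order) + 1
    return [order[v] for v in values]


def _assign_ranks(zrecords, records):
    scorable = [(z, r) for z, r in zip(zrecords, records) if z.scorable]
    if not scorable:
        return
    totals = [r.avg_total for _z, r in scorable]
    inters = [r.avg_interaction for _z, r in scorable]
    comps = [z.z_composite for z, _r in scorable]
    for (z, _r), rt, ri, rc in zip(scorable, _dense_ranks(totals),
                                   _dense_ranks(inters),
                                   _dense_ranks(comps)):
        z.rank_total = rt
        z.rank_interaction = ri
        z.rank_composite = rc


def apply_cutoff(zrecords, cutoff: float = Z_CUTOFF):
    """Candidate ids with composite Z at or below the cutoff."""
    return {z.candidate_id for z in zrecords
            if z.scorable and z.z_composite <= cutoff}


# -- Ramachandran filter ----------------------------------------------------


def ramachandran_check(cx, segment_keys=None):
    """No residue of the extracted loop segment (flank H92 through flank
    H103 by default) may fall in the disallowed region of the map.
    Terminal residues with undefined phi or psi are skipped."""
    if segment_keys is None:
        segment_keys = ([cx.graft_flank[2]] + list(cx.h3_index_map)
                        + [cx.graft_flank[3]])
    chain_keys = cx.chain_residues(segment_keys[0][0])
    offenders = []
    for key in segment_keys:
        for name in ("N", "CA", "C"):
            if not cx.has_atom(*key, name):
                raise ValueError(f"missing backbone atom {name} at {key}")
        pos = chain_keys.index(key)
        prev_key = chain_keys[pos - 1] if pos > 0 else None
        next_key = chain_keys[pos + 1] if pos + 1 < len(chain_keys) else None
        if (prev_key is None or not cx.has_atom(*prev_key, "C")
                or next_key is None or not cx.has_atom(*next_key, "N")):
            continue
        from . import geometry
        phi = np.rad2deg(geometry.dihedral(
            cx.get_atom(*prev_key, "C").position,
            cx.get_atom(*key, "N").position,
            cx.get_atom(*key, "CA").position,
            cx.get_atom(*key, "C").position))
        psi = np.rad2deg(geometry.dihedral(
            cx.get_atom(*key, "N").position,
            cx.get_atom(*key, "CA").position,
            cx.get_atom(*key, "C").position,
            cx.get_atom(*next_key, "N").position))
        if rama.classify(phi, psi, cx.residue_name(*key)) == "disallowed":
            offenders.append(key)
    return len(offenders) == 0, offenders


# -- hydrogen-bond screen ---------------------------------------------------


def _hb_partners(cx):
    """Donor and acceptor heavy atoms split by body (antibody/antigen)."""
    donors, acceptors = [], []
    for i, a in enumerate(cx.atoms):
        region = cx.region(a.chain_id, a.residue_label)
        if region is None:
            continue
        body = 1 if region == "ANTIGEN" else 0
        if rescfg.is_donor(a.residue_name, a.atom_name):
            donors.append((i, body))
        if rescfg.is_acceptor(a.residue_name, a.atom_name):
            acceptors.append((i, body))
    return donors, acceptors


def _donor_antecedent(cx, atom):
    """Bonded heavy neighbor of a donor atom, for the angular factor."""
    names, coords, bonds = (rescfg.template(atom.residue_name)
                            if atom.residue_name in rescfg.AA3_TO_1
                            else (None, None, None))
    if names is None:
        return None
    index = {n: i for i, n in enumerate(names)}
    i = index.get(atom.atom_name)
    if i is None:
        return None
    for a, b in bonds:
        j = b if a == i else (a if b == i else None)
        if j is not None and cx.has_atom(atom.chain_id, atom.residue_label,
                                         names[j]):
            return cx.get_atom(atom.chain_id, atom.residue_label, names[j])
    return None


def hb_terms(cx, hb_cutoff=3.5, sasa_threshold=5.0):
    """(hb_energy, hb_flaw) over the antibody-antigen interface.

    hb_energy: sum of distance/angle hydrogen-bond wells over intermolecular
    donor-acceptor pairs (lower = better).  hb_flaw: count of buried
    interface donors/acceptors with no partner within the cutoff.
    """
    donors, acceptors = _hb_partners(cx)
    xyz = cx.coords()
    e = 0.0
    paired = set()
    for di, dbody in donors:
        datom = cx.atoms[di]
        for ai, abody in acceptors:
            if abody == dbody:
                continue
            aatom = cx.atoms[ai]
            d = np.linalg.norm(datom.position - aatom.position)
            if d > hb_cutoff or d < 2.2:
                continue
            ante = _donor_antecedent(cx, datom)
            ang_factor = 1.0
            if ante is not None:
                from . import geometry
                ang = np.rad2deg(geometry.angle(
                    ante.position, datom.position, aatom.position))
                if ang < 90.0:
                    continue
                ang_factor = (ang - 90.0) / 90.0
            e -= 1.0 * np.exp(-((d - 2.9) / 0.35) ** 2) * ang_factor
            paired.add(di)
            paired.add(ai)
    # flaw term: buried, unpaired interface polar atoms
    ab_xyz = np.array([a.position for a in cx.atoms
                       if cx.region(a.chain_id, a.residue_label)
                       not in (None, "ANTIGEN")])
    ag_xyz = np.array([a.position for a in cx.atoms
                       if cx.region(a.chain_id, a.residue_label)
                       == "ANTIGEN"])
    tree_ab, tree_ag = cKDTree(ab_xyz), cKDTree(ag_xyz)
    radii = np.array([rescfg.radius_of(a.element) for a in cx.atoms])
    candidates = []
    for i, body in donors + acceptors:
        other = tree_ab if body == 1 else tree_ag
        if i not in paired and other.query_ball_point(xyz[i], 5.0):
            candidates.append(i)
    candidates = sorted(set(candidates))
    flaw = 0.0
    if candidates:
        sasa = scoring.shrake_rupley(xyz, radii, subset=candidates,
                                     n_points=60)
        for i, s in zip(candidates, sasa):
            if s < sasa_threshold:
                flaw += 1.0
    return float(e), float(flaw)


def hb_screen(candidate, parent, tolerance: float = 1.0):
    """Candidate must not be more than ``tolerance`` worse than the parent
    on either the hydrogen-bond energy or the flaw count (two independent
    one-sided tests)."""
    e_c, f_c = hb_terms(candidate)
    e_p, f_p = hb_terms(parent)
    ok = (e_c <= e_p + tolerance) and (f_c <= f_p + tolerance)
    return ok, e_c, f_c


# -- curation ---------------------------------------------------------------


def _h3_contacted_antigen_residues(cx, cutoff=4.5):
    h3 = set(cx.h3_index_map)
    h3_xyz = np.array([a.position for a in cx.atoms
                       if (a.chain_id, a.residue_label) in h3])
    contacted = set()
    for a in cx.atoms:
        if cx.region(a.chain_id, a.residue_label) != "ANTIGEN":
            continue
        if len(h3_xyz) and np.min(np.linalg.norm(
                h3_xyz - a.position, axis=1)) <= cutoff:
            contacted.add((a.chain_id, a.residue_label))
    return contacted


def curation_checks(candidate, parent, config: SelectionConfig = None):
    """Codified visual-inspection rules.

    (a) shared epitope: the candidate H3 must contact at least a configured
    fraction of the antigen residues contacted by the parental H3;
    (b) if position s[2] is Arg and s[L-1] is Asp, the stem salt bridge must
    be intact (guanidinium N to carboxylate O within 4 Å);
    (c) no charged H3 side-chain atom may be buried (SASA < 5 Å^2) without
    an opposite charge within 4.5 Å.
    """
    config = config or SelectionConfig()
    reasons = []
    parent_contacts = _h3_contacted_antigen_residues(
        parent, config.contact_cutoff)
    cand_contacts = _h3_contacted_antigen_residues(
        candidate, config.contact_cutoff)
    if parent_contacts:
        shared = len(parent_contacts & cand_contacts) / len(parent_contacts)
    else:
        shared = 1.0
    ok_shared = shared >= config.shared_epitope_threshold
    if not ok_shared:
        reasons.append(f"shared epitope fraction {shared:.2f} below "
                       f"{config.shared_epitope_threshold}")

    ok_salt = True
    keys = candidate.h3_index_map
    if len(keys) >= 3:
        s2, sm1 = keys[1], keys[-2]
        if (candidate.residue_name(*s2) == "ARG"
                and candidate.residue_name(*sm1) == "ASP"):
            guan = [candidate.get_atom(*s2, n).position
                    for n in ("NE", "NH1", "NH2")
                    if candidate.has_atom(*s2, n)]
            carb = [candidate.get_atom(*sm1, n).position
                    for n in ("OD1", "OD2") if candidate.has_atom(*sm1, n)]
            if guan and carb:
                dmin = min(np.linalg.norm(g - c)
                           for g in guan for c in carb)
                ok_salt = dmin <= config.salt_bridge_cutoff
                if not ok_salt:
                    reasons.append(
                        f"stem Arg/Asp interaction broken ({dmin:.1f} Å)")

    ok_buried = True
    charged = []
    xyz = candidate.coords()
    radii = np.array([rescfg.radius_of(a.element)
                      for a in candidate.atoms])
    charges = np.array([rescfg.charge_of(a.residue_name, a.atom_name)
                        for a in candidate.atoms])
    h3 = set(candidate.h3_index_map)
    for i, a in enumerate(candidate.atoms):
        if ((a.chain_id, a.residue_label) in h3 and not a.is_backbone
                and abs(charges[i]) >= 0.45):
            charged.append(i)
    if charged:
        sasa = scoring.shrake_rupley(xyz, radii, subset=charged,
                                     n_points=60)
        for i, s in zip(charged, sasa):
            if s >= config.buried_sasa_threshold:
                continue
            # the charge unit is the side-chain group: any member atom
            # with an opposite charge nearby neutralizes the burial
            a = candidate.atoms[i]
            sign = np.sign(charges[i])
            group = [j for j in charged
                     if (candidate.atoms[j].chain_id,
                         candidate.atoms[j].residue_label)
                     == (a.chain_id, a.residue_label)
                     and np.sign(charges[j]) == sign]
            paired = False
            for j in group:
                d = np.linalg.norm(xyz - xyz[j], axis=1)
                partners = (d <= 4.5) & (np.sign(charges) == -sign) \
                    & (np.abs(charges) >= 0.45)
                if partners.any():
                    paired = True
                    break
            if not paired:
                ok_buried = False
                reasons.append(
                    f"buried unpaired charge {a.residue_name} "
                    f"{a.residue_label}/{a.atom_name}")
    return {"shared_epitope": ok_shared, "salt_bridge": ok_salt,
            "no_buried_charge": ok_buried, "reasons": reasons,
            "shared_fraction": shared}


# -- cascade ----------------------------------------------------------------


def select(zrecords, complexes, parent, config: SelectionConfig = None):
    """Full filter cascade, evaluated on each candidate's best
    total-energy conformer; returns a report DataFrame plus outcomes."""
    config = config or SelectionConfig()
    cutoff_set = apply_cutoff(zrecords, config.z_cutoff)
    outcomes = {}
    for z in sorted([z for z in zrecords if z.scorable],
                    key=lambda z: z.z_composite):
        out = FilterOutcome(z.candidate_id)
        out.passed_z = z.candidate_id in cutoff_set
        if not out.passed_z:
            out.reasons.append(f"composite Z {z.z_composite:.2f} above "
                               f"cutoff {config.z_cutoff}")
        cx = complexes.get(z.candidate_id)
        if cx is None:
            out.reasons.append("no structure available")
            outcomes[z.candidate_id] = out
            continue
        if config.enable_ramachandran:
            ok, offenders = ramachandran_check(cx)
            out.passed_ramachandran = ok
            if not ok:
                out.reasons.append(
                    "disallowed backbone at "
                    + ",".join(f"{c}/{l}" for c, l in offenders))
        else:
            out.passed_ramachandran = True
        if config.enable_hbond:
            ok, e_c, f_c = hb_screen(cx, parent, config.hb_tolerance)
            out.passed_hbond = ok
            if not ok:
                out.reasons.append(
                    f"hydrogen-bond screen failed (E {e_c:.2f}, "
                    f"flaw {f_c:.0f})")
        else:
            out.passed_hbond = True
        if config.enable_curation:
            cur = curation_checks(cx, parent, config)
            out.passed_curation = (cur["shared_epitope"]
                                   and cur["salt_bridge"]
                                   and cur["no_buried_charge"])
            out.reasons.extend(cur["reasons"])
        else:
            out.passed_curation = True
        outcomes[z.candidate_id] = out

    rows = []
    for z in sorted([z for z in zrecords if z.scorable],
                    key=lambda z: z.z_composite):
        o = outcomes[z.candidate_id]
        rows.append((z.candidate_id, z.h3_length, z.z_total,
                     z.z_interaction, z.z_composite, z.rank_composite,
                     o.passed_z, o.passed_ramachandran, o.passed_hbond,
                     o.passed_curation, o.selected,
                     "; ".join(o.reasons)))
    report = pd.DataFrame(rows, columns=[
        "candidate_id", "length", "z_total", "z_interaction", "z_composite",
        "rank", "passed_z", "passed_rama", "passed_hb", "passed_curation",
        "selected", "reasons"])
    return report, outcomes
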