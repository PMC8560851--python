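"""Graft a stem template into the parental complex: anchor superposition,
backbone transplant, rotamer-based side-chain rebuilding and geometric
regularization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield, geometry
from . import model_io
from . import residues as rescfg

CLASH_FACTOR = 0.6  # heavy-atom clash: d < factor * (r_i + r_j)


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points):
        return np.asarray(points, float) @ self.rotation.T + self.translation


@dataclass
class GraftResult:
    complex: "model_io.AntibodyComplex"
    anchor_rmsd: float
    stem_of_origin: str


def superpose(mobile, reference):
    """Least-squares rigid superposition (proper rotation only).

    Returns (RigidTransform, rmsd).
    """
    R, t, rmsd = geometry.kabsch(mobile, reference)
    return RigidTransform(R, t), rmsd


def graft_stem(parent, template, h3_sequence: str) -> GraftResult:
    """Transplant the graft-region backbone of a template into the parent.

    The transform is fitted on the six anchor CA atoms (three framework
    residues on each side of H3); the graft region is replaced by the
    transformed template backbone, the loop is renamed to ``h3_sequence``
    and all graft-region side chains are rebuilt.  Nothing outside the
    graft region moves.
    """
    if template.h3_length != len(h3_sequence):
        raise ValueError(
            f"template length {template.h3_length} != sequence length "
            f"{len(h3_sequence)}")
    for key in parent.graft_flank:
        if not parent.has_atom(*key, "CA"):
            raise ValueError(f"anchor CA missing for {key}")
    ref = np.array([parent.get_atom(*key, "CA").position
                    for key in parent.graft_flank])
    transform, anchor_rmsd = superpose(template.anchor_ca(), ref)

    chain = parent.h3_chain
    L = len(h3_sequence)
    loop_labels = model_io.h3_labels(L)
    flank_n = parent.graft_flank[:3]
    flank_c = parent.graft_flank[3:]
    new_keys = (list(flank_n)
                + [(chain, lab) for lab in loop_labels] + list(flank_c))
    new_names = ([parent.residue_name(*k) for k in flank_n]
                 + [rescfg.AA1_TO_3[aa] for aa in h3_sequence]
                 + [parent.residue_name(*k) for k in flank_c])
    if len(template.residues) != len(new_keys):
        raise ValueError("template does not cover the graft region")

    # transformed backbone records for the graft region
    region_atoms = []
    for (key, res_name, tres) in zip(new_keys, new_names,
                                     template.residues):
        for atom_name in ("N", "CA", "C", "O"):
            if atom_name not in tres:
                continue
            region_atoms.append(model_io.AtomRecord(
                chain_id=key[0], residue_label=key[1], residue_name=res_name,
                atom_name=atom_name, element=atom_name[0],
                position=transform.apply(tres[atom_name][None])[0]))

    # splice: copy everything outside the old graft region untouched
    old_region = set(parent.graft_flank) | set(parent.h3_index_map)
    atoms = []
    inserted = False
    for a in parent.atoms:
        key = (a.chain_id, a.residue_label)
        if key in old_region:
            if not inserted:
                atoms.extend(region_atoms)
                inserted = True
            continue
        atoms.append(a.copy())

    annotation = dict(parent.annotation.region_of)
    for key in parent.h3_index_map:
        annotation.pop(key, None)
    for lab in loop_labels:
        annotation[(chain, lab)] = "H3"
    cx = model_io.AntibodyComplex(
        atoms, model_io.RegionAnnotation(
            annotation, parent.annotation.cdr_definition),
        disulfides=list(parent.disulfides),
        terminal_caps=set(parent.terminal_caps))
    cx = place_side_chains(cx, new_keys)
    cx = form_stem_salt_bridge(cx)
    return GraftResult(cx, float(anchor_rmsd), template.cluster_id)


def form_stem_salt_bridge(cx, target=3.2, clash_factor=0.55):
    """If the parental loop carries the stem Arg(s2)/Asp(s[L-1]) pair,
    swing both side chains into a salt bridge (deterministic chi sweep),
    mirroring the interaction the curation rules expect."""
    import itertools

    keys = cx.h3_index_map
    if len(keys) < 3:
        return cx
    s2, sm1 = keys[1], keys[-2]
    if (cx.residue_name(*s2) != "ARG" or cx.residue_name(*sm1) != "ASP"):
        return cx
    bb = {k: tuple(cx.get_atom(*k, n).position for n in ("N", "CA", "C"))
          for k in (s2, sm1)}
    env = [a for a in cx.atoms
           if (a.chain_id, a.residue_label) not in (s2, sm1)]
    env_xyz = np.array([a.position for a in env])
    env_rad = np.array([rescfg.radius_of(a.element) for a in env])
    tree = cKDTree(env_xyz)

    def clash_free(built):
        for name, xyz in built.items():
            r = rescfg.radius_of(name[0])
            for j in tree.query_ball_point(xyz, 2.2):
                if np.linalg.norm(env_xyz[j] - xyz) < clash_factor * (
                        r + env_rad[j]):
                    return False
        return True

    grid = (-150, -90, -30, 30, 90, 150)
    arg_builds = []
    for ach in itertools.product(grid, repeat=4):
        arg = rescfg.build_side_chain("ARG", *bb[s2], ach)
        if clash_free(arg):
            arg_builds.append((np.array([arg[n] for n in
                                         ("NE", "NH1", "NH2")]), arg))
    best = None
    for dch in itertools.product(grid, repeat=2):
        asp = rescfg.build_side_chain("ASP", *bb[sm1], dch)
        if not clash_free(asp):
            continue
        carb = np.array([asp["OD1"], asp["OD2"]])
        for guan, arg in arg_builds:
            d = float(np.linalg.norm(
                guan[:, None] - carb[None], axis=2).min())
            if best is None or d < best[0]:
                best = (d, arg, asp)
            if best[0] <= target:
                break
        if best is not None and best[0] <= target:
            break
    if best is None or best[0] > 4.0:
        return cx
    _d, arg, asp = best
    out = cx.copy()
    for key, built in ((s2, arg), (sm1, asp)):
        for a in out.atoms:
            if ((a.chain_id, a.residue_label) == key
                    and a.atom_name in built):
                a.position = np.array(built[a.atom_name], float)
    return out



def place_side_chains(cx, residue_keys):
    """Rebuild side chains at the clash-minimal rotamer.

    Greedy pass in chain order over a small backbone-independent rotamer
    set; a clash is a non-bonded heavy-atom pair closer than 0.6 x the sum
    of van der Waals radii.  Ties go to the most frequent rotamer.
    """
    residue_keys = [k for k in cx.residue_keys() if k in set(residue_keys)]
    for key in residue_keys:
        if cx.residue_name(*key) not in rescfg.AA3_TO_1:
            raise ValueError(
                f"unknown residue type {cx.residue_name(*key)} at {key}")
    out = cx.copy()
    # strip all side chains of the residues being (re)built first
    target = set(residue_keys)
    atoms = [a for a in out.atoms
             if (a.chain_id, a.residue_label) not in target
             or a.is_backbone]
    out = model_io.AntibodyComplex(
        atoms, out.annotation, disulfides=out.disulfides,
        terminal_caps=out.terminal_caps,
        check_h3=bool(cx.h3_index_map))

    for key in residue_keys:
        res_name = out.residue_name(*key)
        if res_name in ("GLY",):
            continue
        n_pos = out.get_atom(*key, "N").position
        ca_pos = out.get_atom(*key, "CA").position
        c_pos = out.get_atom(*key, "C").position
        env_records = [a for a in out.atoms
                       if (a.chain_id, a.residue_label) != key]
        env_xyz = np.array([a.position for a in env_records])
        env_rad = np.array([rescfg.radius_of(a.element)
                            for a in env_records])
        tree = cKDTree(env_xyz) if len(env_records) else None
        best = None
        for rot_i, chis in enumerate(rescfg.ROTAMERS[res_name]):
            built = rescfg.build_side_chain(res_name, n_pos, ca_pos, c_pos,
                                            chis)
            clashes = 0
            for name, xyz in built.items():
                if tree is None:
                    break
                r = rescfg.radius_of(name[0])
                for j in tree.query_ball_point(xyz, (r + 1.80)
                                               * CLASH_FACTOR):
                    if np.linalg.norm(env_xyz[j] - xyz) < CLASH_FACTOR * (
                            r + env_rad[j]):
                        clashes += 1
            if best is None or clashes < best[0]:
                best = (clashes, rot_i, built)
        _clashes, _rot_i, built = best
        new_atoms = list(out.atoms)
        for name in rescfg.side_chain_names(res_name):
            if name not in built:
                continue
            new_atoms.append(model_io.AtomRecord(
                chain_id=key[0], residue_label=key[1], residue_name=res_name,
                atom_name=str(name), element=str(name)[0],
                position=np.array(built[name], float)))
        out = model_io.AntibodyComplex(
            new_atoms, out.annotation, disulfides=out.disulfides,
            terminal_caps=out.terminal_caps,
            check_h3=bool(cx.h3_index_map))
    return _regroup_atoms(out)


def count_clashes(cx, residue_keys=None):
    """Non-bonded heavy-atom clash count (pairs < 0.6 x radius sum),
    excluding intra-residue and directly bonded backbone pairs."""
    tab_xyz = cx.coords()
    rads = np.array([rescfg.radius_of(a.element) for a in cx.atoms])
    keys = [(a.chain_id, a.residue_label) for a in cx.atoms]
    tree = cKDTree(tab_xyz)
    pairs = tree.query_pairs(CLASH_FACTOR * 2 * max(rads), output_type="ndarray")
    n = 0
    sel = None if residue_keys is None else set(residue_keys)
    for i, j in pairs:
        if keys[i] == keys[j]:
            continue
        if sel is not None and keys[i] not in sel and keys[j] not in sel:
            continue
        d = np.linalg.norm(tab_xyz[i] - tab_xyz[j])
        if d < CLASH_FACTOR * (rads[i] + rads[j]):
            # ignore the peptide bond itself
            if {cx.atoms[i].atom_name, cx.atoms[j].atom_name} == {"C", "N"}:
                continue
            n += 1
    return n


def _regroup_atoms(cx):
    """Re-order atoms so each residue's atoms are contiguous, backbone
    first, side chain in template order."""
    order = {n: i for i, n in enumerate(("N", "CA", "C", "O"))}
    atoms = []
    for key in cx.residue_keys():
        names = cx.residue_atom_names(*key)
        res_name = cx.residue_name(*key)
        try:
            tpl_order = {n: i for i, n in
                         enumerate(rescfg.heavy_atom_names(res_name))}
        except Exception:
            tpl_order = {}
        names.sort(key=lambda n: (0, order[n]) if n in order
                   else (1, tpl_order.get(n, 99), n))
        for n in names:
            atoms.append(cx.get_atom(*key, n))
    return model_io.AntibodyComplex(
        atoms, cx.annotation, disulfides=cx.disulfides,
        terminal_caps=cx.terminal_caps, check_h3=bool(cx.h3_index_map))


def regularize(cx, region_keys, ca_restraint: float = 5.0,
               max_iter: int = 500, gtol: float = 0.1):
    """Gradient-based geometry clean-up of a region in a fixed environment.

    Bonded terms plus soft-sphere repulsion, with harmonic restraints
    (``ca_restraint`` kcal/mol/Å^2) on the backbone N, CA, C, O atoms.
    Atoms outside the region do not move.
    """
    system = forcefield.RegionSystem(
        cx, region_keys, nonbonded="soft",
        restraint_backbone=ca_restraint, restraint_heavy=0.0)
    coords, _e0, _e1 = system.run(max_iter=max_iter, gtol=gtol)
    return forcefield.apply_mobile_coords(cx, system, coords)
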