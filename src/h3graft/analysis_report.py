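"""Post-hoc analyses: per-region RMSD/BRMSD tables, sequence
identity/similarity, K_D fold-ratio tables, and retrospective grafting of
crystal loop conformations into the parental complex."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import forcefield, geometry, grafting, model_io, scoring
from . import loop_sampling as ls
from . import residues as rescfg

RMSD_REGIONS = ("H1", "H2", "H3", "L1", "L2", "L3", "FR", "ANTIGEN")


@dataclass
class KdRecord:
    candidate_id: str
    kd: float                 # nM
    fold_vs_parent: float
    fold_vs_baseline: float


# -- per-region RMSD --------------------------------------------------------


def _region_keys(cx, region):
    return [key for key in cx.residue_keys()
            if cx.region(*key) == region]


def _matched_positions(model, reference, keys_m, keys_r, backbone_only):
    """Atom position pairs matched by (chain, label, atom name)."""
    pm, pr = [], []
    set_r = {k: set(reference.residue_atom_names(*k)) for k in keys_r}
    keys_r_set = set(keys_r)
    for key in keys_m:
        if key not in keys_r_set:
            continue
        for name in model.residue_atom_names(*key):
            if backbone_only and name not in ("N", "CA", "C", "O"):
                continue
            if name in set_r[key]:
                pm.append(model.get_atom(*key, name).position)
                pr.append(reference.get_atom(*key, name).position)
    return np.array(pm), np.array(pr)


def per_region_rmsd(model, reference) -> pd.DataFrame:
    """Heavy-atom RMSD and backbone RMSD (BRMSD) per region after a single
    rigid fit on the framework backbone.

    The fit is computed once on FR backbone atoms and applied to all
    regions (no per-region refitting).  Regions absent from either
    structure, and H3 regions of differing length, yield empty cells.
    """
    fr_m, fr_r = _matched_positions(model, reference,
                                    _region_keys(model, "FR"),
                                    _region_keys(reference, "FR"), True)
    if len(fr_m) < 3:
        raise ValueError("insufficient matched framework backbone atoms")
    R, t, fr_rmsd = geometry.kabsch(fr_m, fr_r)
    rows = []
    for region in RMSD_REGIONS:
        keys_m = _region_keys(model, region)
        keys_r = _region_keys(reference, region)
        if not keys_m or not keys_r:
            rows.append((region, np.nan, np.nan))
            continue
        if region == "H3" and len(keys_m) != len(keys_r):
            rows.append((region, np.nan, np.nan))  # unlike lengths refused
            continue
        vals = []
        for backbone_only in (False, True):
            pm, pr = _matched_positions(model, reference, keys_m, keys_r,
                                        backbone_only)
            if len(pm) == 0:
                vals.append(np.nan)
            else:
                vals.append(geometry.rmsd(pm @ R.T + t, pr))
        rows.append((region, vals[0], vals[1]))
    return pd.DataFrame(rows, columns=["region", "rmsd_heavy",
                                       "brmsd_backbone"])


# -- sequence identity / similarity ----------------------------------------


def seq_identity_similarity(a: str, b: str):
    """Global BLOSUM62 alignment (affine gaps, open -11 / extend -1);
    identity and similarity over aligned non-gap pairs, whole percent."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    ident = similar = aligned = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            aligned += 1
            if a[i] == b[j]:
                ident += 1
            if matrix[a[i]][b[j]] > 0:
                similar += 1
    if aligned == 0:
        return 0, 0
    return (round(100.0 * ident / aligned),
            round(100.0 * similar / aligned))


# -- K_D fold tables --------------------------------------------------------


def kd_fold_table(records, parent_id, baseline_id):
    """Fold ratios of each design K_D against the parent and baseline."""
    kd = {cid: float(v) for cid, v in records}
    for cid, v in kd.items():
        if v <= 0:
            raise ValueError(f"non-positive K_D for {cid}")
    if parent_id not in kd or baseline_id not in kd:
        raise ValueError("parent or baseline missing from K_D records")
    out = []
    for cid, v in records:
        out.append(KdRecord(cid, float(v),
                            kd[parent_id] / float(v),
                            kd[baseline_id] / float(v)))
    return out


def favorable_h3_count(records, baseline_id, parent_id=None) -> int:
    """Designs whose K_D is strictly better (lower) than the baseline's,
    excluding the parent and the baseline themselves."""
    kd = dict(records)
    base = float(kd[baseline_id])
    n = 0
    for cid, v in records:
        if cid == baseline_id or (parent_id is not None
                                  and cid == parent_id):
            continue
        if float(v) < base:
            n += 1
    return n


def affinity_loss_count(records, parent_id, threshold: float = 500.0,
                        baseline_id=None) -> int:
    """Designs with a K_D at least ``threshold``-fold worse than the
    parent's."""
    kd = dict(records)
    parent = float(kd[parent_id])
    n = 0
    for cid, v in records:
        if cid == parent_id or cid == baseline_id:
            continue
        if float(v) / parent >= threshold:
            n += 1
    return n


# -- retrospective grafting -------------------------------------------------


def retrospective_graft(parent, design_crystal, stored_medians=None,
                        sie_config=None):
    """Graft a crystal H3 loop conformation back into the parental complex
    and score it as a single structure.

    The design crystal is superposed on the parent framework backbone, the
    loop (and its side chains) is transplanted, environment side chains
    that clash with the incoming loop are replaced by the design-crystal
    rotamer, and the loop is minimized in a fixed environment.  Returns
    (total_energy, interaction_energy, z_composite); the Z uses the stored
    per-length medians from the original screen (NaN when absent).
    """
    fr_m, fr_r = _matched_positions(design_crystal, parent,
                                    _region_keys(design_crystal, "FR"),
                                    _region_keys(parent, "FR"), True)
    if len(fr_m) < 3:
        raise ValueError("cannot superpose design crystal on parent "
                         "framework")
    R, t, _ = geometry.kabsch(fr_m, fr_r)
    if np.allclose(R, np.eye(3), atol=1e-9) and np.allclose(t, 0.0,
                                                            atol=1e-9):
        # same frame: keep coordinates bitwise to preserve determinism
        R, t = np.eye(3), np.zeros(3)

    loop_keys = design_crystal.h3_index_map
    L = len(loop_keys)
    chain = parent.h3_chain
    labels = model_io.h3_labels(L)

    region_atoms = []
    for lab, key in zip(labels, loop_keys):
        for name in design_crystal.residue_atom_names(*key):
            a = design_crystal.get_atom(*key, name)
            region_atoms.append(model_io.AtomRecord(
                chain_id=chain, residue_label=lab,
                residue_name=a.residue_name, atom_name=a.atom_name,
                element=a.element, position=a.position @ R.T + t))

    old_loop = set(parent.h3_index_map)
    atoms = []
    inserted = False
    for a in parent.atoms:
        key = (a.chain_id, a.residue_label)
        if key in old_loop:
            if not inserted:
                atoms.extend(region_atoms)
                inserted = True
            continue
        atoms.append(a.copy())
    annotation = dict(parent.annotation.region_of)
    for key in parent.h3_index_map:
        annotation.pop(key, None)
    for lab in labels:
        annotation[(chain, lab)] = "H3"
    grafted = model_io.AntibodyComplex(
        atoms, model_io.RegionAnnotation(annotation), check_h3=True)

    # environment side chains clashing with the incoming loop take the
    # design-crystal rotamer
    grafted, replaced = _resolve_environment_clashes(
        grafted, design_crystal, (R, t))

    total, interaction = scoring.single_structure_scores(
        grafted, sie_config)
    z = np.nan
    if stored_medians is not None:
        med = stored_medians
        if hasattr(med, "set_index"):
            med = {int(r.length): r for r in med.itertuples()}
        row = med.get(L)
        if row is not None:
            zt = (total - row.median_total) / row.scale_total
            zi = (interaction - row.median_interaction) \
                / row.scale_interaction
            z = float((zt + zi) / 2.0)
    return total, interaction, z, {"replaced_side_chains": replaced,
                                   "complex": grafted}


def _resolve_environment_clashes(grafted, design_crystal, transform):
    """Swap clashing environment side-chain rotamers for the
    design-crystal ones where available; unresolvable clashes are
    reported, not fatal."""
    R, t = transform
    h3 = set(grafted.h3_index_map)
    loop_xyz = np.array([a.position for a in grafted.atoms
                         if (a.chain_id, a.residue_label) in h3])
    replaced = []
    out = grafted
    for key in list(grafted.residue_keys()):
        if key in h3:
            continue
        clash = False
        for name in out.residue_atom_names(*key):
            if name in ("N", "CA", "C", "O"):
                continue
            a = out.get_atom(*key, name)
            r = rescfg.radius_of(a.element)
            d = np.linalg.norm(loop_xyz - a.position, axis=1)
            if (d < grafting.CLASH_FACTOR * (r + 1.8)).any():
                clash = True
                break
        if not clash:
            continue
        if key in set(design_crystal.residue_keys()):
            new_atoms = []
            for a in out.atoms:
                if ((a.chain_id, a.residue_label) == key
                        and not a.is_backbone):
                    continue
                new_atoms.append(a)
            for name in design_crystal.residue_atom_names(*key):
                if name in ("N", "CA", "C", "O"):
                    continue
                src = design_crystal.get_atom(*key, name)
                new_atoms.append(model_io.AtomRecord(
                    chain_id=key[0], residue_label=key[1],
                    residue_name=src.residue_name, atom_name=src.atom_name,
                    element=src.element, position=src.position @ R.T + t))
            out = model_io.AntibodyComplex(
                new_atoms, out.annotation, disulfides=out.disulfides,
                terminal_caps=out.terminal_caps, check_h3=True)
            replaced.append(key)
        else:
            replaced.append((key, "unresolved"))
    return out, replaced
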