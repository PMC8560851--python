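"""Synthetic inputs for every pipeline stage.

The toy complex is a ~90-residue antibody-like scaffold: a heavy chain whose
framework strands flank a hairpin H3 (parental sequence SRWGGDGFYAMDY), a
light-chain hairpin, and a rigid convex antigen (a short helix) placed
against the H3 tip so that the parental loop makes at least five heavy-atom
contacts at 4.5 Å.  Loop amino-acid composition for generated libraries is
drawn from the residue frequencies of the bH1 redesign panel, keeping
fixtures in a realistic composition regime.  Everything is deterministic
under the FixtureSpec seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import data, geometry, grafting, model_io, stem_library
from . import residues as rescfg

CONTACT_CUTOFF = 4.5
MIN_PARENT_CONTACTS = 5


@dataclass
class FixtureSpec:
    seed: int = 0
    h3_length_range: tuple = (7, 16)
    library_size: int = 100
    length_bias_slope: float = 1.0   # score units per residue
    noise_sd: float = 1.0            # score units

    def __post_init__(self):
        lo, hi = self.h3_length_range
        if not (6 <= lo <= hi <= 30):
            raise ValueError("length range must lie within [6, 30]")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# -- toy complex ------------------------------------------------------------

_H_FW1 = "QVTLSADTSKNQFSLKLSSV"   # labels 70..89
_H_FLANK_N = "YFA"               # 90..92
_H_FLANK_C = "WGQ"               # 103..105
_H_FW2 = "GTLVTVSSAS"            # 106..115
_L_SEQ = "DIQMTQSPSSLSASVGDRVTITKRASQS"   # light chain 1..28
_AG_SEQ = "NERKFLDWYQTGSH"       # antigen helix 1..14

_STRAND = (-125.0, 135.0)
_TURN = [(-60.0, -30.0), (-90.0, 0.0), (-70.0, -20.0), (-60.0, -30.0)]


def _h3_dihedrals(length, rng):
    """Compact hairpin loop dihedrals with small seeded jitter."""
    n_out = max((length - 2) // 2, 1)
    base = ([(-120.0, 135.0)] * n_out
            + [(55.0, 40.0), (75.0, 5.0)]
            + [(-120.0, 135.0)] * max(length - n_out - 2, 0))
    base = base[:length]
    while len(base) < length:
        base.append((-120.0, 135.0))
    return [(p + rng.uniform(-6, 6), s + rng.uniform(-6, 6))
            for p, s in base]


def _chain_records(chain_id, labels, seq, dihedrals, transform=None):
    phis = [d[0] for d in dihedrals]
    psis = [d[1] for d in dihedrals]
    N, CA, C = geometry.build_chain(len(seq), phis, psis)
    O = np.zeros_like(N)
    for i in range(len(seq) - 1):
        O[i] = geometry.place_carbonyl_oxygen(CA[i], C[i], N[i + 1])
    O[-1] = geometry.terminal_oxygen(N[-1], CA[-1], C[-1])
    coords = {"N": N, "CA": CA, "C": C, "O": O}
    if transform is not None:
        R, t = transform
        for k in coords:
            coords[k] = coords[k] @ R.T + t
    atoms = []
    for i, (lab, aa) in enumerate(zip(labels, seq)):
        res_name = rescfg.AA1_TO_3[aa]
        for name in ("N", "CA", "C", "O"):
            atoms.append(model_io.AtomRecord(
                chain_id=chain_id, residue_label=lab, residue_name=res_name,
                atom_name=name, element=name[0],
                position=np.array(coords[name][i], float)))
    return atoms


def _rot(axis, deg):
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(np.deg2rad(deg) * np.asarray(axis,
                                                             float)).as_matrix()


def toy_annotation(h3_len: int) -> model_io.RegionAnnotation:
    mapping = {}
    h_labels = ([str(i) for i in range(70, 90)]
                + ["90", "91", "92"])
    for lab in h_labels:
        mapping[("H", lab)] = "FR"
    for lab in ("75", "76", "77"):
        mapping[("H", lab)] = "H1"
    for lab in ("81", "82", "83"):
        mapping[("H", lab)] = "H2"
    for lab in model_io.h3_labels(h3_len):
        mapping[("H", lab)] = "H3"
    for lab in [str(i) for i in range(103, 116)]:
        mapping[("H", lab)] = "FR"
    for i in range(1, 29):
        mapping[("L", str(i))] = "FR"
    for lab in ("5", "6", "7"):
        mapping[("L", lab)] = "L1"
    for lab in ("13", "14", "15"):
        mapping[("L", lab)] = "L2"
    for lab in ("20", "21", "22"):
        mapping[("L", lab)] = "L3"
    for i in range(1, len(_AG_SEQ) + 1):
        mapping[("A", str(i))] = "ANTIGEN"
    return model_io.RegionAnnotation(mapping)


def make_toy_complex(spec: FixtureSpec = None) -> model_io.AntibodyComplex:
    """Deterministic antibody-like complex with a contacting H3."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    parent_h3 = data.PARENT_H3
    L = len(parent_h3)

    # heavy chain dihedrals
    dih = []
    for i in range(len(_H_FW1)):  # 70..89
        if 10 <= i <= 13:
            dih.append(_TURN[i - 10])
        else:
            dih.append(_STRAND)
    dih += [_STRAND] * 3                      # 90..92
    dih += _h3_dihedrals(L, rng)              # H3
    dih += [_STRAND] * 3                      # 103..105
    dih += [_STRAND] * len(_H_FW2)            # 106..115
    h_labels = ([str(i) for i in range(70, 93)]
                + model_io.h3_labels(L)
                + [str(i) for i in range(103, 116)])
    h_seq = _H_FW1 + _H_FLANK_N + parent_h3 + _H_FLANK_C + _H_FW2
    atoms = _chain_records("H", h_labels, h_seq, dih)

    # light chain: hairpin, rigidly offset from the heavy chain
    l_dih = ([_STRAND] * 12 + _TURN + [_STRAND] * 12)[:len(_L_SEQ)]
    l_transform = (_rot([0, 0, 1], 180.0), np.array([-4.0, 14.0, -6.0]))
    atoms += _chain_records("L", [str(i) for i in range(1, 29)], _L_SEQ,
                            l_dih, transform=l_transform)

    annotation = toy_annotation(L)
    cx = model_io.AntibodyComplex(atoms, annotation, check_h3=False)
    # drop the (not yet built) antigen from the annotation check
    ab_keys = cx.residue_keys()
    cx = model_io.AntibodyComplex(atoms, annotation, check_h3=True)
    cx = grafting.place_side_chains(cx, ab_keys)

    antigen = _place_antigen(cx, rng)
    full = model_io.AntibodyComplex(
        cx.atoms + antigen, annotation, check_h3=True)
    # final pass over the graft region in the complete environment so a
    # self-graft reproduces the parental side chains exactly
    full = grafting.place_side_chains(
        full, full.graft_flank[:3] + full.h3_index_map + full.graft_flank[3:])
    full = grafting.form_stem_salt_bridge(full)
    if parent_contact_count(full) < MIN_PARENT_CONTACTS:
        raise RuntimeError("toy antigen placement failed the contact "
                           "guarantee")
    return full


def _place_antigen(cx, rng):
    """Build a rigid helical antigen and slide it onto the H3 tip."""
    # helix in local frame, side chains placed in isolation
    dih = [(-63.0, -42.0)] * len(_AG_SEQ)
    ag_atoms = _chain_records("A", [str(i) for i in range(1, len(_AG_SEQ)
                                                          + 1)],
                              _AG_SEQ, dih)
    tmp = model_io.AntibodyComplex(
        ag_atoms, model_io.RegionAnnotation(
            {("A", a.residue_label): "ANTIGEN" for a in ag_atoms}),
        check_h3=False)
    tmp = grafting.place_side_chains(tmp, tmp.residue_keys())
    ag_xyz = tmp.coords()
    ag_center = ag_xyz.mean(axis=0)

    # H3 tip direction: from framework centroid through the loop tip
    h3_keys = set(cx.h3_index_map)
    tip_keys = set(cx.h3_index_map[2:-3]) or h3_keys
    tip_xyz = np.array([a.position for a in cx.atoms
                        if (a.chain_id, a.residue_label) in tip_keys])
    fw_xyz = np.array([a.position for a in cx.atoms
                       if (a.chain_id, a.residue_label) not in h3_keys])
    tip_c = tip_xyz.mean(axis=0)
    u = tip_c - fw_xyz.mean(axis=0)
    u /= np.linalg.norm(u)

    # helix principal axis -> perpendicular to the approach direction
    axis = np.linalg.svd(ag_xyz - ag_center)[2][0]
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)
    rot_align, _ = _align_vectors(axis, v)
    spin = _rotation_about(u, rng.uniform(0.0, 20.0))

    ab_xyz = cx.coords()
    ab_rad = np.array([rescfg.radius_of(a.element) for a in cx.atoms])
    ab_chg = np.array([rescfg.charge_of(a.residue_name, a.atom_name)
                       for a in cx.atoms])
    ag_rad = np.array([rescfg.radius_of(a.element) for a in tmp.atoms])
    ag_chg = np.array([rescfg.charge_of(a.residue_name, a.atom_name)
                       for a in tmp.atoms])
    tree = cKDTree(ab_xyz)

    def placement_energy(xyz):
        e = 0.0
        for i, js in enumerate(tree.query_ball_point(xyz, 8.0)):
            if not js:
                continue
            js = np.asarray(js, int)
            d = np.maximum(np.linalg.norm(ab_xyz[js] - xyz[i], axis=1),
                           1.0)
            rmin = ag_rad[i] + ab_rad[js]
            s6 = (rmin / d) ** 6
            e += float(np.clip(0.15 * (s6 ** 2 - 2 * s6), None,
                               5.0).sum())
            e += float((83.0 * ag_chg[i] * ab_chg[js] / d ** 2).sum())
        return e

    # choose the azimuth that complements the parental loop best, among
    # placements that keep the loop in contact with the antigen
    h3_tree = cKDTree(np.array([a.position for a in cx.atoms
                                if (a.chain_id, a.residue_label)
                                in h3_keys]))
    placed = fallback = None
    best_e = np.inf
    best_contacts = -1
    for extra_spin in np.arange(0.0, 360.0, 30.0):
        spin2 = _rotation_about(u, extra_spin)
        base = (ag_xyz - ag_center) @ rot_align.T @ spin2.T @ spin.T
        for offset in np.arange(3.0, 16.0, 0.25):
            xyz = base + tip_c + u * offset
            dmin, _ = tree.query(xyz, k=1)
            if dmin.min() >= 3.2:
                contacts = int(sum(len(js) for js in
                                   h3_tree.query_ball_point(xyz, 4.5)))
                if contacts > best_contacts:
                    best_contacts = contacts
                    fallback = xyz
                if contacts >= MIN_PARENT_CONTACTS:
                    e = placement_energy(xyz)
                    if e < best_e:
                        best_e = e
                        placed = xyz
                break
    if placed is None:
        placed = fallback
    if placed is None:
        raise RuntimeError("could not place toy antigen")
    placed = _settle_antigen(placed, ab_xyz, ab_rad, ab_chg,
                             ag_rad, ag_chg, tree)
    out = []
    for a, p in zip(tmp.atoms, placed):
        rec = a.copy()
        rec.position = np.array(p, float)
        out.append(rec)
    return out


def _settle_antigen(xyz0, ab_xyz, ab_rad, ab_chg, ag_rad, ag_chg, tree):
    """Rigid-body relaxation of the antigen pose against the antibody:
    Lennard-Jones, screened Coulomb and a donor/acceptor distance well.
    Makes the epitope genuinely complementary to the parental loop."""
    from scipy.optimize import minimize as _sp_min
    from scipy.spatial.transform import Rotation

    center = xyz0.mean(axis=0)

    def energy(params):
        rotvec, trans = params[:3], params[3:]
        R = Rotation.from_rotvec(rotvec).as_matrix()
        xyz = (xyz0 - center) @ R.T + center + trans
        e = 0.0
        for i, js in enumerate(tree.query_ball_point(xyz, 8.0)):
            if not js:
                continue
            js = np.asarray(js, int)
            d = np.maximum(np.linalg.norm(ab_xyz[js] - xyz[i], axis=1),
                           1.0)
            rmin = ag_rad[i] + ab_rad[js]
            s6 = (rmin / d) ** 6
            e += float(np.clip(0.15 * (s6 ** 2 - 2 * s6), None, 5.0).sum())
            e += float((83.0 * ag_chg[i] * ab_chg[js] / d ** 2).sum())
            polar = (np.abs(ab_chg[js]) > 0.2) & (abs(ag_chg[i]) > 0.2) \
                & (ag_chg[i] * ab_chg[js] < 0)
            e += float((-1.5 * np.exp(-((d[polar] - 2.9) / 0.4) ** 2)).sum())
        return e

    res = _sp_min(energy, np.zeros(6), method="Powell",
                  options={"maxiter": 400, "xtol": 1e-3})
    R = Rotation.from_rotvec(res.x[:3]).as_matrix()
    return (xyz0 - center) @ R.T + center + res.x[3:]


def _align_vectors(a, b):
    """Rotation taking direction a to direction b."""
    from scipy.spatial.transform import Rotation
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    rot, rssd = Rotation.align_vectors(b[None], a[None])
    return rot.as_matrix(), rssd


def _rotation_about(axis, deg):
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(deg) * axis).as_matrix()


def parent_contact_count(cx, cutoff=CONTACT_CUTOFF) -> int:
    """Heavy-atom contacts between the H3 loop and the antigen."""
    h3 = set(cx.h3_index_map)
    h3_xyz = np.array([a.position for a in cx.atoms
                       if (a.chain_id, a.residue_label) in h3])
    ag_xyz = np.array([a.position for a in cx.atoms
                       if cx.region(a.chain_id, a.residue_label)
                       == "ANTIGEN"])
    if not len(ag_xyz):
        return 0
    tree = cKDTree(ag_xyz)
    return int(sum(len(js) for js in
                   tree.query_ball_point(h3_xyz, cutoff)))


# -- libraries --------------------------------------------------------------


def make_h3_library(spec: FixtureSpec = None):
    """Cysteine-free H3 library: parent, minimal-H3 control, then random
    sequences with panel-derived composition and lengths cycling through
    the requested range."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.h3_length_range
    freqs = data.design_residue_frequencies()
    freqs.pop("C", None)
    letters = sorted(freqs)
    p = np.array([freqs[ch] for ch in letters])
    p /= p.sum()

    entries = []
    parent = data.PARENT_H3
    control = parent[:3] + "G" + parent[-3:]
    if lo <= len(parent) <= hi:
        entries.append((data.PARENT_ID, parent))
    if lo <= len(control) <= hi:
        entries.append((data.MINH3_ID, control))
    lengths = list(range(lo, hi + 1))
    i = 0
    while len(entries) < spec.library_size:
        L = lengths[i % len(lengths)]
        seq = "".join(rng.choice(letters, size=L, p=p))
        i += 1
        entries.append((f"{L:02d}_{i:04d}", seq))
    return entries[:spec.library_size]


def make_score_table(spec: FixtureSpec = None):
    """Synthetic score table reproducing the size bias of binding scores:
    score = base − slope·length + Normal(0, noise_sd)."""
    import pandas as pd

    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed + 17)
    entries = make_h3_library(spec)
    rows = []
    for cid, seq in entries:
        L = len(seq)
        total = -250.0 - spec.length_bias_slope * L + rng.normal(
            0.0, spec.noise_sd)
        inter = -10.0 - spec.length_bias_slope * L / 3.0 + rng.normal(
            0.0, spec.noise_sd / 3.0)
        rows.append((cid, L, total, inter))
    return pd.DataFrame(rows, columns=[
        "id", "length", "total_energy", "interaction_energy"])


# -- stem clusters ----------------------------------------------------------


def make_stem_clusters(spec: FixtureSpec = None, toy=None):
    """Three cluster representatives derived from the toy geometry with
    distinct stem sequences."""
    spec = spec or FixtureSpec()
    toy = toy if toy is not None else make_toy_complex(spec)
    c1 = stem_library.extract_template(toy, "c1", source_tag="toy")
    rng = np.random.default_rng(spec.seed + 7)
    c2 = _perturb_cluster(c1, rng, "c2", "ARG" + "YFDY")
    c3 = _perturb_cluster(c1, rng, "c3", "GRS" + "GMDV")
    return [c1, c2, c3]


def _perturb_cluster(c1, rng, cluster_id, stem_seq):
    """Rebuild the loop interior with jittered dihedrals, keeping the
    grafted stem residues fixed."""
    residues = [dict(r) for r in c1.residues]
    loop = residues[3:-3]
    m = len(loop) - 5  # interior between N-stem (2) and C-stem (3)
    anchor = loop[1]
    target = loop[-3]
    phis = rng.uniform(-150, -50, size=m + 1)
    psis = rng.uniform(-40, 160, size=m)
    segN, segCA, segC, gap = geometry.close_segment(
        (anchor["N"], anchor["CA"], anchor["C"]), 120.0, phis, psis,
        np.array([target["N"], target["CA"], target["C"]]),
        pivot_prev_psi=True)
    for i in range(m):
        next_n = segN[i + 1] if i + 1 < m else target["N"]
        loop[2 + i] = {"N": segN[i], "CA": segCA[i], "C": segC[i],
                       "O": geometry.place_carbonyl_oxygen(
                           segCA[i], segC[i], next_n)}
    loop[1] = dict(loop[1])
    loop[1]["O"] = geometry.place_carbonyl_oxygen(
        anchor["CA"], anchor["C"], segN[0] if m else target["N"])
    out = residues[:3] + loop + residues[-3:]
    return stem_library.StemTemplate(
        cluster_id=cluster_id, h3_length=c1.h3_length, residues=out,
        stem_sequence=stem_seq, source_tag="toy-perturbed")


def make_stem_library(spec: FixtureSpec = None, lengths=range(7, 17),
                      toy=None):
    clusters = make_stem_clusters(spec, toy=toy)
    return stem_library.library_from_clusters(clusters, lengths)


def write_fasta(entries, target):
    text = "".join(f">{cid}\n{seq}\n" for cid, seq in entries)
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


def read_fasta(source):
    from Bio import SeqIO
    import io as _io
    if hasattr(source, "read"):
        handle = source
    else:
        handle = _io.StringIO(source) if source.lstrip().startswith(">") \
            else open(source)
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
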