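"""Stem-template library: anchored H3 backbone fragments per (cluster,
length), sequence matching of candidate stems, and stem/tip partitions.

An H3 loop's stem is its structurally conserved flanks.  Templates keep the
first 2 and last 3 loop residues (plus the three framework anchor residues
on each side) from a cluster representative and bridge the remainder with a
poly-glycine linker closed by CCD.  Candidate sequences are matched to
templates by a BLOSUM62 log-odds profile over the 7 North stem positions
(first 3 + last 4); all templates within a retention window of the best
score are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from . import geometry
from . import model_io

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

MIN_LENGTH = 7
MAX_LENGTH = 30
DEFAULT_RETENTION_WINDOW = 1.7

_N_STEM = 2   # grafted N-stem residues
_C_STEM = 3   # grafted C-stem residues


@dataclass
class StemTemplate:
    """Backbone fragment covering the graft region (3 flank + L + 3 flank).

    ``residues`` is a list of dicts mapping backbone atom name (N, CA, C, O)
    to xyz; the first/last three entries are the framework anchors.
    """
    cluster_id: str
    h3_length: int
    residues: list
    stem_sequence: str = ""
    source_tag: str = ""

    @property
    def flank_n(self):
        return self.residues[:3]

    @property
    def flank_c(self):
        return self.residues[-3:]

    @property
    def loop(self):
        return self.residues[3:-3]

    def anchor_ca(self) -> np.ndarray:
        return np.array([r["CA"] for r in self.flank_n + self.flank_c])

    def backbone_ok(self, tol=0.08) -> bool:
        """Bond-length sanity over the fragment backbone."""
        for r in self.residues:
            if abs(np.linalg.norm(r["CA"] - r["N"]) - 1.46) > tol + 0.01:
                return False
            if abs(np.linalg.norm(r["C"] - r["CA"]) - 1.52) > tol + 0.01:
                return False
        for r1, r2 in zip(self.residues, self.residues[1:]):
            if abs(np.linalg.norm(r2["N"] - r1["C"]) - 1.33) > tol:
                return False
        return True


@dataclass
class StemMatch:
    template: StemTemplate
    alignment_score: float
    retained: bool


def stem_parts(h3_sequence: str):
    """Shortened stems actually grafted: first 2 and last 3 residues."""
    if len(h3_sequence) < 6:
        raise ValueError(
            f"H3 sequence too short for stem partition: {h3_sequence!r}")
    return h3_sequence[:_N_STEM], h3_sequence[-_C_STEM:]


def north_stem(h3_sequence: str) -> str:
    """The 7 stem positions used for sequence matching (first 3 + last 4)."""
    if len(h3_sequence) < 7:
        raise ValueError("H3 sequence shorter than the 7 stem positions")
    return h3_sequence[:3] + h3_sequence[-4:]


def extract_template(cx, cluster_id="self", source_tag="") -> StemTemplate:
    """Lift the graft-region backbone of a complex into a StemTemplate."""
    keys = cx.graft_flank[:3] + cx.h3_index_map + cx.graft_flank[3:]
    residues = []
    for key in keys:
        residues.append({n: np.array(cx.get_atom(*key, n).position)
                         for n in ("N", "CA", "C", "O")
                         if cx.has_atom(*key, n)})
    return StemTemplate(cluster_id=cluster_id, h3_length=cx.h3_length,
                        residues=residues,
                        stem_sequence=north_stem(cx.h3_sequence()),
                        source_tag=source_tag or "extracted")


def build_template(cluster_backbone: StemTemplate,
                   target_length: int) -> StemTemplate:
    """Template of a new loop length from a cluster representative.

    The framework anchors, the first 2 and the last 3 loop residues keep the
    cluster coordinates; the middle is a poly-glycine linker built extended
    and CCD-closed onto the C-stem.  Lengths 7–30 are supported.
    """
    if not MIN_LENGTH <= target_length <= MAX_LENGTH:
        raise ValueError(
            f"target length {target_length} outside supported range "
            f"[{MIN_LENGTH}, {MAX_LENGTH}]")
    loop = cluster_backbone.loop
    if len(loop) < _N_STEM + _C_STEM:
        raise ValueError("cluster backbone provides too few loop residues")
    if target_length == len(loop):
        # the representative already has this length: its own loop is the
        # template
        return StemTemplate(
            cluster_id=cluster_backbone.cluster_id,
            h3_length=target_length,
            residues=[dict(r) for r in cluster_backbone.residues],
            stem_sequence=cluster_backbone.stem_sequence,
            source_tag=f"{cluster_backbone.source_tag}|L{target_length}")
    n_part = [dict(r) for r in loop[:_N_STEM]]
    c_part = [dict(r) for r in loop[-_C_STEM:]]
    m = target_length - _N_STEM - _C_STEM
    anchor = n_part[-1]
    prev_triad = (anchor["N"], anchor["CA"], anchor["C"])
    target = c_part[0]
    target_triad = np.array([target["N"], target["CA"], target["C"]])

    if m == 0:
        gap = 0.0
        middle = []
    else:
        best = None
        starts = [(np.full(m + 1, -139.0) + 12.0 * k,
                   np.full(m, 135.0) - 15.0 * k) for k in range(4)]
        rng = np.random.default_rng(1234 + target_length)
        starts += [(rng.uniform(-150, -50, m + 1),
                    rng.uniform(-45, 160, m)) for _ in range(8)]
        for phis, psis in starts:
            segN, segCA, segC, gap = geometry.close_segment(
                prev_triad, 120.0, phis, psis, target_triad,
                pivot_prev_psi=True)
            if best is None or gap < best[-1]:
                best = (segN, segCA, segC, gap)
            if gap <= 0.03:
                break
        segN, segCA, segC, gap = best
        if gap > 0.03:
            # short linkers cannot always meet the rigid C-stem triad at
            # ideal geometry; let the bond angles flex to absorb the rest
            segN, segCA, segC, ok = _relax_bridge(
                prev_triad, segN, segCA, segC, target_triad)
            gap = 0.0 if ok else gap
        if gap > 0.5:
            raise ValueError(
                f"cannot close a {m}-residue linker for length "
                f"{target_length} (gap {gap:.2f} Å)")
        middle = []
        for i in range(m):
            next_n = segN[i + 1] if i + 1 < m else target["N"]
            middle.append({
                "N": segN[i], "CA": segCA[i], "C": segC[i],
                "O": geometry.place_carbonyl_oxygen(segCA[i], segC[i],
                                                    next_n)})
        # anchor O follows the (possibly pivoted) psi toward the new chain
        n_part[-1] = dict(n_part[-1])
        n_part[-1]["O"] = geometry.place_carbonyl_oxygen(
            anchor["CA"], anchor["C"], segN[0])

    residues = (list(cluster_backbone.flank_n) + n_part + middle + c_part
                + list(cluster_backbone.flank_c))
    stem = cluster_backbone.stem_sequence
    return StemTemplate(
        cluster_id=cluster_backbone.cluster_id, h3_length=target_length,
        residues=residues, stem_sequence=stem,
        source_tag=f"{cluster_backbone.source_tag}|L{target_length}")


def _relax_bridge(prev_triad, segN, segCA, segC, target_triad,
                  bond_tol=0.08):
    """Cartesian relaxation of a bridge segment between fixed anchor triads.

    Bond lengths are held near ideal while backbone angles absorb the
    closure residual.  Returns (N, CA, C, ok) where ok means all bonds ended
    within tolerance of ideal.
    """
    from scipy.optimize import minimize as _sp_min

    from . import forcefield as ff

    m = len(segN)
    # layout: anchor N,CA,C | seg (N,CA,C)*m | target N,CA,C
    fixed_pre = np.asarray(prev_triad, float)
    fixed_post = np.asarray(target_triad, float)
    X0 = np.concatenate([fixed_pre,
                         np.stack([segN, segCA, segC], axis=1).reshape(-1, 3),
                         fixed_post])
    nfree = 3 * m

    def tri(i):  # residue i in 0..m+1 -> (N, CA, C) indices
        return 3 * i, 3 * i + 1, 3 * i + 2

    bonds = []
    angles = []
    torsions = []
    for i in range(m + 1):
        _n1, ca1, c1 = tri(i)
        n2, ca2, c2 = tri(i + 1)
        bonds.append((c1, n2, geometry.BOND_C_N))
        angles.append((ca1, c1, n2, geometry.ANGLE_CA_C_N))
        angles.append((c1, n2, ca2, geometry.ANGLE_C_N_CA))
        torsions.append((ca1, c1, n2, ca2, 180.0))
    for i in range(1, m + 1):
        n, ca, c = tri(i)
        bonds.append((n, ca, geometry.BOND_N_CA))
        bonds.append((ca, c, geometry.BOND_CA_C))
        angles.append((n, ca, c, geometry.ANGLE_N_CA_C))
    bi = np.array([(a, b) for a, b, _ in bonds], int)
    br = np.array([r for *_ab, r in bonds], float)
    ai = np.array([(a, b, c) for a, b, c, _ in angles], int)
    at = np.deg2rad([t for *_abc, t in angles])
    ti = np.array([(a, b, c, d) for a, b, c, d, _ in torsions], int)
    tt = np.deg2rad([t for *_abcd, t in torsions])

    def fun(x):
        X = X0.copy()
        X[3:3 + m * 3] = x.reshape(-1, 3)
        d = X[bi[:, 0]] - X[bi[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - br
        e = float(np.sum(400.0 * dr ** 2))
        G = np.zeros_like(X)
        f = (800.0 * dr / np.maximum(r, 1e-9))[:, None] * d
        np.add.at(G, bi[:, 0], f)
        np.add.at(G, bi[:, 1], -f)
        ea, ga = ff._angle_terms(X, ai, at, 20.0)
        et, gt = ff._torsion_terms(X, ti, tt, 10.0)
        return e + ea + et, (G + ga + gt)[3:3 + m * 3].ravel()

    res = _sp_min(fun, X0[3:3 + m * 3].ravel(), jac=True, method="L-BFGS-B",
                  options={"maxiter": 400, "gtol": 1e-4})
    X = X0.copy()
    X[3:3 + m * 3] = res.x.reshape(-1, 3)
    d = np.linalg.norm(X[bi[:, 0]] - X[bi[:, 1]], axis=1)
    ok = bool(np.all(np.abs(d - br) <= bond_tol))
    seg = X[3:3 + m * 3].reshape(m, 3, 3)
    return seg[:, 0], seg[:, 1], seg[:, 2], ok


def profile_score(stem_a: str, stem_b: str) -> float:
    """BLOSUM62 log-odds profile score over the 7 stem positions."""
    return float(sum(_BLOSUM62[a][b] for a, b in zip(stem_a, stem_b)))


def match_stems(h3_sequence: str, library,
                retention_window: float = DEFAULT_RETENTION_WINDOW):
    """Score all same-length templates; retain those within the window of
    the best.  At least one match is always retained."""
    length = len(h3_sequence)
    candidates = [t for t in library if t.h3_length == length]
    if not candidates:
        raise ValueError(f"no stem template of length {length} in library")
    query = north_stem(h3_sequence)
    scored = [(profile_score(query, t.stem_sequence), t) for t in candidates]
    best = max(s for s, _t in scored)
    matches = [StemMatch(t, s, bool(best - s <= retention_window))
               for s, t in sorted(scored, key=lambda x: -x[0])]
    return matches


def library_from_clusters(cluster_backbones, lengths=range(7, 17)):
    """Expand cluster representatives into a (cluster, length) template
    library; lengths a cluster cannot close are skipped with a warning."""
    library = []
    for cb in cluster_backbones:
        for L in lengths:
            try:
                library.append(build_template(cb, L))
            except ValueError as exc:
                warnings.warn(
                    f"cluster {cb.cluster_id}: length {L} skipped ({exc})")
    return library


def read_template_dir(path):
    """Load templates from a directory with a ``manifest.tsv`` of
    ``cluster_id  length  file`` rows of PDB fragments (graft region,
    backbone atoms), plus optional 4th column stem sequence."""
    import os

    library = []
    with open(os.path.join(path, "manifest.tsv")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            cluster_id, length, fname = parts[0], int(parts[1]), parts[2]
            stem_seq = parts[3] if len(parts) > 3 else ""
            with open(os.path.join(path, fname)) as pf:
                text = pf.read()
            residues, seq = _fragment_residues(text)
            library.append(StemTemplate(
                cluster_id=cluster_id, h3_length=length, residues=residues,
                stem_sequence=stem_seq or seq, source_tag=fname))
    return library


def _fragment_residues(pdb_text):
    import gemmi

    from . import residues as rescfg
    st = gemmi.read_pdb_string(pdb_text)
    model = st[0]
    residues = []
    one = []
    for chain in model:
        for res in chain:
            d = {}
            for atom in res:
                if atom.name in ("N", "CA", "C", "O"):
                    d[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
            residues.append(d)
            one.append(rescfg.AA3_TO_1.get(res.name, "X"))
    seq = "".join(one)
    loop_seq = seq[3:-3]
    stem = loop_seq[:3] + loop_seq[-4:] if len(loop_seq) >= 7 else ""
    return residues, stem
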