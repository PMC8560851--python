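"""Geometric primitives: internal-coordinate placement, dihedrals, rigid
superposition (Kabsch SVD with reflection correction) and cyclic coordinate
descent (CCD) loop closure."""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (Engh-Huber-like values, Å and degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def _unit(v):
    return v / np.linalg.norm(v)


def _cross3(a, b):
    """Cross product of 3-vectors without numpy's axis machinery."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _cross_rows(u, m):
    """Cross of a single 3-vector u with each row of (n, 3) array m."""
    return np.stack((u[1] * m[:, 2] - u[2] * m[:, 1],
                     u[2] * m[:, 0] - u[0] * m[:, 2],
                     u[0] * m[:, 1] - u[1] * m[:, 0]), axis=1)


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: the new atom D is bonded to c, with angle(b, c, D) and
    dihedral(a, b, c, D) as given (degrees)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = _unit(np.asarray(c, float) - b)
    n = _unit(_cross3(np.asarray(b, float) - a, bc))
    m = _cross3(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(chi),
                  bond * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians (IUPAC convention)."""
    b0 = np.asarray(p0, float) - p1
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(_cross3(b1u, v), w)
    return float(np.arctan2(y, x))


def angle(p0, p1, p2) -> float:
    """Bond angle at p1 in radians."""
    u = _unit(np.asarray(p0, float) - p1)
    v = _unit(np.asarray(p2, float) - p1)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def wrap_angle(a):
    """Wrap angle(s) in radians to (-pi, pi]."""
    return np.arctan2(np.sin(a), np.cos(a))


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` approximates ``reference``.
    The rotation is always proper (det = +1).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("at least 3 points required for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid ** 2).sum() / len(P)))
    return R, t, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def rotate_about_axis(coords, p1, p2, theta, indices=None):
    """Rotate selected rows of ``coords`` by ``theta`` (radians) about the
    axis through p1 -> p2.  Returns a new array."""
    coords = np.array(coords, float)
    u = _unit(np.asarray(p2, float) - p1)
    sel = slice(None) if indices is None else indices
    r = coords[sel] - p1
    par = np.outer(r @ u, u)
    perp = r - par
    cross = np.cross(np.broadcast_to(u, perp.shape), perp)
    coords[sel] = p1 + par + perp * np.cos(theta) + cross * np.sin(theta)
    return coords


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is expected to be present
    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


@_njit
def _ccd_kernel(coords, piv_ia, piv_ib, piv_start, end_idx, targets,
                max_iter, tol):  # pragma: no cover - exercised via ccd_close
    n = coords.shape[0]
    n_end = end_idx.shape[0]
    gap = 0.0
    for e in range(n_end):
        dx = coords[end_idx[e], 0] - targets[e, 0]
        dy = coords[end_idx[e], 1] - targets[e, 1]
        dz = coords[end_idx[e], 2] - targets[e, 2]
        gap += dx * dx + dy * dy + dz * dz
    gap = np.sqrt(gap / n_end)
    prev_gap = 1e30
    it = 0
    while gap > tol and it < max_iter:
        for p in range(piv_ia.shape[0]):
            ia, ib, start = piv_ia[p], piv_ib[p], piv_start[p]
            ox, oy, oz = coords[ib, 0], coords[ib, 1], coords[ib, 2]
            ux = ox - coords[ia, 0]
            uy = oy - coords[ia, 1]
            uz = oz - coords[ia, 2]
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= un
            uy /= un
            uz /= un
            a_sum = 0.0
            b_sum = 0.0
            used = 0
            for e in range(n_end):
                k = end_idx[e]
                if k < start:
                    continue
                used += 1
                rx = coords[k, 0] - ox
                ry = coords[k, 1] - oy
                rz = coords[k, 2] - oz
                proj = rx * ux + ry * uy + rz * uz
                fx = rx - proj * ux
                fy = ry - proj * uy
                fz = rz - proj * uz
                dx = targets[e, 0] - ox - proj * ux
                dy = targets[e, 1] - oy - proj * uy
                dz = targets[e, 2] - oz - proj * uz
                a_sum += fx * dx + fy * dy + fz * dz
                cx = uy * fz - uz * fy
                cy = uz * fx - ux * fz
                cz = ux * fy - uy * fx
                b_sum += cx * dx + cy * dy + cz * dz
            if used == 0:
                continue
            theta = np.arctan2(b_sum, a_sum)
            if abs(theta) < 1e-12:
                continue
            ct = np.cos(theta)
            st = np.sin(theta)
            for k in range(start, n):
                rx = coords[k, 0] - ox
                ry = coords[k, 1] - oy
                rz = coords[k, 2] - oz
                proj = rx * ux + ry * uy + rz * uz
                fx = rx - proj * ux
                fy = ry - proj * uy
                fz = rz - proj * uz
                cx = uy * fz - uz * fy
                cy = uz * fx - ux * fz
                cz = ux * fy - uy * fx
                coords[k, 0] = ox + proj * ux + fx * ct + cx * st
                coords[k, 1] = oy + proj * uy + fy * ct + cy * st
                coords[k, 2] = oz + proj * uz + fz * ct + cz * st
        gap = 0.0
        for e in range(n_end):
            dx = coords[end_idx[e], 0] - targets[e, 0]
            dy = coords[end_idx[e], 1] - targets[e, 1]
            dz = coords[end_idx[e], 2] - targets[e, 2]
            gap += dx * dx + dy * dy + dz * dz
        gap = np.sqrt(gap / n_end)
        it += 1
        if prev_gap - gap < 1e-4:
            break
        prev_gap = gap
    return gap, it


def ccd_close(coords, pivots, end_indices, targets,
              max_iter=100, tol=0.08):
    """Cyclic coordinate descent closure on a chain.

    coords: (n, 3) mobile chain atoms (modified copy returned).
    pivots: list of (axis_a_idx, axis_b_idx, downstream_start) — rotation
        about the bond axis_a -> axis_b moves the suffix
        ``coords[downstream_start:]`` (chains are laid out in order).
    end_indices: indices of the end-effector atoms within coords.
    targets: (len(end_indices), 3) fixed anchor positions.

    Returns (coords, gap, n_iter); gap is the RMSD of the end-effector atoms
    to their targets.  Stops early when progress stalls.
    """
    coords = np.array(coords, float)
    targets = np.ascontiguousarray(targets, float)
    end_indices = np.asarray(end_indices, np.int64)
    piv_ia = np.array([p[0] for p in pivots], np.int64)
    piv_ib = np.array([p[1] for p in pivots], np.int64)
    piv_start = np.array([p[2] for p in pivots], np.int64)
    gap, it = _ccd_kernel(coords, piv_ia, piv_ib, piv_start, end_indices,
                          targets, max_iter, tol)
    return coords, float(gap), int(it)


def build_chain(n_res, phis, psis, omega=180.0, start=None):
    """Build an ideal-geometry backbone of ``n_res`` residues.

    phis, psis: arrays of length n_res (degrees).  phi of residue 0 and psi
    of the last residue still shape the chain ends' C / next-N placement.
    Returns (N, CA, C) arrays each (n_res, 3).

    If ``start`` is given it must be a triad (N0, CA0, C0) for residue 0;
    the phi of residue 0 is then ignored for N/CA/C placement of residue 0
    itself but used for nothing else.
    """
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    if start is not None:
        N[0], CA[0], C[0] = start
    else:
        N[0] = np.array([0.0, 0.0, 0.0])
        CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
        # place C with the ideal N-CA-C angle in the xy plane
        th = np.deg2rad(180.0 - ANGLE_N_CA_C)
        C[0] = CA[0] + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phis[i])
    return N, CA, C


def close_segment(prev_triad, psi_prev, phis, psis, target_triad,
                  pivot_prev_psi=False, max_iter=150, tol=0.05):
    """Rebuild a backbone segment between fixed anchors and close it by CCD.

    prev_triad: (N, CA, C) of the fixed residue preceding the segment.
    psi_prev: psi of that anchor residue (degrees); a CCD pivot only if
        ``pivot_prev_psi``.
    phis: per-segment-residue phi plus the phi of the following residue
        (length m + 1, degrees).
    psis: per-segment-residue psi (length m, degrees).
    target_triad: fixed (N, CA, C) of the residue after the segment.

    Returns (N, CA, C) arrays of shape (m, 3) for the segment plus the
    closure gap (RMSD of the rebuilt next-residue triad vs the target).
    """
    m = len(psis)
    if len(phis) != m + 1:
        raise ValueError("need m+1 phi values for m segment residues")
    n_res = m + 2
    all_phis = np.concatenate([[0.0], phis])
    all_psis = np.concatenate([[psi_prev], psis, [0.0]])
    N, CA, C = build_chain(n_res, all_phis, all_psis, start=prev_triad)
    coords = np.empty((3 * n_res, 3))
    coords[0::3] = N
    coords[1::3] = CA
    coords[2::3] = C

    def idx(res, atom):  # atom: 0=N 1=CA 2=C
        return 3 * res + atom

    pivots = []
    if pivot_prev_psi:
        pivots.append((idx(0, 1), idx(0, 2), idx(1, 0)))
    for r in range(1, m + 1):
        pivots.append((idx(r, 0), idx(r, 1), idx(r, 2)))
        pivots.append((idx(r, 1), idx(r, 2), idx(r + 1, 0)))
    # phi of the following residue moves only its own C (the end effector)
    pivots.append((idx(m + 1, 0), idx(m + 1, 1), idx(m + 1, 2)))
    end_indices = [idx(m + 1, 0), idx(m + 1, 1), idx(m + 1, 2)]
    coords, gap, _it = ccd_close(coords, pivots, end_indices,
                                 np.asarray(target_triad, float),
                                 max_iter=max_iter, tol=tol)
    segN = coords[[idx(r, 0) for r in range(1, m + 1)]]
    segCA = coords[[idx(r, 1) for r in range(1, m + 1)]]
    segC = coords[[idx(r, 2) for r in range(1, m + 1)]]
    return segN, segCA, segC, gap


def place_carbonyl_oxygen(ca, c, next_n):
    """Carbonyl O in the peptide plane, trans to the next amide nitrogen."""
    return place_atom(next_n, ca, c, BOND_C_O, ANGLE_CA_C_O, 180.0)


def terminal_oxygen(n, ca, c, psi_deg=120.0):
    """O for a chain-terminal residue (no next N): place from psi."""
    return place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi_deg)
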