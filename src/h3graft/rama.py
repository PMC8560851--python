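"""Backbone dihedral propensity model.

A small mixture-of-Gaussians Ramachandran density with separate maps for
glycine, proline and all other residues.  It serves three roles: sampling
loop dihedrals, a -log propensity term in the total-energy score, and a
core/allowed/generous/disallowed classification for the backbone-quality
filter.  Class boundaries are relative-density thresholds on the map.
"""

from __future__ import annotations

import numpy as np

# (phi0, psi0, sigma_phi, sigma_psi, weight), degrees
_BASINS = {
    "GENERAL": [(-120.0, 130.0, 30.0, 25.0, 0.40),
                (-65.0, 145.0, 20.0, 20.0, 0.20),
                (-63.0, -43.0, 17.0, 17.0, 0.32),
                (57.0, 40.0, 15.0, 15.0, 0.08)],
    "GLY": [(-100.0, 140.0, 35.0, 30.0, 0.25),
            (100.0, -140.0, 35.0, 30.0, 0.25),
            (-63.0, -40.0, 20.0, 20.0, 0.20),
            (63.0, 40.0, 20.0, 20.0, 0.20),
            (180.0, 180.0, 35.0, 35.0, 0.10)],
    "PRO": [(-65.0, 150.0, 12.0, 20.0, 0.55),
            (-65.0, -30.0, 12.0, 17.0, 0.45)],
}

# relative-density thresholds for the classification raster
_THRESHOLDS = (("core", 0.30), ("allowed", 0.03), ("generous", 0.003))


def _map_for(res_name: str) -> str:
    if res_name == "GLY":
        return "GLY"
    if res_name == "PRO":
        return "PRO"
    return "GENERAL"


def _wrap_deg(x):
    return (np.asarray(x, float) + 180.0) % 360.0 - 180.0


def density(phi, psi, res_name: str = "ALA"):
    """Unnormalized mixture density at (phi, psi) in degrees."""
    total = 0.0
    for p0, s0, sp, ss, w in _BASINS[_map_for(res_name)]:
        dp = _wrap_deg(np.asarray(phi) - p0) / sp
        ds = _wrap_deg(np.asarray(psi) - s0) / ss
        total = total + w * np.exp(-0.5 * (dp ** 2 + ds ** 2)) / (sp * ss)
    return total


_PEAK = {m: None for m in _BASINS}
_MEAN = {m: None for m in _BASINS}


def _grid_stats(map_name: str):
    if _PEAK[map_name] is None:
        grid = np.arange(-180.0, 180.0, 2.0)
        pp, ss = np.meshgrid(grid, grid)
        name = {"GENERAL": "ALA", "GLY": "GLY", "PRO": "PRO"}[map_name]
        d = density(pp, ss, name)
        _PEAK[map_name] = float(np.max(d))
        _MEAN[map_name] = float(np.mean(d))
    return _PEAK[map_name], _MEAN[map_name]


def _peak(map_name: str) -> float:
    return _grid_stats(map_name)[0]


def classify(phi_deg: float, psi_deg: float, res_name: str = "ALA") -> str:
    """Classify a (phi, psi) pair as core/allowed/generous/disallowed."""
    rel = float(density(phi_deg, psi_deg, res_name)) / _peak(
        _map_for(res_name))
    for label, thr in _THRESHOLDS:
        if rel > thr:
            return label
    return "disallowed"


def log_propensity(phi_deg: float, psi_deg: float,
                   res_name: str = "ALA") -> float:
    """Log density relative to the map's own mean density, so the term is
    comparable across residue types (no composition bias)."""
    m = _map_for(res_name)
    _pk, mean = _grid_stats(m)
    return float(np.log(density(phi_deg, psi_deg, res_name) / mean + 1e-12))


def sample(rng: np.random.Generator, res_name: str = "ALA"):
    """Draw one (phi, psi) pair (degrees) from the propensity map."""
    basins = _BASINS[_map_for(res_name)]
    weights = np.array([b[4] for b in basins])
    k = rng.choice(len(basins), p=weights / weights.sum())
    p0, s0, sp, ss, _w = basins[k]
    phi = _wrap_deg(rng.normal(p0, sp))
    psi = _wrap_deg(rng.normal(s0, ss))
    return float(phi), float(psi)
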