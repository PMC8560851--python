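"""Published experimental panel for the bH1–VEGF CDR-H3 redesign campaign.

The parental bH1 Fab binds VEGF-A (complex PDB 3BDY).  Sixteen redesigned H3
loops plus a minimal-H3 control (stem residues bridged by one glycine) were
produced and characterized; four designs were co-crystallized (PDB 7KEZ,
7KF0, 7KF1, 7KF2).  The tables below carry the reported screen ranking
(length-stratified composite Z-scores, library-wide ranks for the
total-energy and interaction-energy tracks, merged Z rank) and the measured
dissociation constants.  They are inputs for the analysis/statistics layer
and for fixture composition sampling.
"""

from __future__ import annotations

import pandas as pd

PARENT_ID = "parent"
MINH3_ID = "minH3"
PARENT_H3 = "SRWGGDGFYAMDY"
MINH3_H3 = "SRWGMDY"

# id, H3 sequence, length, composite Z (length-stratified),
# total-energy-track rank, interaction-track rank, merged Z rank
_DESIGNS = [
    ("16_0325", "ARGGAVAGTGVYYFDY", 16, -1.71, 153, 13, 41),
    ("14_0112", "AKGGSSSGPYHFEY", 14, -1.79, 296, 5, 35),
    ("14_0472", "ARGIAVAGAYYFDY", 14, -2.09, 41, 36, 14),
    ("13_0346", "ARGGSFYYYYMDV", 13, -1.81, 212, 181, 34),
    ("16_0102", "AKGWEGTTVTLTPVDY", 16, -1.56, 90, 105, 79),
    ("15_0485", "ARHGVRGYYYYYMDV", 15, -2.07, 33, 30, 18),
    ("14_0905", "VRGGYLRDYYGMDV", 14, -1.94, 122, 49, 27),
    ("14_0130", "AKLGIGYYYYGMDV", 14, -2.46, 8, 20, 3),
    ("14_0822", "GRSGPRLGMYYFDF", 14, -1.99, 68, 39, 25),
    ("12_0327", "ARGRKYSSSFDY", 12, -1.60, 746, 144, 68),
    ("14_0480", "ARGLERSGNYYLDY", 14, -2.08, 28, 75, 15),
    ("14_0129", "AKLGGQGSYYHFDY", 14, -2.08, 72, 10, 16),
    ("16_0460", "ARPSGGSRSWLYYFDY", 16, -1.68, 5, 533, 47),
    ("14_0490", "ARGNEAGYYYGMDV", 14, -1.70, 128, 92, 42),
    ("14_0622", "ARNGGDSYSGYFQH", 14, -1.70, 310, 16, 43),
    ("14_0688", "ARSGRDAYNYYFDS", 14, -1.66, 562, 21, 54),
]
_PARENT_ROW = (PARENT_ID, PARENT_H3, 13, -2.55, 80, 18, 1)

# id, K_D (nM), censored (">" lower bound), crystallized PDB code or None
_KD = [
    (MINH3_ID, 16000.0, False, None),
    (PARENT_ID, 100.0, False, "3BDY"),
    ("16_0325", 8.0, False, "7KEZ"),
    ("14_0112", 8.0, False, None),
    ("14_0472", 59000.0, False, None),
    ("13_0346", 80.0, False, "7KF0"),
    ("16_0102", 50000.0, False, None),
    ("15_0485", 310.0, False, None),
    ("14_0905", 5000.0, False, None),
    ("14_0130", 2800.0, False, "7KF1"),
    ("14_0822", 50000.0, True, None),
    ("12_0327", 1600.0, False, "7KF2"),
    ("14_0480", 2720.0, False, None),
    ("14_0129", 3480.0, False, None),
    ("16_0460", 4500.0, False, None),
    ("14_0490", 3590.0, False, None),
    ("14_0622", 4970.0, False, None),
    ("14_0688", 3600.0, False, None),
]


def design_panel(include_parent: bool = True) -> pd.DataFrame:
    rows = ([_PARENT_ROW] if include_parent else []) + _DESIGNS
    return pd.DataFrame(rows, columns=[
        "id", "sequence", "length", "z_score",
        "rank_total", "rank_interaction", "rank_z"])


def kd_panel() -> pd.DataFrame:
    return pd.DataFrame(_KD, columns=["id", "kd_nM", "censored", "pdb"])


def design_residue_frequencies() -> dict:
    """One-letter residue frequencies over the design panel H3 sequences
    (cysteine-free by construction)."""
    counts = {}
    for _id, seq, *_rest in _DESIGNS + [_PARENT_ROW]:
        for ch in seq:
            counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    return {ch: c / total for ch, c in sorted(counts.items())}
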