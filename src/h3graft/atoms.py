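"""Flat numpy views over AntibodyComplex atoms for fast energetics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import residues as rescfg


@dataclass
class AtomTable:
    index: np.ndarray        # indices into the source complex atom list
    coords: np.ndarray       # (n, 3)
    radius: np.ndarray
    charge: np.ndarray
    donor: np.ndarray        # bool
    acceptor: np.ndarray     # bool
    is_backbone: np.ndarray  # bool
    res_ordinal: np.ndarray  # global residue ordinal in the complex
    res_name: np.ndarray     # object
    atom_name: np.ndarray    # object
    element: np.ndarray      # object
    chain: np.ndarray        # object
    label: np.ndarray        # object

    def __len__(self):
        return len(self.coords)

    def subset(self, mask) -> "AtomTable":
        return AtomTable(*[getattr(self, f)[mask] if getattr(self, f).ndim
                           else getattr(self, f)
                           for f in ("index", "coords", "radius", "charge",
                                     "donor", "acceptor", "is_backbone",
                                     "res_ordinal", "res_name", "atom_name",
                                     "element", "chain", "label")])


def atom_table(cx, residue_keys=None) -> AtomTable:
    """Build an AtomTable for the whole complex or a residue-key subset."""
    ordinals = {key: i for i, key in enumerate(cx.residue_keys())}
    key_set = None if residue_keys is None else set(residue_keys)
    rows = []
    for i, a in enumerate(cx.atoms):
        key = (a.chain_id, a.residue_label)
        if key_set is not None and key not in key_set:
            continue
        rows.append((i, a, key))
    n = len(rows)
    tab = AtomTable(
        index=np.empty(n, int), coords=np.empty((n, 3), float),
        radius=np.empty(n, float), charge=np.empty(n, float),
        donor=np.empty(n, bool), acceptor=np.empty(n, bool),
        is_backbone=np.empty(n, bool), res_ordinal=np.empty(n, int),
        res_name=np.empty(n, object), atom_name=np.empty(n, object),
        element=np.empty(n, object), chain=np.empty(n, object),
        label=np.empty(n, object))
    for j, (i, a, key) in enumerate(rows):
        tab.index[j] = i
        tab.coords[j] = a.position
        tab.radius[j] = rescfg.radius_of(a.element)
        tab.charge[j] = rescfg.charge_of(a.residue_name, a.atom_name)
        tab.donor[j] = rescfg.is_donor(a.residue_name, a.atom_name)
        tab.acceptor[j] = rescfg.is_acceptor(a.residue_name, a.atom_name)
        tab.is_backbone[j] = a.is_backbone
        tab.res_ordinal[j] = ordinals[key]
        tab.res_name[j] = a.residue_name
        tab.atom_name[j] = a.atom_name
        tab.element[j] = a.element
        tab.chain[j] = a.chain_id
        tab.label[j] = a.residue_label
    return tab
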