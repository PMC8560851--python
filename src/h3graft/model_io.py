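"""Annotated antibody–antigen structures: reading, preparation, writing.

Structures are handled heavy-atom-only.  Regions come from a user-supplied
tab-separated annotation table (``chain  residue_label  region``) with the
fixed vocabulary {FR, H1, H2, H3, L1, L2, L3, ANTIGEN}; CDR delineation is
IMGT by convention.  The H3 loop uses the internal coordinate convention
s[1] ↔ H93 … s[L] ↔ H102, with insertion codes on residue 100 once the loop
exceeds 10 residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import residues as rescfg

REGIONS = ("FR", "H1", "H2", "H3", "L1", "L2", "L3", "ANTIGEN")
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_METAL_ELEMENTS = {"NA", "MG", "K", "CA", "ZN", "FE", "MN", "CU", "NI", "CO",
                   "CD", "HG"}
_HALOGEN_ELEMENTS = {"F", "CL", "BR", "I"}


class AnnotationError(ValueError):
    pass


@dataclass
class AtomRecord:
    chain_id: str
    residue_label: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in ("N", "CA", "C", "O")

    def copy(self) -> "AtomRecord":
        return replace(self, position=np.array(self.position, float))


@dataclass
class RegionAnnotation:
    region_of: dict
    cdr_definition: str = "IMGT"

    @classmethod
    def from_tsv(cls, source) -> "RegionAnnotation":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = source
        mapping = {}
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise AnnotationError(f"line {ln}: expected 3 columns")
            chain, label, region = parts
            if region not in REGIONS:
                raise AnnotationError(
                    f"line {ln}: unknown region {region!r}")
            mapping[(chain, label)] = region
        return cls(mapping)

    def to_tsv(self) -> str:
        return "\n".join(f"{c}\t{l}\t{r}"
                         for (c, l), r in self.region_of.items()) + "\n"

    def region(self, chain: str, label: str):
        return self.region_of.get((chain, label))

    def chains(self):
        return {c for c, _ in self.region_of}


@dataclass
class PrepReport:
    copies_removed: int = 0
    waters_ions_removed: int = 0
    chain_breaks_capped: int = 0
    missing_sidechains_completed: int = 0


def h3_labels(length: int) -> list:
    """Residue labels for an H3 loop of the given length.

    s[1] ↔ 93 and s[L] ↔ 102; the last two positions are always 101 and 102;
    numbering runs 93..100 and overflows into insertion codes on 100.
    """
    if length < 3:
        raise ValueError("H3 length must be at least 3")
    body = length - 2
    labels = [str(93 + i) for i in range(min(body, 8))]
    for k in range(body - 8):
        labels.append("100" + chr(ord("A") + k))
    labels += ["101", "102"]
    return labels


class AntibodyComplex:
    """Atomic model with region annotation and H3 loop index mapping."""

    def __init__(self, atoms, annotation: RegionAnnotation,
                 disulfides=None, terminal_caps=None, check_h3=True):
        self.atoms = list(atoms)
        self.annotation = annotation
        self.disulfides = list(disulfides or [])
        self.terminal_caps = set(terminal_caps or ())
        self._reindex()
        if check_h3:
            self._build_h3_map()
        else:
            self.h3_index_map = []
            self.graft_flank = []

    # -- indexing ----------------------------------------------------------
    def _reindex(self):
        self._res_order = []
        self._res_atoms = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_label)
            if key not in self._res_atoms:
                self._res_atoms[key] = {}
                self._res_order.append(key)
            self._res_atoms[key][a.atom_name] = i

    def _build_h3_map(self):
        h3 = [(c, l) for (c, l) in self._res_order
              if self.annotation.region(c, l) == "H3"]
        if not h3:
            raise AnnotationError("no residues annotated H3")
        chains = {c for c, _ in h3}
        if len(chains) > 1:
            raise AnnotationError("H3 annotated on more than one chain: "
                                  + ", ".join(sorted(chains)))
        chain = h3[0][0]
        chain_res = [key for key in self._res_order if key[0] == chain]
        pos = [chain_res.index(key) for key in h3]
        if pos != list(range(pos[0], pos[0] + len(h3))):
            raise AnnotationError("H3 residues are not contiguous")
        self.h3_index_map = h3
        lo, hi = pos[0], pos[-1]
        if lo < 3 or hi + 3 >= len(chain_res):
            raise AnnotationError("H3 flanking framework residues missing")
        self.graft_flank = chain_res[lo - 3:lo] + chain_res[hi + 1:hi + 4]
        for key in self.graft_flank:
            have = self._res_atoms[key]
            if not all(n in have for n in ("N", "CA", "C", "O")):
                raise AnnotationError(
                    f"flank residue {key[0]}/{key[1]} lacks backbone atoms")

    # -- convenience -------------------------------------------------------
    def residue_keys(self):
        return list(self._res_order)

    def residue_name(self, chain, label):
        idx = self._res_atoms[(chain, label)]
        return self.atoms[next(iter(idx.values()))].residue_name

    def residue_atom_names(self, chain, label):
        return list(self._res_atoms[(chain, label)])

    def get_atom(self, chain, label, name) -> AtomRecord:
        return self.atoms[self._res_atoms[(chain, label)][name]]

    def has_atom(self, chain, label, name) -> bool:
        return name in self._res_atoms.get((chain, label), {})

    def atom_index(self, chain, label, name) -> int:
        return self._res_atoms[(chain, label)][name]

    def region(self, chain, label):
        return self.annotation.region(chain, label)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], float)

    def set_coords(self, xyz):
        for a, p in zip(self.atoms, np.asarray(xyz, float)):
            a.position = np.array(p, float)

    @property
    def h3_length(self) -> int:
        return len(self.h3_index_map)

    @property
    def h3_chain(self) -> str:
        return self.h3_index_map[0][0]

    def h3_sequence(self) -> str:
        return "".join(
            rescfg.AA3_TO_1.get(self.residue_name(c, l), "X")
            for c, l in self.h3_index_map)

    def chain_residues(self, chain):
        return [key for key in self._res_order if key[0] == chain]

    def copy(self) -> "AntibodyComplex":
        return AntibodyComplex(
            [a.copy() for a in self.atoms],
            RegionAnnotation(dict(self.annotation.region_of),
                             self.annotation.cdr_definition),
            disulfides=list(self.disulfides),
            terminal_caps=set(self.terminal_caps),
            check_h3=bool(self.h3_index_map))


# ---------------------------------------------------------------------------


def read_structure(pdb_source, annotation_source) -> AntibodyComplex:
    """Parse a PDB text stream plus a region table into an AntibodyComplex.

    Only the first MODEL is used; for alternate locations the
    highest-occupancy conformer wins (ties broken by altloc identifier).
    Hydrogens are dropped (heavy-atom-only convention).
    """
    if hasattr(pdb_source, "read"):
        pdb_text = pdb_source.read()
    else:
        pdb_text = pdb_source
    annotation = (annotation_source
                  if isinstance(annotation_source, RegionAnnotation)
                  else RegionAnnotation.from_tsv(annotation_source))
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models in PDB input")
    model = structure[0]
    atoms = []
    for chain in model:
        for res in chain:
            label = f"{res.seqid.num}{(res.seqid.icode or '').strip()}"
            chosen = {}
            for atom in res:
                if atom.element.name == "H":
                    continue
                prev = chosen.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "~")) > \
                        (prev.occ, -ord(prev.altloc or "~")):
                    chosen[atom.name] = atom
            for name, atom in chosen.items():
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_label=label,
                    residue_name=res.name,
                    atom_name=name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(atom.occ)))
    present = {(a.chain_id, a.residue_label) for a in atoms}
    for key, region in annotation.region_of.items():
        if key not in present:
            raise AnnotationError(
                f"annotated residue {key[0]}/{key[1]} ({region}) "
                "absent from coordinates")
    return AntibodyComplex(atoms, annotation)


def prepare_complex(complex: AntibodyComplex):
    """Clean a freshly read complex for modelling.

    Removes waters/metals/halogens and unannotated chains (extra biounit
    copies), records disulfides (SG–SG < 2.5 Å), completes missing side-chain
    heavy atoms at ideal geometry without repacking, and flags chain breaks
    (C–N > 2.0 Å) and termini as capped.  Idempotent.
    """
    report = PrepReport()
    annotated_chains = complex.annotation.chains()
    kept = []
    removed_chains = set()
    removed_residues = set()
    for a in complex.atoms:
        if a.chain_id not in annotated_chains:
            removed_chains.add(a.chain_id)
            continue
        if a.residue_name in _WATER_NAMES:
            removed_residues.add((a.chain_id, a.residue_label))
            continue
        kept.append(a)
    # single-atom ion residues
    counts = {}
    for a in kept:
        counts.setdefault((a.chain_id, a.residue_label), []).append(a)
    kept2 = []
    for key, group in counts.items():
        if len(group) == 1 and group[0].element in (
                _METAL_ELEMENTS | _HALOGEN_ELEMENTS):
            removed_residues.add(key)
            continue
        kept2.extend(group)
    report.copies_removed = len(removed_chains)
    report.waters_ions_removed = len(removed_residues)

    out = AntibodyComplex(kept2, complex.annotation, check_h3=False)

    # disulfides
    sg = [(key, out.get_atom(*key, "SG").position)
          for key in out.residue_keys()
          if out.residue_name(*key) == "CYS" and out.has_atom(*key, "SG")]
    disulfides = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i][1] - sg[j][1]) < 2.5:
                disulfides.append((sg[i][0], sg[j][0]))

    # complete missing side-chain atoms
    new_atoms = list(out.atoms)
    n_added = 0
    for key in out.residue_keys():
        res_name = out.residue_name(*key)
        if res_name not in rescfg.AA3_TO_1:
            continue
        if not all(out.has_atom(*key, n) for n in ("N", "CA", "C")):
            continue
        have = set(out.residue_atom_names(*key))
        expected = set(rescfg.heavy_atom_names(res_name))
        missing = expected - have - {"O"}
        if not missing:
            continue
        n_pos = out.get_atom(*key, "N").position
        ca_pos = out.get_atom(*key, "CA").position
        c_pos = out.get_atom(*key, "C").position
        chis = _infer_chis(out, key, res_name)
        built = rescfg.build_side_chain(res_name, n_pos, ca_pos, c_pos, chis)
        for name in sorted(missing):
            if name not in built:
                continue
            new_atoms.append(AtomRecord(
                chain_id=key[0], residue_label=key[1],
                residue_name=res_name, atom_name=str(name),
                element=str(name)[0], position=built[name]))
            n_added += 1
    report.missing_sidechains_completed = n_added

    out = AntibodyComplex(new_atoms, complex.annotation, check_h3=False)
    # chain breaks & termini
    caps = set()
    n_breaks = 0
    for chain in sorted({a.chain_id for a in out.atoms}):
        keys = out.chain_residues(chain)
        if not keys:
            continue
        caps.add(keys[0])
        caps.add(keys[-1])
        for k1, k2 in zip(keys, keys[1:]):
            if out.has_atom(*k1, "C") and out.has_atom(*k2, "N"):
                d = np.linalg.norm(out.get_atom(*k1, "C").position
                                   - out.get_atom(*k2, "N").position)
                if d > 2.0:
                    n_breaks += 1
                    caps.add(k1)
                    caps.add(k2)
    report.chain_breaks_capped = n_breaks

    result = AntibodyComplex(out.atoms, complex.annotation,
                             disulfides=disulfides, terminal_caps=caps)
    return result, report


def _infer_chis(cx: AntibodyComplex, key, res_name):
    """Chi angles from whatever side-chain atoms exist, default rotamer
    values for the rest."""
    from . import geometry
    defaults = rescfg.ROTAMERS[res_name][0]
    chis = []
    for k, quad in enumerate(rescfg.CHI_ATOMS.get(res_name, [])):
        if all(cx.has_atom(*key, n) for n in quad):
            pts = [cx.get_atom(*key, n).position for n in quad]
            chis.append(float(np.rad2deg(geometry.dihedral(*pts))))
        else:
            chis.append(defaults[k] if k < len(defaults) else 180.0)
    return tuple(chis)


def write_structure(complex: AntibodyComplex, target) -> None:
    """Serialize to standard fixed-width PDB ATOM records."""
    lines = []
    serial = 0
    prev_chain = None
    for a in complex.atoms:
        if len(a.residue_name) > 3:
            raise ValueError(f"residue name too long: {a.residue_name}")
        if len(a.atom_name) > 4:
            raise ValueError(f"atom name too long: {a.atom_name}")
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        label = a.residue_label
        num = "".join(ch for ch in label if ch.isdigit() or ch == "-")
        icode = label[len(num):] or " "
        name = a.atom_name
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{a.residue_name:>4s} "
            f"{a.chain_id:1s}{int(num):4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}")
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


def to_pdb_string(complex: AntibodyComplex) -> str:
    buf = io.StringIO()
    write_structure(complex, buf)
    return buf.getvalue()
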