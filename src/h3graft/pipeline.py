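"""End-to-end screening pipeline: library -> stem matching -> grafting ->
ensemble generation -> two-track scoring -> stratified-Z selection."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import grafting, model_io, ranking_selection, scoring, stem_library
from . import loop_sampling as ls


@dataclass
class ScreenConfig:
    n_samples: int = 5000
    keep_rescore: int = 1000
    keep_top: int = 250
    keep_per_stem: int = 100
    expansions_stage1: int = 5
    expansions_stage2: int = 25
    retention_window: float = 5.0       # kcal/mol
    stem_retention_window: float = 1.7  # log-odds units
    contact_cutoff: float = 4.5         # Å
    kT: float = 1.0
    selection: ranking_selection.SelectionConfig = field(
        default_factory=ranking_selection.SelectionConfig)

    @classmethod
    def full(cls) -> "ScreenConfig":
        return cls()

    @classmethod
    def desk(cls) -> "ScreenConfig":
        """Scaled-down counts for desk-size screens and tests."""
        return cls(n_samples=200, keep_rescore=100, keep_top=25,
                   keep_per_stem=10, expansions_stage1=2,
                   expansions_stage2=5)


@dataclass
class CandidateResult:
    candidate_id: str
    sequence: str
    record: scoring.ScoreRecord
    ensemble: ls.LoopEnsemble
    best_complex: "model_io.AntibodyComplex"
    n_stems: int
    contact_removed_fraction: float


@dataclass
class ScreenResult:
    candidates: dict
    records: list
    zrecords: list
    medians: pd.DataFrame
    report: pd.DataFrame
    outcomes: dict
    skipped: list

    @property
    def cutoff_set(self):
        return ranking_selection.apply_cutoff(self.zrecords)

    def score_table(self) -> pd.DataFrame:
        rows = [(r.candidate_id, r.h3_length, r.avg_total,
                 r.avg_interaction, r.n_conformers)
                for r in self.records]
        return pd.DataFrame(rows, columns=[
            "candidate_id", "length", "avg_total", "avg_interaction",
            "n_conformers"])


def candidate_seed(base_seed: int, candidate_id: str) -> int:
    h = 2166136261
    for ch in f"{base_seed}|{candidate_id}":
        h = (h ^ ord(ch)) * 16777619 % (1 << 31)
    return h


def screen_candidate(parent, candidate_id, sequence, stem_templates,
                     config: ScreenConfig, seed: int):
    """Run one H3 sequence through grafting, sampling and scoring."""
    matches = stem_library.match_stems(sequence, stem_templates,
                                       config.stem_retention_window)
    retained = [m.template for m in matches if m.retained]
    per_stem = {}
    removed = []
    for k, template in enumerate(retained):
        graft = grafting.graft_stem(parent, template, sequence)
        ens = ls.sample_tip(graft, n_samples=config.n_samples,
                            seed=seed + 17 * k)
        reference = ls.replace_stage(
            ens, ens.conformations[:config.keep_rescore], "initial")
        culled = ls.cull_ensemble(ens, config.keep_rescore, config.keep_top)
        filtered = ls.contact_filter(culled, reference)
        removed.append(filtered.meta.get("contact_removed_fraction", 0.0))
        if not filtered.conformations:
            # every conformer lost antigen contact; fall back to the culled
            # set so the candidate can still be scored (and penalized)
            filtered = culled
        minimized = [ls.minimize_loop(c, filtered.environment)
                     for c in filtered.conformations]
        per_stem[template.cluster_id] = ls.replace_stage(
            filtered, minimized, "minimized")
    merged = ls.retain_per_stem(per_stem, config.keep_per_stem)
    merged.candidate_id = candidate_id
    refined = ls.refine_ensemble(
        merged, config.expansions_stage1, config.expansions_stage2,
        config.retention_window, seed=seed + 9001)
    refined.candidate_id = candidate_id
    scorer = scoring.ConformerScorer(refined)
    record = scoring.score_ensemble(refined, kT=config.kT, scorer=scorer)
    record.candidate_id = candidate_id
    best = min(refined.conformations, key=lambda c: c.total_energy)
    best_cx = ls.apply_conf(refined.environments[best.stem_of_origin],
                            best.coords)
    return CandidateResult(
        candidate_id, sequence, record, refined, best_cx,
        n_stems=len(retained),
        contact_removed_fraction=float(np.mean(removed)) if removed
        else 0.0)


def screen(parent, library, stem_templates, config: ScreenConfig = None,
           seed: int = 0) -> ScreenResult:
    """Screen an H3 sequence library against a parental complex.

    ``library`` is a sequence of (candidate_id, h3_sequence); candidates
    whose length has no stem template are skipped with a warning.
    """
    config = config or ScreenConfig.desk()
    candidates = {}
    records = []
    skipped = []
    for cid, seq in library:
        try:
            res = screen_candidate(parent, cid, seq, stem_templates,
                                   config,
                                   candidate_seed(seed, cid))
        except ValueError as exc:
            warnings.warn(f"candidate {cid} skipped: {exc}")
            skipped.append((cid, str(exc)))
            continue
        candidates[cid] = res
        records.append(res.record)
    zrecords = ranking_selection.stratified_z(records)
    medians = ranking_selection.stratum_stats(records)
    complexes = {cid: res.best_complex for cid, res in candidates.items()}
    report, outcomes = ranking_selection.select(
        zrecords, complexes, parent, config.selection)
    return ScreenResult(candidates, records, zrecords, medians, report,
                        outcomes, skipped)


# -- persistence ------------------------------------------------------------


def write_outputs(result: ScreenResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.score_table().to_csv(
        os.path.join(outdir, "score_table.tsv"), sep="\t", index=False)
    result.report.to_csv(
        os.path.join(outdir, "selection.tsv"), sep="\t", index=False)
    result.medians.to_csv(
        os.path.join(outdir, "medians.tsv"), sep="\t", index=False)
    ens_dir = os.path.join(outdir, "ensembles")
    os.makedirs(ens_dir, exist_ok=True)
    for cid, res in result.candidates.items():
        safe = cid.replace("/", "_")
        write_ensemble(res.ensemble,
                       os.path.join(ens_dir, f"{safe}.pdb"),
                       os.path.join(ens_dir, f"{safe}.tsv"))


def write_ensemble(ens: ls.LoopEnsemble, pdb_path: str,
                   tsv_path: str) -> None:
    """Multi-model PDB of the loop region plus a per-conformer sidecar."""
    lines = []
    rows = []
    for k, conf in enumerate(ens.conformations, 1):
        lines.append(f"MODEL     {k:4d}")
        cx = ls.apply_conf(ens.environments[conf.stem_of_origin],
                           conf.coords)
        serial = 0
        for key in cx.h3_index_map:
            for name in cx.residue_atom_names(*key):
                a = cx.get_atom(*key, name)
                serial += 1
                num = "".join(ch for ch in a.residue_label
                              if ch.isdigit())
                icode = a.residue_label[len(num):] or " "
                atom_name = (" " + name if len(name) < 4
                             and len(a.element) == 1 else name)
                x, y, z = a.position
                lines.append(
                    f"ATOM  {serial:5d} {atom_name:<4s}{a.residue_name:>4s}"
                    f" {a.chain_id:1s}{int(num):4d}{icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}")
        lines.append("ENDMDL")
        rows.append((k, ens.stage, conf.stem_of_origin,
                     _fmt(conf.stat_energy), _fmt(conf.total_energy),
                     conf.contact_count, round(conf.closure_gap, 3)))
    lines.append("END")
    with open(pdb_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    pd.DataFrame(rows, columns=[
        "conformer_id", "stage", "stem", "stat_energy", "total_energy",
        "contact_count", "closure_gap"]).to_csv(tsv_path, sep="\t",
                                                index=False)


def _fmt(x):
    return None if x is None else round(float(x), 3)
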