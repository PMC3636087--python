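"""End-to-end orchestration: inputs -> design -> statistics -> reports.

One :func:`run` call executes the whole experiment on either a synthetic
bundle or user-supplied files: multi-state design of one consensus
sequence over the ensemble plus a single-state design per complex, bit
score recovery against germline and mature references, the maturation
correlation, phi-psi flexibility statistics, interface-occurrence binning,
and germline-reversion energetics. All randomness flows from one base
seed; reports are TSV plus a plain-text/JSON summary so every summary
number is recomputable from stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import alignment as almod
from . import dihedral_stats as dsmod
from . import recovery as rmod
from . import reversion as revmod
from . import structure as stmod
from .constants import (
    INTERFACE_DELTA_THRESHOLD,
    RECOVERED_BIT_THRESHOLD,
    REVERSION_CANDIDATE_FREQ,
    REVERSION_SIGNIFICANCE_REU,
)
from .design import AnnealSchedule, DesignEnsemble, DesignTask, design, read_energy_tables, write_ensemble
from .synthetic import GeneratorSpec, SyntheticBundle, generate

log = logging.getLogger("polyspec.pipeline")


@dataclass(frozen=True)
class ComplexInput:
    complex_id: str
    pdb: str
    heavy_chain: str
    antigen_chains: tuple[str, ...]


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; every fixed constant is overridable here."""

    out_dir: str = "polyspec_out"
    n_trajectories: int = 100
    base_seed: int = 0
    synthetic: Mapping[str, Any] | None = None  # GeneratorSpec overrides
    # file-based inputs (ignored when synthetic is set)
    alignment_path: str | None = None
    germline_id: str = "germline"
    numbering_map_path: str | None = None
    energy_table_paths: tuple[str, ...] = ()
    complexes: tuple[ComplexInput, ...] = ()
    # thresholds
    interface_threshold: float = INTERFACE_DELTA_THRESHOLD
    recovered_bit_threshold: float = RECOVERED_BIT_THRESHOLD
    reversion_candidate_freq: float = REVERSION_CANDIDATE_FREQ
    reversion_significance_reu: float = REVERSION_SIGNIFICANCE_REU
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "complexes" in raw:
            raw["complexes"] = tuple(
                ComplexInput(
                    complex_id=c["id"], pdb=c["pdb"],
                    heavy_chain=c.get("heavy_chain", "H"),
                    antigen_chains=tuple(c.get("antigen_chains", ())),
                )
                for c in raw["complexes"]
            )
        if "energy_table_paths" in raw:
            raw["energy_table_paths"] = tuple(raw["energy_table_paths"])
        if "schedule" in raw:
            raw["schedule"] = AnnealSchedule(**raw["schedule"])
        return cls(**raw)


@dataclass
class ComplexResult:
    complex_id: str
    mutation_count: int
    mutation_pct: float
    msd_norm_germline: float
    msd_norm_mature: float
    msd_delta: float
    ssd_norm_germline: float
    ssd_norm_mature: float
    ssd_delta: float


@dataclass
class PipelineResult:
    config: RunConfig
    designed_columns: tuple[int, ...]
    per_complex: list[ComplexResult]
    msd_ensemble: DesignEnsemble
    ssd_ensembles: dict[str, DesignEnsemble]
    msd_germline_bits: dict[int, float]  # per-column clamped bits vs germline
    msd_wilcoxon: rmod.PairedTests  # germline vs mature normalized, MSD
    ssd_wilcoxon: rmod.PairedTests
    protocol_paired_t: rmod.PairedTests  # MSD delta vs SSD delta
    maturation: rmod.TestResult  # SSD deltas vs mutation %
    occurrence_bins: list[rmod.OccurrenceBin]
    interface_columns: dict[str, set[int]]
    deviations: list[dsmod.PhiPsiDeviation]
    group_comparison: dsmod.RecoveryGroupComparison | None
    reversions: list[revmod.ReversionRecord]
    tolerance_estimate: tuple[float, float, int]
    bundle: SyntheticBundle | None = None

    def summary_dict(self) -> dict[str, Any]:
        gc = self.group_comparison
        return {
            "designed_columns": list(self.designed_columns),
            "per_complex": [dataclasses.asdict(c) for c in self.per_complex],
            "msd_wilcoxon_p": self.msd_wilcoxon.wilcoxon.pvalue,
            "ssd_wilcoxon_p": self.ssd_wilcoxon.wilcoxon.pvalue,
            "protocol_paired_t_p": self.protocol_paired_t.paired_t.pvalue,
            "maturation_r2": self.maturation.r2,
            "maturation_r": self.maturation.statistic,
            "occurrence_bins": [
                {"label": b.label, "n": len(b.columns), "mean": b.mean, "sd": b.sd}
                for b in self.occurrence_bins
            ],
            "phi_psi_groups": None if gc is None else {
                "recovered_mean": gc.mean_recovered,
                "recovered_sem": gc.sem_recovered,
                "n_recovered": gc.n_recovered,
                "other_mean": gc.mean_other,
                "other_sem": gc.sem_other,
                "n_other": gc.n_other,
                "t_p": gc.ttest.pvalue,
                "reference_mean": gc.reference_mean,
                "reference_sem": gc.reference_sem,
            },
            "reversion": {
                "candidates": [r.column for r in self.reversions],
                "significant": [r.column for r in self.reversions if r.significant],
                "tolerance_estimate_reu": self.tolerance_estimate[0],
                "tolerance_estimate_sd": self.tolerance_estimate[1],
            },
        }


def _stage(name: str, t0: float, n: int) -> None:
    log.info("%s | wall-time %.2fs | n-items %d", name, time.time() - t0, n)


def run(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    bundle = None
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        bundle = generate(GeneratorSpec(**spec_kwargs),
                          out_dir=(out / "bundle") if config.write_outputs else None)
        aln = bundle.alignment
        pmap = bundle.position_map
        tables = bundle.tables
        structures = bundle.structures
        complex_meta = {
            cid: (bundle.spec.heavy_chain, (bundle.spec.antigen_chain,))
            for cid in structures
        }
    else:
        if config.alignment_path is None:
            raise ValueError("config needs either synthetic or alignment_path")
        aln = almod.read_alignment(config.alignment_path, config.germline_id)
        pmap = almod.select_designed_positions(aln)
        if config.numbering_map_path:
            pmap = pmap.with_numbering(
                almod.read_numbering_map(config.numbering_map_path),
                scheme="author-provided table",
            )
        tables = []
        for p in config.energy_table_paths:
            tables.extend(read_energy_tables(p))
        structures = {
            c.complex_id: stmod.read_structure(c.pdb, required_chains=[c.heavy_chain])
            for c in config.complexes
        }
        complex_meta = {
            c.complex_id: (c.heavy_chain, tuple(c.antigen_chains))
            for c in config.complexes
        }
    designed = pmap.designed_columns
    summaries = almod.mutation_summary(aln)
    state_ids = [t.state_id for t in tables]
    _stage("inputs", t0, len(state_ids))

    # ---- design -----------------------------------------------------------
    t0 = time.time()
    germ_designed = almod.subsequence(aln.germline, designed)
    mature_designed = {cid: almod.subsequence(seq, designed)
                       for cid, seq in aln.mature.items()}
    msd_task = DesignTask(columns=designed, states=tuple(tables), mode="multi",
                          n_trajectories=config.n_trajectories,
                          base_seed=config.base_seed)
    msd = design(msd_task, config.schedule)
    ssd: dict[str, DesignEnsemble] = {}
    for i, cid in enumerate(state_ids):
        task = DesignTask(columns=designed, states=tuple(tables), mode="single",
                          target_state=cid,
                          n_trajectories=config.n_trajectories,
                          base_seed=config.base_seed + 1000 * (i + 1))
        ssd[cid] = design(task, config.schedule)
    _stage("design", t0, (1 + len(state_ids)) * config.n_trajectories)

    # ---- recovery statistics ---------------------------------------------
    t0 = time.time()
    msd_profiles = rmod.profile(msd)
    msd_germ = rmod.recovery(msd_profiles, germ_designed, "germline")
    per_complex: list[ComplexResult] = []
    msd_deltas, ssd_deltas, mut_pcts = [], [], []
    for cid in state_ids:
        msd_mat = rmod.recovery(msd_profiles, mature_designed[cid], f"mature:{cid}")
        sprof = rmod.profile(ssd[cid])
        ssd_germ = rmod.recovery(sprof, germ_designed, "germline")
        ssd_mat = rmod.recovery(sprof, mature_designed[cid], f"mature:{cid}")
        md = rmod.delta(msd_mat, msd_germ, cid).value
        sd = rmod.delta(ssd_mat, ssd_germ, cid).value
        summ = summaries[cid]
        per_complex.append(ComplexResult(
            complex_id=cid, mutation_count=summ.count, mutation_pct=summ.percentage,
            msd_norm_germline=msd_germ.normalized, msd_norm_mature=msd_mat.normalized,
            msd_delta=md,
            ssd_norm_germline=ssd_germ.normalized, ssd_norm_mature=ssd_mat.normalized,
            ssd_delta=sd,
        ))
        msd_deltas.append(md)
        ssd_deltas.append(sd)
        mut_pcts.append(summ.percentage)
    def safe_paired(a, b):
        try:
            return rmod.paired_tests(a, b)
        except rmod.RecoveryError as exc:  # e.g. fewer than 5 pairs
            log.warning("paired tests unavailable: %s", exc)
            nan = float("nan")
            t = rmod.TestResult("paired_t", nan, nan, len(a), degenerate=True)
            w = rmod.TestResult("wilcoxon_matched_pairs", nan, nan, len(a),
                                degenerate=True)
            return rmod.PairedTests(wilcoxon=w, paired_t=t)

    msd_wil = safe_paired([c.msd_norm_germline for c in per_complex],
                          [c.msd_norm_mature for c in per_complex])
    ssd_wil = safe_paired([c.ssd_norm_mature for c in per_complex],
                          [c.ssd_norm_germline for c in per_complex])
    protocol_t = safe_paired(ssd_deltas, msd_deltas)
    maturation = rmod.maturation_correlation(ssd_deltas, mut_pcts)
    msd_bits = dict(zip(msd_germ.columns, msd_germ.per_column_bit))
    _stage("recovery", t0, len(per_complex))

    # ---- structure statistics --------------------------------------------
    t0 = time.time()
    interface_cols: dict[str, set[int]] = {}
    dihedrals_by_complex: dict[str, dict[int, stmod.DihedralRecord]] = {}
    for cid, model in structures.items():
        heavy, antigens = complex_meta[cid]
        annos = stmod.classify_interface(model, [heavy], list(antigens),
                                         threshold=config.interface_threshold)
        cols = set()
        for a in annos:
            col = pmap.column_for(cid, a.key[0], a.key[1])
            if a.is_interface and col is not None:
                cols.add(col)
        interface_cols[cid] = cols
        recs = stmod.compute_dihedrals(model, heavy)
        by_col = {}
        for rec in recs:
            col = pmap.column_for(cid, rec.key[0], rec.key[1])
            if col is not None:
                by_col[col] = rec
        dihedrals_by_complex[cid] = by_col
    bins = rmod.bin_by_interface_occurrence(msd_bits, interface_cols)
    all_devs = dsmod.position_deviation(dihedrals_by_complex, beta_filter=True)
    designed_devs = {d.column: d.combined for d in all_devs if d.column in set(designed)}
    reference_devs = [d.combined for d in all_devs]
    try:
        groups = dsmod.compare_recovery_groups(
            designed_devs, msd_bits, reference_devs,
            bit_threshold=config.recovered_bit_threshold)
    except dsmod.DeviationError as exc:
        log.warning("group comparison undefined: %s", exc)
        groups = None
    _stage("structstats", t0, len(all_devs))

    # ---- reversion --------------------------------------------------------
    t0 = time.time()
    candidates = revmod.reversion_candidates(
        msd, germ_designed, threshold=config.reversion_candidate_freq)
    reversions = revmod.reversion_energies(
        msd_task, msd, candidates, germ_designed,
        significance=config.reversion_significance_reu)
    tol = revmod.significance_tolerance(tables, germ_designed, mature_designed)
    _stage("reversion", t0, len(reversions))

    result = PipelineResult(
        config=config, designed_columns=designed, per_complex=per_complex,
        msd_ensemble=msd, ssd_ensembles=ssd, msd_germline_bits=msd_bits,
        msd_wilcoxon=msd_wil, ssd_wilcoxon=ssd_wil, protocol_paired_t=protocol_t,
        maturation=maturation, occurrence_bins=bins,
        interface_columns=interface_cols, deviations=all_devs,
        group_comparison=groups, reversions=reversions,
        tolerance_estimate=tol, bundle=bundle,
    )
    if config.write_outputs:
        _write_reports(result, out, msd_germ, dihedrals_by_complex)
    return result


def _write_reports(result: PipelineResult, out: Path,
                   msd_germ: rmod.RecoveryScore,
                   dihedrals_by_complex) -> None:
    write_ensemble(result.msd_ensemble, out / "msd_designs.fasta",
                   out / "msd_fitness.tsv")
    for cid, ens in result.ssd_ensembles.items():
        write_ensemble(ens, out / f"ssd_{cid}_designs.fasta")
    # per-column table
    occ = {c: sum(1 for cols in result.interface_columns.values() if c in cols)
           for c in result.designed_columns}
    bin_label = {}
    for b in result.occurrence_bins:
        for c in b.columns:
            bin_label[c] = b.label
    raw = dict(zip(msd_germ.columns, msd_germ.per_column_raw))
    pd.DataFrame({
        "column": list(msd_germ.columns),
        "bit_germline_raw": [raw[c] for c in msd_germ.columns],
        "bit_germline": [result.msd_germline_bits[c] for c in msd_germ.columns],
        "interface_occurrence": [occ.get(c, 0) for c in msd_germ.columns],
        "occurrence_bin": [bin_label.get(c, "") for c in msd_germ.columns],
    }).to_csv(out / "per_column.tsv", sep="\t", index=False, float_format="%.6f")
    # per-complex table
    pd.DataFrame([dataclasses.asdict(c) for c in result.per_complex]).to_csv(
        out / "per_complex.tsv", sep="\t", index=False, float_format="%.6f")
    # structure table
    rows = []
    devs = {d.column: d for d in result.deviations}
    for col, d in sorted(devs.items()):
        rows.append({
            "column": col, "sd_phi": d.sd_phi, "sd_psi": d.sd_psi,
            "combined": d.combined, "n_structures": d.n_structures,
            "bit_germline": result.msd_germline_bits.get(col, float("nan")),
        })
    pd.DataFrame(rows).to_csv(out / "phi_psi_deviation.tsv", sep="\t",
                              index=False, float_format="%.6f")
    # reversion table
    rrows = []
    for r in result.reversions:
        for state, de in r.delta_e_by_state.items():
            rrows.append({
                "column": r.column, "designed_aa": r.designed_modal_aa,
                "germline_aa": r.germline_aa, "state": state,
                "deltaE": de, "significant": r.significant,
            })
    pd.DataFrame(rrows, columns=["column", "designed_aa", "germline_aa",
                                 "state", "deltaE", "significant"]).to_csv(
        out / "reversion.tsv", sep="\t", index=False, float_format="%.6f")
    # logo counts for the multi-state ensemble
    rmod.logo_counts(rmod.profile(result.msd_ensemble)).to_csv(
        out / "msd_logo_counts.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.txt", "w") as fh:
        s = result.summary_dict()
        fh.write("polyspec run summary\n")
        fh.write(f"designed columns: {len(result.designed_columns)}\n")
        for c in result.per_complex:
            fh.write(
                f"{c.complex_id}: mut={c.mutation_count} ({c.mutation_pct:.1f}%) "
                f"MSD germ/mat={c.msd_norm_germline:.3f}/{c.msd_norm_mature:.3f} "
                f"SSD germ/mat={c.ssd_norm_germline:.3f}/{c.ssd_norm_mature:.3f}\n")
        fh.write(f"MSD Wilcoxon (germ vs mature) p={s['msd_wilcoxon_p']:.4g}\n")
        fh.write(f"SSD Wilcoxon (mature vs germ) p={s['ssd_wilcoxon_p']:.4g}\n")
        fh.write(f"maturation correlation r2={s['maturation_r2']:.4f}\n")
        if s["phi_psi_groups"]:
            g = s["phi_psi_groups"]
            fh.write(
                f"phi-psi: recovered {g['recovered_mean']:.1f}+-{g['recovered_sem']:.1f} "
                f"vs other {g['other_mean']:.1f}+-{g['other_sem']:.1f} "
                f"(t p={g['t_p']:.3g}; reference {g['reference_mean']:.1f})\n")
        fh.write(
            f"reversion: {len(s['reversion']['candidates'])} candidates, "
            f"{len(s['reversion']['significant'])} significant; "
            f"tolerance estimate {s['reversion']['tolerance_estimate_reu']:.2f} REU\n")
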