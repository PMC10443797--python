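"""End-to-end orchestration: cohort data in, rescue/score/motif/clinical
tables out.

The run order mirrors the analysis narrative: per-individual and grouped
contrasts versus controls, splicing rescue and dysregulation, expression
rescue and dysregulation, shared-rescue overlaps, YGCY motif enrichment,
clinical change metrics, and the molecular-clinical correlations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import contrasts as ct
from . import motif as mt
from . import rescue as rs
from .io_model import (
    ContrastTable,
    FormatError,
    PsiMatrix,
    ValidationError,
    read_clinical_table,
    read_count_matrix,
    read_event_bed,
    read_psi_matrix,
    read_region_fasta,
    read_sample_meta,
    validate_sample_set,
    write_report,
)

logger = logging.getLogger("dmrescue")

#: literature test-retest ICCs for the non-1-RM tests (the 1-RM method has no
#: published SEMT, so 1-RM rows get no MDC screen)
DEFAULT_ICC = {"knee_extensors": 0.95, "thirty_sec_sts": 0.90,
               "comfortable_walk_speed": 0.99, "max_walk_speed": 0.98}


@dataclass
class RunConfig:
    """Complete, serializable parameter set of one analysis run."""

    preset: str = "strength"
    thresholds: dict = field(default_factory=dict)  # overrides of the preset
    include_overrescued: bool = False
    count_filter_mode: str = "every"
    normalization: str = "median_ratio"
    pseudocount: float = 0.5
    sd_floor_gene: float = 0.05
    sd_floor_psi: float = 0.01
    flank: int = 250
    k_background: int = 5
    motif_epsilon: float = mt.DEFAULT_EPSILON
    rm_tests: tuple = clin.RM_TESTS
    icc_by_test: dict = field(default_factory=lambda: dict(DEFAULT_ICC))
    semt_variant: str = "sqrt"
    panel_file: str | None = None
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rm_tests"] = list(self.rm_tests)
        return d

    def resolve_thresholds(self) -> ct.Thresholds:
        return ct.get_thresholds(self.preset, **self.thresholds)


def _drop_untestable(tbl: ContrastTable, label: str) -> ContrastTable:
    """Remove rows lacking effect/p/fdr (insufficient supported values)."""
    t = tbl.table
    bad = t[["effect", "p_value", "fdr"]].isna().any(axis=1)
    if bad.any():
        logger.info("[%s] %d unit(s) untestable (missing values), excluded",
                    label, int(bad.sum()))
        return ContrastTable(t.loc[~bad].reset_index(drop=True))
    return tbl


def _subject_arms(meta):
    controls = [s.sample_id for s in meta if s.group == "control"]
    pre, post, ages = {}, {}, {}
    for s in meta:
        if s.group == "patient":
            if s.timepoint == "pre":
                pre[s.subject_id] = s.sample_id
            else:
                post[s.subject_id] = s.sample_id
            if s.age is not None:
                ages[s.subject_id] = s.age
    return controls, pre, post, ages


def _gene_stage(counts, meta, config: RunConfig, th: ct.Thresholds) -> dict:
    controls, pre, post, _ = _subject_arms(meta)
    counts = ct.filter_low_counts(counts, th.min_gene_count,
                                  config.count_filter_mode)
    logexpr = ct.normalized_log_expression(counts, config.pseudocount,
                                           config.normalization)
    subjects = sorted(pre)
    records, score_rows, delta_rows = [], [], []
    pct_rescued, sig_sets = {}, {}

    def contrast(samples_a, samples_b, label, single):
        tbl = ct.estimate_log2fc(counts, samples_a, samples_b,
                                 config.pseudocount, label,
                                 config.normalization)
        return ct.attach_significance(tbl, logexpr[samples_a],
                                      logexpr[samples_b], "welch_bh",
                                      sd_floor=config.sd_floor_gene)

    grouped_pre = contrast([pre[s] for s in subjects], controls,
                           "grouped_pre_vs_control", False)
    grouped_post_samples = [post[s] for s in subjects if s in post]
    grouped_post = (ct.estimate_log2fc(counts, grouped_post_samples, controls,
                                       config.pseudocount,
                                       "grouped_post_vs_control",
                                       config.normalization)
                    if grouped_post_samples else None)

    def analyze(label, pre_tbl, post_tbl):
        sig = ct.filter_significant(pre_tbl, th, "gene")
        sig_sets[label] = sig
        if not sig:
            logger.warning("gene stage [%s]: no significant pre-training DEGs",
                           label)
            return
        eff_pre = pre_tbl.effects()
        rec = rs.rescue_records(eff_pre.to_dict(),
                                post_tbl.effects().to_dict() if post_tbl else {},
                                0.0, sorted(sig), label, "gene")
        records.append(rec)
        score_rows.append({"subject_id": label, "modality": "gene",
                           "timepoint": "pre",
                           "score": rs.dysregulation_score(eff_pre.loc[sorted(sig)]),
                           "n_units": len(sig)})
        if post_tbl is not None:
            eff_post = post_tbl.effects().reindex(sorted(sig))
            score_rows.append({"subject_id": label, "modality": "gene",
                               "timepoint": "post",
                               "score": rs.dysregulation_score(eff_post),
                               "n_units": len(sig)})
            delta_rows.append(ct.delta_log2fc(pre_tbl, post_tbl, label))
        if len(rec):
            pct_rescued[label] = rs.percent_units_rescued(
                rec, config.include_overrescued)

    for subj in subjects:
        pre_tbl = contrast([pre[subj]], controls, f"{subj}_pre_vs_control", True)
        post_tbl = (ct.estimate_log2fc(counts, [post[subj]], controls,
                                       config.pseudocount,
                                       f"{subj}_post_vs_control",
                                       config.normalization)
                    if subj in post else None)
        analyze(subj, pre_tbl, post_tbl)
    analyze("grouped", grouped_pre, grouped_post)

    rec_df = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["unit_id", "subject_id", "modality", "percent_rescue", "category"])
    delta_df = pd.concat(delta_rows, ignore_index=True) if delta_rows else \
        pd.DataFrame(columns=["unit_id", "subject_id", "delta_lfc"])
    return {"records": rec_df, "scores": score_rows, "delta": delta_df,
            "pct_rescued": {k: v for k, v in pct_rescued.items()
                            if k != "grouped"},
            "sig_sets": sig_sets}


def _splice_stage(psi: PsiMatrix, meta, config: RunConfig,
                  th: ct.Thresholds, panel: list[str] | None) -> dict:
    controls, pre, post, _ = _subject_arms(meta)
    psi = ct.apply_support_filter(psi, th.min_event_reads)
    df = psi.psi
    ctrl_mean = df[controls].mean(axis=1)
    subjects = sorted(pre)
    records, score_rows, panel_states = [], [], {}
    rescued_sets, sig_sets = {}, {}

    def analyze(label, pre_vals: pd.Series, post_vals: pd.Series | None,
                tbl: ContrastTable):
        sig = ct.filter_significant(tbl, th, "event")
        sig_sets[label] = sig
        if not sig:
            logger.warning("splice stage [%s]: no significant events", label)
            return pd.DataFrame(columns=["unit_id", "subject_id", "modality",
                                         "percent_rescue", "category"])
        rec = rs.rescue_records(pre_vals.dropna().to_dict(),
                                post_vals.dropna().to_dict()
                                if post_vals is not None else {},
                                ctrl_mean.to_dict(), sorted(sig),
                                label, "event")
        records.append(rec)
        devs_pre = (pre_vals - ctrl_mean).loc[sorted(sig)]
        score_rows.append({"subject_id": label, "modality": "event",
                           "timepoint": "pre",
                           "score": rs.dysregulation_score(devs_pre),
                           "n_units": len(sig)})
        if post_vals is not None:
            devs_post = (post_vals - ctrl_mean).loc[sorted(sig)]
            score_rows.append({"subject_id": label, "modality": "event",
                               "timepoint": "post",
                               "score": rs.dysregulation_score(devs_post),
                               "n_units": len(sig)})
        return rec

    for subj in subjects:
        pre_col = df[pre[subj]]
        post_col = df[post[subj]] if subj in post else None
        # events with no pre reads are excluded from this subject's universe
        tbl = ct.delta_psi_contrast(df[~pre_col.isna()], [pre[subj]], controls,
                                    f"{subj}_pre_vs_control")
        tbl = ct.attach_significance(
            tbl, df.loc[~pre_col.isna(), [pre[subj]]],
            df.loc[~pre_col.isna(), controls], "welch_bh",
            sd_floor=config.sd_floor_psi)
        tbl = _drop_untestable(tbl, f"{subj} splice")
        rec = analyze(subj, pre_col, post_col, tbl)
        rescued_sets[subj] = set(rec.loc[rec["category"] == "rescued",
                                         "unit_id"]) if len(rec) else set()
        if panel is not None:
            pre_ok = (~pre_col.isna()).to_dict()
            post_ok = ((~post_col.isna()).to_dict() if post_col is not None
                       else {e: False for e in df.index})
            panel_states[subj] = rs.panel_classify(
                panel, rec, sig_sets[subj], pre_ok, post_ok)

    pre_samples = [pre[s] for s in subjects]
    post_samples = [post[s] for s in subjects if s in post]
    gtbl = ct.delta_psi_contrast(df, pre_samples, controls,
                                 "grouped_pre_vs_control")
    gtbl = ct.attach_significance(gtbl, df[pre_samples], df[controls],
                                  "welch_bh", sd_floor=config.sd_floor_psi)
    gtbl = _drop_untestable(gtbl, "grouped splice")
    analyze("grouped", df[pre_samples].mean(axis=1),
            df[post_samples].mean(axis=1) if post_samples else None, gtbl)

    overlaps = (rs.shared_rescue_overlaps(rescued_sets)
                if len(rescued_sets) >= 2 else None)
    rec_df = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["unit_id", "subject_id", "modality", "percent_rescue", "category"])
    panel_df = pd.DataFrame(panel_states) if panel_states else None
    return {"records": rec_df, "scores": score_rows, "overlaps": overlaps,
            "panel": panel_df, "rescued_sets": rescued_sets,
            "sig_sets": sig_sets, "grouped_table": gtbl}


def _motif_stage(input_dir: Path, config: RunConfig,
                 grouped_tbl: ContrastTable, sig_events: set[str],
                 th: ct.Thresholds) -> pd.DataFrame | None:
    bed = input_dir / "events.bed"
    fasta = input_dir / "genome.fa"
    if not (bed.exists() and fasta.exists()):
        logger.info("motif stage skipped: events.bed / genome.fa not present")
        return None
    events = read_event_bed(bed)
    genome = read_region_fasta(fasta)
    effects = grouped_tbl.effects()
    directions = {}
    for ev in sig_events:
        if ev in effects.index:
            directions[ev] = "inclusion" if effects[ev] > 0 else "exclusion"
    return mt.enrichment_analysis(events, genome, directions,
                                  flank=config.flank, k=config.k_background,
                                  seed=config.seed,
                                  epsilon=config.motif_epsilon)


def run_analysis(input_dir: str | Path, config: RunConfig,
                 write: bool = True) -> dict:
    """Run the full pipeline on a cohort directory; return the result bundle.

    Expects counts.tsv, psi.tsv, support.tsv, samples.tsv, clinical.tsv and
    optionally events.bed + genome.fa (motif stage) and a panel file.
    """
    input_dir = Path(input_dir)
    meta = read_sample_meta(input_dir / "samples.tsv")
    counts = read_count_matrix(input_dir / "counts.tsv")
    support = input_dir / "support.tsv"
    psi = read_psi_matrix(input_dir / "psi.tsv",
                          support if support.exists() else None)
    clin_rows = read_clinical_table(input_dir / "clinical.tsv")
    panel = None
    if config.panel_file:
        panel = [ln.split()[0] for ln in
                 Path(config.panel_file).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
    return analyze_cohort(counts, psi, meta, clin_rows, config, panel=panel,
                          motif_dir=input_dir, write=write)


def analyze_cohort(counts, psi, meta, clin_rows, config: RunConfig,
                   panel: list[str] | None = None,
                   motif_dir: Path | None = None,
                   write: bool = False) -> dict:
    """Run every analysis stage on in-memory cohort objects."""
    th = config.resolve_thresholds()
    validate_sample_set(meta)
    missing = [s.sample_id for s in meta
               if s.sample_id not in counts.sample_ids
               or s.sample_id not in psi.sample_ids]
    if missing:
        raise ValidationError(
            f"sample(s) in metadata absent from count/PSI matrices: {missing}")

    gene = _gene_stage(counts, meta, config, th)
    splice = _splice_stage(psi, meta, config, th, panel)
    enrichment = None
    if motif_dir is not None:
        enrichment = _motif_stage(Path(motif_dir), config,
                                  splice["grouped_table"],
                                  splice["sig_sets"].get("grouped", set()), th)

    # ---- clinical + correlations
    clin_table = clin.build_clinical_table(clin_rows, config.icc_by_test,
                                           config.semt_variant)
    rm_change = clin.per_subject_1rm_change(clin_table, config.rm_tests)
    _, _, _, ages = _subject_arms(meta)
    correlations = {}
    if len(gene["pct_rescued"]) >= 4:
        try:
            correlations = clin.correlate_rescue_with_clinical(
                gene["pct_rescued"], rm_change.to_dict(), ages or None)
        except clin.DegenerateCorrelationError as exc:
            logger.warning("correlation omitted: %s", exc)
    else:
        logger.warning("correlation skipped: fewer than 4 subjects with "
                       "defined %%DEGs rescued")
    ordered = list(rm_change.sort_values(ascending=False).index)
    gene_rescued_sets = {}
    grec = gene["records"]
    for subj in gene["pct_rescued"]:
        sel = (grec["subject_id"] == subj) & (grec["category"] == "rescued")
        gene_rescued_sets[subj] = set(grec.loc[sel, "unit_id"])
    descending = clin.grouped_descending_overlap(
        [s for s in ordered if s in gene_rescued_sets], gene_rescued_sets)

    # ---- assemble report
    scores = pd.DataFrame(gene["scores"] + splice["scores"])
    corr_df = pd.DataFrame(
        [{"pair": name, "rho": r.rho, "p_value": r.p_value, "n": r.n,
          "controlled_for": r.controlled_for or ""}
         for name, r in correlations.items()])
    tables = {
        "rescue_records": pd.concat([gene["records"], splice["records"]],
                                    ignore_index=True),
        "dysregulation_scores": scores,
        "delta_log2fc": gene["delta"],
        "clinical": clin_table,
        "correlations": corr_df,
        "pct_degs_rescued": pd.Series(gene["pct_rescued"], name="pct_rescued")
            .rename_axis("subject_id").reset_index(),
        "avg_1rm_change": rm_change.rename("avg_1rm_pct_change")
            .rename_axis("subject_id").reset_index(),
    }
    if splice["overlaps"] is not None:
        tables["overlap_exact"] = splice["overlaps"]["exact"]
        tables["overlap_per_k"] = splice["overlaps"]["per_k"]
        tables["overlap_unique"] = splice["overlaps"]["unique"]
    if splice["panel"] is not None:
        tables["panel_states"] = splice["panel"].rename_axis("event_id") \
            .reset_index()
    if enrichment is not None:
        tables["ygcy_enrichment"] = enrichment

    extras = {
        "n_sig_genes": {k: len(v) for k, v in gene["sig_sets"].items()},
        "n_sig_events": {k: len(v) for k, v in splice["sig_sets"].items()},
        "descending_overlap_depth": descending["depth"],
        "descending_overlap_terminal_size": len(descending["terminal"]),
        "descending_overlap_terminal_head": sorted(descending["terminal"])[:10],
        "preset": config.preset,
    }
    result = {"tables": tables, "correlations": correlations,
              "descending": descending, "pct_rescued": gene["pct_rescued"],
              "rm_change": rm_change, "extras": extras,
              "rescued_event_sets": splice["rescued_sets"]}
    if write:
        result["manifest"] = write_report(tables, config.out_dir,
                                          config.to_dict(), config.seed,
                                          extras=extras)
    return result
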