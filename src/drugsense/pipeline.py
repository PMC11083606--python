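"""End-to-end driver: simulate -> impute -> nominate -> biomarker -> doseresp.

Runs the whole discovery pipeline on either a synthetic study (default; all
inputs generated from one seed with full ground truth) or user-supplied
delimited-text inputs, writing every intermediate table to the output
directory. Identical config + seed yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import causal, dose_response, imputation, io, nomination, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Thresholds, modes and input locations for one pipeline run.

    With no input paths the pipeline simulates its own study from
    ``sim``/``seed``. ``r_min`` defaults to 0.30 for the synthetic study
    (see docs/methods.md); the per-call default of
    :func:`drugsense.causal.scc_filter` remains 0.60.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    sim: simulate.SimulationConfig = field(default=None)  # type: ignore[assignment]
    n_clinical: int = 5
    include_avatar: bool = True
    # thresholds
    min_fraction: float = 0.40
    alpha: float = 0.05
    q_max: float = 0.05
    r_min: float = 0.30
    max_k: int = 3
    min_clinical: int = 3
    require_avatar: bool = True
    percentile: float = 0.5
    lam_mode: str = "loo"
    axis: str = "log10_dose"
    biomarker_drugs: Optional[list[str]] = None   # None = nominated (or first) drugs
    # external inputs (optional; all-or-none for panel+screen)
    panel_expression_path: Optional[str] = None
    screen_path: Optional[str] = None
    cohort_paths: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (dataset_id, expression_path, labels_path, kind)

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = simulate.SimulationConfig(seed=self.seed)
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        for name in ("alpha", "q_max", "percentile"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must be in [0, 1]")
        if self.max_k < 0 or self.min_clinical < 1:
            raise ValueError("max_k must be >= 0 and min_clinical >= 1")
        if self.lam_mode not in ("loo", "fixed"):
            raise ValueError("lam_mode must be 'loo' or 'fixed'")
        if self.axis not in ("log10_dose", "linear_dose"):
            raise ValueError("axis must be 'log10_dose' or 'linear_dose'")
        if (self.panel_expression_path is None) != (self.screen_path is None):
            raise ValueError("panel_expression_path and screen_path must be "
                             "given together")
        for p in [self.panel_expression_path, self.screen_path] + [
                path for rec in self.cohort_paths for path in rec[1:3]]:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _load_or_simulate(cfg: PipelineConfig, out: Path):
    if cfg.panel_expression_path is not None:
        expr = io.read_expression(cfg.panel_expression_path)
        screen = io.read_screen(cfg.screen_path)
        cohorts = [
            simulate.Cohort(dataset_id=did, expression=io.read_expression(ep),
                            labels=io.read_labels(lp), true_auc=pd.DataFrame(),
                            kind=kind)
            for did, ep, lp, kind in cfg.cohort_paths
        ]
        study = simulate.StudyData(panel_expression=expr, screen=screen,
                                   truth=None, cohorts=cohorts)
    else:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        study = simulate.generate_study(sim, n_clinical=cfg.n_clinical,
                                        include_avatar=cfg.include_avatar)
        io.write_truth(study.truth, out / "truth.json")
    io.write_expression(study.panel_expression, out / "panel_expression.tsv")
    io.write_screen(study.screen, out / "screen.tsv")
    for c in study.cohorts:
        io.write_expression(c.expression, out / f"expression_{c.dataset_id}.tsv")
        io.write_labels(c.labels, out / f"labels_{c.dataset_id}.tsv")
    logger.info("simulate: %d genes, %d lines, %d drugs, %d cohorts",
                *study.panel_expression.shape, study.screen.shape[1],
                len(study.cohorts))
    return study


@_stage("impute")
def _impute(cfg: PipelineConfig, study, out: Path) -> dict[str, pd.DataFrame]:
    screen = imputation.filter_drugs(study.screen, cfg.min_fraction)
    logger.info("impute: coverage >= %.0f%%, %d drugs retained; lam_mode=%s",
                100 * cfg.min_fraction, screen.shape[1], cfg.lam_mode)
    models = imputation.fit_models(study.panel_expression, screen,
                                   lam_mode=cfg.lam_mode)
    imputed = {}
    for c in study.cohorts:
        _, test = imputation.harmonize(study.panel_expression, c.expression)
        tab = imputation.impute_panel(models, test)
        imputed[c.dataset_id] = tab
        tab.to_csv(out / f"imputed_{c.dataset_id}.tsv", sep="\t",
                   index_label="sample_id")
    return imputed


@_stage("nominate")
def _nominate(cfg: PipelineConfig, study, imputed, out: Path):
    records = []
    kinds = {}
    for c in study.cohorts:
        kinds[c.dataset_id] = c.kind
        records.append(nomination.nominate(
            imputed[c.dataset_id], c.labels, c.dataset_id,
            alpha=cfg.alpha, percentile=cfg.percentile))
    records = pd.concat(records, ignore_index=True)
    cons = nomination.consensus(records, kinds, min_clinical=cfg.min_clinical,
                                require_avatar=cfg.require_avatar)
    io.write_table(records, out / "nominations.tsv")
    io.write_table(cons, out / "consensus.tsv")
    membership = records.pivot_table(index="drug", columns="dataset",
                                     values="selected", aggfunc="any",
                                     fill_value=False).astype(int)
    membership.to_csv(out / "selection_membership.tsv", sep="\t")
    logger.info("nominate: alpha=%g percentile=%g min_clinical=%d "
                "require_avatar=%s; %d drugs nominated",
                cfg.alpha, cfg.percentile, cfg.min_clinical,
                cfg.require_avatar, int(cons["nominated"].sum()))
    return records, cons


@_stage("biomarker")
def _biomarker(cfg: PipelineConfig, study, imputed, cons, out: Path):
    cohort = study.clinical[0]
    tab = imputed[cohort.dataset_id]
    drugs = cfg.biomarker_drugs
    if drugs is None:
        nominated = cons.loc[cons["nominated"], "drug"].tolist()
        drugs = nominated or list(tab.columns[:1])
    reports, edges = [], []
    for drug in drugs:
        response = tab[drug]
        filt = causal.scc_filter(cohort.expression, response,
                                 r_min=cfg.r_min, q_max=cfg.q_max)
        cand = cohort.expression.loc[filt.loc[filt["retained"], "gene"]]
        pc = causal.mmpc(response, cand, alpha=cfg.alpha, max_k=cfg.max_k)
        oriented = causal.orient_parents(response, pc, cand,
                                         alpha=cfg.alpha, max_k=cfg.max_k)
        reports.append(causal.biomarker_report(filt, pc, oriented, drug=drug))
        e = oriented.edges.copy()
        e.insert(0, "drug", drug)
        edges.append(e)
        logger.info("biomarker %s: r_min=%g q_max=%g alpha=%g max_k=%d; "
                    "%d retained, %d PC, %d parental", drug, cfg.r_min,
                    cfg.q_max, cfg.alpha, cfg.max_k,
                    int(filt["retained"].sum()), len(pc.pc_genes),
                    len(oriented.parental_genes))
    io.write_table(pd.concat(reports, ignore_index=True),
                   out / "biomarker_report.tsv")
    io.write_table(pd.concat(edges, ignore_index=True), out / "edges.tsv")


@_stage("doseresp")
def _doseresp(cfg: PipelineConfig, study, out: Path):
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    curves, labels, true_auc = simulate.generate_dose_response(sim)
    io.write_dose_response(curves, out / "dose_response.tsv")
    auc = pd.Series({c.sample_id: dose_response.auc_trapezoid(c, axis=cfg.axis)
                     for c in curves}, name="auc")
    io.write_table(pd.DataFrame({"sample_id": auc.index, "auc": auc.to_numpy(),
                                 "group": labels.reindex(auc.index).to_numpy()}),
                   out / "measured_auc.tsv")
    p, hle = dose_response.compare_measured(auc, labels)
    io.write_table(pd.DataFrame([{"comparison": "GBM_vs_NPC", "p": p,
                                  "hle": hle, "axis": cfg.axis}]),
                   out / "dose_comparison.tsv")
    logger.info("doseresp: axis=%s p=%.4g hle=%.3f", cfg.axis, p, hle)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the artifact directory.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = _load_or_simulate(cfg, out)
    imputed = _impute(cfg, study, out)
    records, cons = _nominate(cfg, study, imputed, out)
    _biomarker(cfg, study, imputed, cons, out)
    if study.truth is not None:
        _doseresp(cfg, study, out)
    logger.info("pipeline complete: %s", out)
    return out
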