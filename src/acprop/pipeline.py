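"""End-to-end analysis pipeline and study report.

Orchestrates: curation -> MMP/AC mining -> per-kinase propensity ->
sequence descriptors -> feature matrix -> surrogate-forest importance ->
GA feature selection -> CV/test evaluation -> Y-scrambling -> report.
Inputs come either from a synthetic study config or from files (FASTA +
activity CSV + optional SMARTS list).  All intermediates are written as
CSV so every number in the report can be re-derived; a single global seed
fans out to per-stage seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aadata
from .curation import CurationLog, curate, read_activity_table, write_curated_csv
from .descriptors import descriptor_matrix, read_fasta
from .ml import (LearnerSpec, build_feature_matrix, evaluate, fit_classifier,
                 leave20_cv)
from .mmp import (THRESHOLD_B_DEFAULT, find_mmps, kinase_propensity, label_cliffs,
                  transform_crosstab, write_crosstab_csv, write_mmp_csv,
                  write_propensity_csv)
from .selection import GAParams, ga_feature_select, global_feature_importance, y_scramble
from .synthetic import StudyConfig, generate_study, write_fixtures

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one input source: a synthetic ``study`` config, or file paths
    (``fasta`` + ``activities``).  Defaults are the desk-scale "fast mode"
    (GA population 20 / 20 generations, 200 scrambling trials); the
    full-scale settings are GAParams() defaults and 1000 trials.
    """

    study: StudyConfig | None = None
    fasta: str | None = None
    activities: str | None = None
    smarts: str | None = None  # None -> bundled demo type-II signatures
    outdir: str = "acprop_out"
    schemes: tuple[str, ...] = ("default",)
    learners: tuple[str, ...] = ("random_forest",)
    threshold_b: float | None = None  # None -> survey mean + 1 SD of this run
    test_fraction: float = 0.2
    gfi_top: int = 180
    ga: GAParams = field(default_factory=lambda: GAParams(population=20, generations=20,
                                                          stagnation=10))
    n_scramble: int = 200
    seed: int = 0

    def __post_init__(self):
        if (self.study is None) == (self.fasta is None or self.activities is None):
            raise ValueError("provide either a synthetic study config or fasta+activities paths")
        if not self.schemes:
            raise ValueError("at least one classification scheme required")


@dataclass
class StudyReport:
    """All result tables of one pipeline run."""

    propensity: pd.DataFrame
    crosstab: pd.DataFrame
    metrics: dict
    variability: pd.DataFrame
    threshold_b: float
    seed: int

    def to_dict(self) -> dict:
        """Serialized report; percentages at 1 decimal, metrics at 2."""
        def _round_metrics(d):
            out = {}
            for k, v in d.items():
                if isinstance(v, dict):
                    out[k] = _round_metrics(v)
                elif isinstance(v, float):
                    out[k] = round(v, 2)
                else:
                    out[k] = v
            return out

        prop = self.propensity.copy()
        prop["acs_over_mmps_pct"] = prop["acs_over_mmps_pct"].round(1)
        var = self.variability.copy()
        for c in var.columns:
            if c.endswith("pct_kinases"):
                var[c] = var[c].round(1)
        return {
            "threshold_b": round(self.threshold_b, 2),
            "seed": self.seed,
            "propensity": prop.to_dict(orient="records"),
            "crosstab": self.crosstab.to_dict(orient="records"),
            "metrics": _round_metrics(self.metrics),
            "class_variability": var.reset_index().to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def tabulate_class_variability(features, descriptors: pd.DataFrame,
                               classes: dict[str, str]) -> pd.DataFrame:
    """Per-class occurrence and magnitude of selected descriptor columns.

    For each feature and class: the percentage of kinases in the class with
    a non-zero value, plus mean and SD of the value.  For tripeptide
    composition columns "non-zero" means the motif occurs at least once.
    """
    rows = {}
    cls_order = sorted(set(classes.values()))
    for feat in features:
        if feat not in descriptors.columns:
            raise KeyError(f"feature {feat!r} not in descriptor matrix")
        row = {}
        for cls in cls_order:
            kin = [k for k, c in classes.items() if c == cls]
            vals = descriptors.loc[kin, feat].to_numpy()
            tag = cls.replace(" ", "_")
            row[f"{tag}.pct_kinases"] = 100.0 * float((vals > 0).sum()) / len(vals) if len(vals) else 0.0
            row[f"{tag}.mean"] = float(vals.mean()) if len(vals) else 0.0
            row[f"{tag}.sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows[feat] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full analysis and write intermediates + report to outdir."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    pkg_log = logging.getLogger("acprop")
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    fh.setLevel(logging.INFO)
    prev_level = pkg_log.level
    pkg_log.addHandler(fh)
    if pkg_log.level > logging.INFO or pkg_log.level == logging.NOTSET:
        pkg_log.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir, seeds, t0)
    finally:
        pkg_log.removeHandler(fh)
        fh.close()
        pkg_log.setLevel(prev_level)


def _run_pipeline(config: PipelineConfig, outdir: Path, seeds: list[int],
                  t0: float) -> StudyReport:

    # --- inputs -----------------------------------------------------------
    if config.study is not None:
        bundle = generate_study(config.study)
        write_fixtures(bundle, outdir / "inputs")
        proteins = bundle.proteins
        records = [r for kid in sorted(bundle.activity_tables)
                   for r in bundle.activity_tables[kid]]
    else:
        proteins = read_fasta(config.fasta)
        records = read_activity_table(config.activities)
    if config.smarts is not None:
        from .curation import read_smarts_list

        smarts = read_smarts_list(config.smarts)
    else:
        smarts = list(aadata.demo_type2_smarts())
    log.info("inputs: %d proteins, %d activity rows (%.1fs)",
             len(proteins), len(records), time.time() - t0)

    # --- curation ---------------------------------------------------------
    clog = CurationLog()
    curated = curate(records, smarts, clog)
    write_curated_csv(curated, outdir / "curated.csv")
    log.info("curation: %d molecules kept, %d type-II excluded (%.1fs)",
             len(curated), clog.type2_excluded, time.time() - t0)

    # --- MMP / AC mining --------------------------------------------------
    by_kinase: dict[str, list] = {}
    for c in curated:
        by_kinase.setdefault(c.kinase_id, []).append(c)
    all_mmps = []
    props = []
    for kid in sorted(by_kinase):
        mmps = label_cliffs(find_mmps(by_kinase[kid], kid))
        all_mmps.extend(mmps)
        props.append((kid, mmps, len(by_kinase[kid])))
    pcts = np.array([100.0 * sum(m.is_cliff for m in mm) / len(mm) if mm else 0.0
                     for _, mm, _ in props])
    threshold_b = (config.threshold_b if config.threshold_b is not None
                   else float(pcts.mean() + pcts.std(ddof=1)) if len(pcts) > 1
                   else THRESHOLD_B_DEFAULT)
    propensities = [kinase_propensity(kid, mm, n, threshold_b)
                    for kid, mm, n in props]
    crosstab = transform_crosstab(all_mmps)
    write_mmp_csv(all_mmps, outdir / "mmps.csv")
    write_propensity_csv(propensities, outdir / "propensity.csv")
    write_crosstab_csv(crosstab, outdir / "crosstab.csv")
    log.info("mmp: %d pairs, %d cliffs, threshold B %.2f (%.1fs)", len(all_mmps),
             sum(m.is_cliff for m in all_mmps), threshold_b, time.time() - t0)

    # --- descriptors ------------------------------------------------------
    desc = descriptor_matrix(proteins)
    desc.to_csv(outdir / "descriptors.csv", float_format="%.10g")
    log.info("descriptors: %s (%.1fs)", desc.shape, time.time() - t0)

    # --- per-scheme ML ----------------------------------------------------
    metrics: dict = {}
    selected_tripeptides: list[str] = []
    ga_full = GAParams()
    for scheme in config.schemes:
        fm = build_feature_matrix(desc, propensities, scheme,
                                  config.test_fraction, seed=seeds[0])
        Xtr, ytr = fm.train()
        Xte, yte = fm.test()
        metrics[scheme] = {}
        for family in config.learners:
            spec = LearnerSpec(family=family, seed=seeds[1])
            model = fit_classifier(Xtr, ytr, spec, scheme)
            ranking = global_feature_importance(Xtr, model, seed=seeds[2])
            candidates = list(ranking.retained[:config.gfi_top])
            ga = config.ga if config.ga is not None else ga_full
            best = ga_feature_select(Xtr, ytr, spec, candidates, ga,
                                     seed=seeds[3], scheme=scheme)
            cols = list(best.features)
            cv_pred = leave20_cv(Xtr[cols], ytr, spec, seed=seeds[4], scheme=scheme)
            cv_rep = evaluate(ytr, cv_pred, fm.classes)
            final = fit_classifier(Xtr[cols], ytr, spec, scheme)
            test_rep = evaluate(yte, final.predict(Xte[cols]), fm.classes)
            scramble = y_scramble(Xtr, ytr, spec, cols, config.n_scramble,
                                  seed=seeds[5], scheme=scheme)
            metrics[scheme][family] = {
                "n_candidates": len(candidates),
                "selected_features": cols,
                "ga_fitness": best.fitness,
                "cv": {"accuracy": cv_rep.accuracy, "kappa": cv_rep.kappa,
                       "band": cv_rep.band},
                "test": {"accuracy": test_rep.accuracy, "kappa": test_rep.kappa,
                         "band": test_rep.band},
                "scrambling": scramble.to_dict(),
            }
            selected_tripeptides.extend(
                c for c in cols if len(c) == 3 and c.isalpha() and c.isupper())
            log.info("%s/%s: cv kappa %.2f, test kappa %.2f (%.1fs)", scheme, family,
                     cv_rep.kappa, test_rep.kappa, time.time() - t0)

    # --- class variability table -----------------------------------------
    classes_default = {p.kinase_id: p.class_default for p in propensities}
    tri = sorted(set(selected_tripeptides))
    variability = (tabulate_class_variability(tri, desc, classes_default)
                   if tri else pd.DataFrame())
    prop_df = pd.DataFrame([{
        "kinase_id": p.kinase_id, "n_inhibitors": p.n_inhibitors,
        "n_mmps": p.n_mmps, "n_acs": p.n_acs,
        "acs_over_mmps_pct": p.acs_over_mmps_pct,
        "class_default": p.class_default, "class_A": p.class_A,
        "class_B": p.class_B} for p in propensities])
    cross_df = pd.DataFrame([{
        "frag_a": t.transform_key[0], "frag_b": t.transform_key[1],
        "n_ac_kinases": t.n_ac_kinases, "n_nonac_kinases": t.n_nonac_kinases,
        "behavior": t.behavior} for t in crosstab])
    report = StudyReport(prop_df, cross_df, metrics, variability, threshold_b,
                         config.seed)
    report.to_json(outdir / "report.json")
    if not variability.empty:
        variability.to_csv(outdir / "class_variability.csv")
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report
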