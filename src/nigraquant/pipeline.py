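"""End-to-end orchestration: simulate -> extract -> composite -> stats.

One seeded run produces the full study-style report bundle: the feature
and subject tables, group-difference summaries with effect sizes and ROC,
the clinical correlation grid, reader-agreement statistics, ROC curve
points for plotting, and a human-readable markdown summary.  Identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composite import COMPOSITE_FACTORS, add_composite
from .datatypes import FEATURE_COLUMNS, ThresholdPolicy
from .features import extract_feature_vector
from .phantom import (PhantomConfig, bundles_to_tables, generate_cohort,
                      generate_feature_table, simulate_reader_ratings,
                      simulate_second_rater)
from .stats import (cohen_kappa, empirical_auc_ci, fleiss_kappa,
                    group_summary_table, icc_absolute_agreement,
                    spearman_bonferroni_table, youden_operating_point)

log = logging.getLogger("nigraquant")

SCHEMA_VERSION = "1.0"

#: Reader (sensitivity, specificity) defaults for the simulated visual
#: ratings: two senior readers, one junior, one non-neuroradiologist.
DEFAULT_READER_ACCURACIES = ((1.00, 0.98), (0.99, 0.96),
                             (0.94, 0.89), (0.74, 0.80))

#: Per-modality reliability targets for the simulated second segmenter.
DEFAULT_ICC_TARGETS = {"nm": 0.88, "qsm": 0.95, "smwi": 0.97}

MODALITY_COLS = {
    "nm": ("nm_signal", "nm_contrast_range", "nm_size", "nm_size_high"),
    "qsm": ("qsm_chi_mean", "qsm_size", "qsm_size_low"),
    "smwi": ("smwi_signal", "smwi_size", "smwi_size_lowsig"),
}

CLINICAL_CORR_COLS = ("age", "mmse", "updrs1", "updrs2", "updrs3")

#: Features enter the clinical correlation grid when their AUC clears this.
CORR_AUC_GATE = 0.80


@dataclass
class RunConfig:
    """Single-run configuration (YAML-serialisable)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    reader_accuracies: tuple = DEFAULT_READER_ACCURACIES
    icc_targets: dict = field(default_factory=lambda: dict(DEFAULT_ICC_TARGETS))
    stats_method: str = "auto"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import load_yaml

        raw = load_yaml(path)
        kwargs = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("voxel_dims_nm", "voxel_dims_qsm"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "policy" in raw:
            kwargs["policy"] = ThresholdPolicy(**raw["policy"])
        if "reader_accuracies" in raw:
            kwargs["reader_accuracies"] = tuple(
                tuple(p) for p in raw["reader_accuracies"])
        for key in ("icc_targets", "stats_method"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the in-memory report dict (also serialised to ``out_dir``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.phantom.seed
    t0 = time.time()
    log.info("simulate: n=%d/%d seed=%d image_level=%s",
             config.phantom.n_controls, config.phantom.n_patients, seed,
             config.phantom.image_level)

    if config.phantom.image_level:
        bundles = generate_cohort(config.phantom)
        features, subjects = bundles_to_tables(bundles)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in bundles:
                fv = extract_feature_vector(b.volumes, b.masks, config.policy)
                row = {"subject_id": b.record.subject_id,
                       "group": b.record.group}
                row.update({k: v for k, v in fv.as_dict().items()
                            if k != "composite"})
                rows.append(row)
        features = pd.DataFrame(rows)
    else:
        features, subjects = generate_feature_table(config.phantom)
    log.info("simulate: done in %.2fs", time.time() - t0)

    features = add_composite(features)
    feature_cols = list(FEATURE_COLUMNS) + ["composite"]

    t1 = time.time()
    group_stats = group_summary_table(features, feature_cols,
                                      method=config.stats_method)
    log.info("group stats: done in %.2fs", time.time() - t1)

    # ROC report for the composite and its factors.
    is_pat = (features["group"] == "patient").to_numpy()
    roc_rows, curves = [], []
    for f in list(COMPOSITE_FACTORS) + ["composite"]:
        scores = features[f].to_numpy(dtype=float)
        auc, ci = empirical_auc_ci(scores, is_pat, positive_direction="lower")
        op = youden_operating_point(scores, is_pat,
                                    positive_direction="lower")
        log.info("ROC %s: AUC=%.3f cutoff=%.4g", f, auc, op.cutoff)
        roc_rows.append({"feature": f, "auc": auc, "auc_ci_low": ci[0],
                         "auc_ci_high": ci[1], "cutoff": op.cutoff,
                         "sensitivity": op.sensitivity,
                         "specificity": op.specificity,
                         "accuracy": op.accuracy})
        fpr, tpr = _roc_points(-scores, is_pat)
        curves.append(pd.DataFrame({"feature": f, "fpr": fpr, "tpr": tpr}))
    roc_summary = pd.DataFrame(roc_rows)
    roc_curves = pd.concat(curves, ignore_index=True)

    # Clinical correlation grid for the highly discriminant features.
    gated = group_stats.loc[
        (group_stats["auc"] > CORR_AUC_GATE)
        & (group_stats["feature"] != "composite"), "feature"].tolist()
    correlations = spearman_bonferroni_table(
        features, subjects, gated, CLINICAL_CORR_COLS)

    # Reader agreement on simulated visual ratings.
    ratings = simulate_reader_ratings(subjects, config.reader_accuracies,
                                      seed=seed + 1)
    reader_cols = [c for c in ratings.columns if c.startswith("reader_")]
    rating_mat = ratings[reader_cols].to_numpy()
    agreement = {
        "fleiss_kappa_all_readers": fleiss_kappa(rating_mat).value,
        "cohen_kappa_senior_readers": cohen_kappa(
            rating_mat[:, 0], rating_mat[:, 1]).value,
    }
    # Reliability of the quantitative measures against a second segmenter.
    rater2 = features
    icc_values = {}
    for modality, icc_t in config.icc_targets.items():
        cols = MODALITY_COLS[modality]
        rater2 = simulate_second_rater(features, icc_t, seed=seed + 2,
                                       feature_cols=cols)
        per_feature = [icc_absolute_agreement(
            np.column_stack([features[c], rater2[c]])).value for c in cols]
        icc_values[f"icc_{modality}"] = float(np.mean(per_feature))
    agreement.update(icc_values)

    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "n_controls": int(config.phantom.n_controls),
        "n_patients": int(config.phantom.n_patients),
        "image_level": bool(config.phantom.image_level),
        "thresholds": {
            "qsm_chi_cutoff": config.policy.qsm_chi_cutoff,
            "nm_k": config.policy.nm_k,
            "smwi_low_quantile": config.policy.smwi_low_quantile,
        },
        "agreement": agreement,
        "composite_auc": float(
            roc_summary.loc[roc_summary.feature == "composite",
                            "auc"].iloc[0]),
    }
    write_report({"features": features, "subjects": subjects,
                  "ratings": ratings, "group_stats": group_stats,
                  "roc_summary": roc_summary, "roc_curves": roc_curves,
                  "correlations": correlations, "summary": report}, out)
    log.info("pipeline complete in %.2fs", time.time() - t0)
    return report


def _roc_points(scores: np.ndarray, positive: np.ndarray):
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(positive.astype(int), scores)
    return fpr, tpr


def write_report(reports: dict, out_dir) -> list[Path]:
    """Serialise the report bundle: CSVs, JSON summary, markdown digest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("features", "subjects", "ratings", "group_stats",
                 "roc_summary", "roc_curves", "correlations"):
        if name in reports:
            p = out / f"{name}.csv"
            reports[name].to_csv(p, index=False)
            written.append(p)
    summary = reports.get("summary", {})
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(p)
    written.append(_markdown_digest(reports, out / "report.md"))
    return written


def _markdown_digest(reports: dict, path: Path) -> Path:
    lines = ["# nigraquant run report", ""]
    summary = reports.get("summary", {})
    lines += [f"- schema version: {summary.get('schema_version')}",
              f"- seed: {summary.get('seed')}",
              f"- cohort: {summary.get('n_controls')} controls / "
              f"{summary.get('n_patients')} patients", ""]
    if "group_stats" in reports:
        lines += ["## Group differences", "",
                  reports["group_stats"].round(3).to_markdown(index=False),
                  ""]
    if "roc_summary" in reports:
        lines += ["## Classification", "",
                  reports["roc_summary"].round(3).to_markdown(index=False),
                  ""]
    if "correlations" in reports:
        lines += ["## Clinical correlations (Bonferroni-screened)", "",
                  reports["correlations"].round(3).to_markdown(index=False),
                  ""]
    if summary.get("agreement"):
        lines += ["## Agreement", ""]
        lines += [f"- {k}: {v:.3f}" for k, v in summary["agreement"].items()]
        lines.append("")
    path.write_text("\n".join(lines))
    return path
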