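"""Synthetic cohort generator.

Generates case-control cohorts whose per-group feature and clinical
marginals, and whose pooled feature-clinical rank correlations, match the
calibration targets.  Two levels are available:

* table level (default): per-subject truth feature vectors and clinical
  records only -- sufficient for every statistical stage;
* image level: additionally renders NM / QSM / SWI-magnitude volumes and
  mask sets per subject such that feature extraction on the noiseless
  volumes reproduces the truth features exactly (see ``nigraquant.render``).

All randomness flows from ``PhantomConfig.seed`` through a single
``numpy.random.Generator``; identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import (DEFAULT_CLINICAL_MARGINALS,
                          DEFAULT_FEATURE_MARGINALS, DEFAULT_MALE_FRACTION,
                          DEFAULT_TARGET_RANK_CORRELATIONS,
                          HY_SEVERITY_LOADING, THRESHOLDED_PARENT,
                          CopulaCalibration, assemble_latent_scores,
                          fit_copula_cached, fraction_transform,
                          marginal_transform)
from .datatypes import (CLINICAL_COLUMNS, FEATURE_COLUMNS, FeatureVector,
                        SubjectRecord, SyntheticSubjectBundle)


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the calibration cohort: 111 controls / 80 patients,
    the published per-group feature and clinical summaries, and the pooled
    feature-clinical Spearman targets.
    """

    n_controls: int = 111
    n_patients: int = 80
    seed: int = 0
    feature_marginals: dict = field(
        default_factory=lambda: {k: {g: tuple(v) for g, v in d.items()}
                                 for k, d in DEFAULT_FEATURE_MARGINALS.items()})
    clinical_marginals: dict = field(
        default_factory=lambda: {k: {g: tuple(v) for g, v in d.items()}
                                 for k, d in DEFAULT_CLINICAL_MARGINALS.items()})
    target_rank_correlations: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_TARGET_RANK_CORRELATIONS.items()})
    gradient_strength: float = 1.0
    noise_sd: float = 3.0  # image noise, a.u./ppb (volume level only)
    voxel_dims_nm: tuple[float, float, float] = (0.5, 0.5, 3.0)
    voxel_dims_qsm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    image_level: bool = False

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_patients <= 0:
            raise ValueError("group sizes must be positive")
        for table in (self.feature_marginals, self.clinical_marginals):
            for name, groups in table.items():
                for g, (mean, sd) in groups.items():
                    if sd < 0:
                        raise ValueError(f"negative sd for {name}/{g}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for dims in (self.voxel_dims_nm, self.voxel_dims_qsm):
            if any(d <= 0 for d in dims):
                raise ValueError("voxel dimensions must be positive")

    def fit(self) -> CopulaCalibration:
        """Fitted (cached) copula calibration for these study conditions."""
        return fit_copula_cached(self.feature_marginals,
                                 self.clinical_marginals,
                                 self.target_rank_correlations,
                                 self.n_controls, self.n_patients)


def _sample_tables(config: PhantomConfig, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised core: draw (features, subjects) tables for the cohort."""
    cop = config.fit()
    n_c, n_p = config.n_controls, config.n_patients
    n = n_c + n_p
    group = np.array(["control"] * n_c + ["patient"] * n_p)
    is_pat = group == "patient"
    group_sel = (("control", ~is_pat), ("patient", is_pat))

    z = rng.standard_normal(n)  # latent severity (within-group)
    eta = rng.standard_normal(n)  # age factor
    all_vars = list(FEATURE_COLUMNS) + list(CLINICAL_COLUMNS) + ["hy", "ledd"]
    eps = {v: rng.standard_normal(n) for v in all_vars}

    scores = assemble_latent_scores(z, eta, eps, cop,
                                    config.gradient_strength)
    for name in all_vars:
        if name not in scores and name != "smwi_size":
            scores[name] = eps[name]
    b_hy = HY_SEVERITY_LOADING
    scores["hy"] = b_hy * z + np.sqrt(1 - b_hy * b_hy) * eps["hy"]

    features = pd.DataFrame(index=range(n), columns=list(FEATURE_COLUMNS),
                            dtype=float)
    clinical: dict[str, np.ndarray] = {}
    plain = [v for v in all_vars
             if v not in THRESHOLDED_PARENT and v != "smwi_size"]
    for name in plain:
        out = np.full(n, np.nan)
        marg = (config.feature_marginals.get(name)
                or config.clinical_marginals.get(name))
        for g, sel in group_sel:
            if g not in marg:
                continue  # e.g. LEDD for controls
            mean, sd = marg[g]
            out[sel] = marginal_transform(name, scores[name][sel], mean, sd)
        if name in FEATURE_COLUMNS:
            features[name] = out
        else:
            clinical[name] = out
    # Unthresholded mask sizes are physical areas: keep them positive.
    features["nm_size"] = features["nm_size"].clip(lower=1.0)
    features["qsm_size"] = features["qsm_size"].clip(lower=1.0)
    features["smwi_size"] = features["qsm_size"]  # same physical mask

    # Thresholded sizes: surviving beta fraction x parent size.
    for name, parent in THRESHOLDED_PARENT.items():
        out = np.full(n, np.nan)
        for g, sel in group_sel:
            ab, mean_frac = cop.fraction_params[(name, g)]
            frac = fraction_transform(scores[name][sel], ab, mean_frac)
            out[sel] = frac * features[parent].to_numpy()[sel]
        features[name] = out

    ids = [f"S{i + 1:04d}" for i in range(n)]
    hy = np.where(is_pat,
                  np.clip(np.round(clinical["hy"] * 2) / 2, 0.0, 5.0), 0.0)
    sex = np.where(
        rng.random(n) < np.where(is_pat, DEFAULT_MALE_FRACTION["patient"],
                                 DEFAULT_MALE_FRACTION["control"]),
        "M", "F")
    subjects = pd.DataFrame({
        "subject_id": ids,
        "group": group,
        "age": clinical["age"],
        "sex": sex,
        "updrs1": clinical["updrs1"],
        "updrs2": clinical["updrs2"],
        "updrs3": clinical["updrs3"],
        "mmse": clinical["mmse"],
        "hy": hy,
        "ledd": clinical["ledd"],
        "latent_severity": z,
    })
    features.insert(0, "subject_id", ids)
    features.insert(1, "group", group)
    return features, subjects


def generate_feature_table(config: PhantomConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort's (features, subjects) tables (table level).

    Deterministic in ``config.seed``; per-group sample moments converge to
    ``feature_marginals`` and pooled rank correlations approach
    ``target_rank_correlations`` as n grows.
    """
    rng = np.random.default_rng(config.seed)
    return _sample_tables(config, rng)


def generate_cohort(config: PhantomConfig) -> list[SyntheticSubjectBundle]:
    """Generate the full cohort as per-subject bundles.

    With ``config.image_level`` set, each bundle carries rendered volumes
    and masks; truth features are then quantised to the voxel lattice so
    that noiseless extraction reproduces them exactly.
    """
    rng = np.random.default_rng(config.seed)
    features, subjects = _sample_tables(config, rng)
    bundles = []
    for (_, frow), (_, srow) in zip(features.iterrows(), subjects.iterrows()):
        record = SubjectRecord(
            subject_id=srow["subject_id"], group=srow["group"],
            age=float(srow["age"]), sex=srow["sex"],
            updrs1=float(srow["updrs1"]), updrs2=float(srow["updrs2"]),
            updrs3=float(srow["updrs3"]), mmse=float(srow["mmse"]),
            hy=float(srow["hy"]),
            ledd=None if pd.isna(srow["ledd"]) else float(srow["ledd"]),
            latent_severity=float(srow["latent_severity"]))
        truth = FeatureVector(**{k: float(frow[k]) for k in FEATURE_COLUMNS})
        bundle = SyntheticSubjectBundle(record=record, truth_features=truth)
        if config.image_level:
            from .render import render_subject_volumes
            volumes, masks, truth = render_subject_volumes(
                truth, config,
                rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            bundle.volumes, bundle.masks = volumes, masks
            bundle.truth_features = truth
        bundles.append(bundle)
    return bundles


def bundles_to_tables(bundles: Sequence[SyntheticSubjectBundle]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collect bundles back into (features, subjects) DataFrames."""
    feat_rows, subj_rows = [], []
    for b in bundles:
        d = {"subject_id": b.record.subject_id, "group": b.record.group}
        d.update({k: v for k, v in b.truth_features.as_dict().items()
                  if k != "composite"})
        feat_rows.append(d)
        r = b.record
        subj_rows.append({
            "subject_id": r.subject_id, "group": r.group, "age": r.age,
            "sex": r.sex, "updrs1": r.updrs1, "updrs2": r.updrs2,
            "updrs3": r.updrs3, "mmse": r.mmse, "hy": r.hy,
            "ledd": np.nan if r.ledd is None else r.ledd,
            "latent_severity": r.latent_severity})
    return pd.DataFrame(feat_rows), pd.DataFrame(subj_rows)


# --------------------------------------------------------------------------
# Reader-rating simulation
# --------------------------------------------------------------------------

def simulate_reader_ratings(records: Sequence[SubjectRecord] | pd.DataFrame,
                            reader_accuracies: Sequence[tuple[float, float]],
                            seed: int) -> pd.DataFrame:
    """Binary PD/non-PD ratings per reader with stated error rates.

    ``reader_accuracies`` is one (sensitivity, specificity) pair per
    reader; conditional on the true group each reader rates independently.
    Returns a DataFrame with ``subject_id``, ``group``, and one
    ``reader_k`` column per reader (1 = rated PD).
    """
    for sens, spec in reader_accuracies:
        if not (0 <= sens <= 1 and 0 <= spec <= 1):
            raise ValueError("sensitivities/specificities must lie in [0, 1]")
    if isinstance(records, pd.DataFrame):
        ids = records["subject_id"].to_numpy()
        groups = records["group"].to_numpy()
    else:
        ids = np.array([r.subject_id for r in records])
        groups = np.array([r.group for r in records])
    rng = np.random.default_rng(seed)
    is_pat = groups == "patient"
    out = {"subject_id": ids, "group": groups}
    for k, (sens, spec) in enumerate(reader_accuracies, start=1):
        p_rate_pd = np.where(is_pat, sens, 1.0 - spec)
        out[f"reader_{k}"] = (rng.random(len(ids)) < p_rate_pd).astype(int)
    return pd.DataFrame(out)


def simulate_second_rater(features: pd.DataFrame, icc_target: float,
                          seed: int,
                          feature_cols: Sequence[str] = FEATURE_COLUMNS
                          ) -> pd.DataFrame:
    """A second segmenter's feature table with a target reliability.

    Adds zero-mean measurement noise per feature to a copy of the first
    rater's (noise-free) table.  With error confined to one of the two
    raters the expected ICC(2,1) is sigma_b^2 / (sigma_b^2 +
    sigma_e^2 / 2), so sigma_e^2 = 2 sigma_b^2 (1 - ICC) / ICC hits the
    target, with sigma_b^2 the between-subject feature variance.
    """
    if not 0 < icc_target <= 1:
        raise ValueError("icc_target must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = features.copy()
    for col in feature_cols:
        x = out[col].to_numpy(dtype=float)
        sigma_b = np.std(x, ddof=1)
        sigma_e = sigma_b * np.sqrt(2.0 * (1 - icc_target) / icc_target)
        out[col] = np.clip(x + rng.normal(0.0, sigma_e, len(x)), 0.0, None)
    return out
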