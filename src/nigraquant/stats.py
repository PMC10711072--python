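"""Statistical layer: group differences, ROC, correlations, agreement.

Reproduces the study-style statistical report: per-feature group
comparisons with pooled-SD effect sizes, empirical ROC with DeLong
confidence intervals and Youden operating points, Bonferroni-screened
Spearman correlation grids against clinical scores, and rater-agreement
statistics (ICC(2,1), Fleiss' and Cohen's kappa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "hedges_g", "group_compare", "empirical_auc", "empirical_auc_ci",
    "youden_operating_point", "spearman_bonferroni_table",
    "icc_absolute_agreement", "fleiss_kappa", "cohen_kappa",
    "relative_difference_summary", "group_summary_table", "OperatingPoint",
    "AgreementResult",
]


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class AgreementResult:
    statistic: str  # "fleiss_kappa" | "cohen_kappa" | "icc"
    value: float
    n_subjects: int
    n_raters: int


# --------------------------------------------------------------------------
# Effect sizes and group comparison
# --------------------------------------------------------------------------

def hedges_g(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int,
             corrected: bool = False) -> float:
    """Pooled-SD standardised mean difference (absolute value).

    ``s_pooled^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)``.  By
    default no small-sample correction is applied -- the variant that
    matches the reported effect-size column; ``corrected=True`` applies
    the usual J factor.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative sd")
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance: degenerate groups")
    g = abs(mean2 - mean1) / np.sqrt(s2)
    if corrected:
        df = n1 + n2 - 2
        g *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(g)


def group_compare(values: np.ndarray, labels: np.ndarray,
                  method: str = "auto") -> float:
    """Two-sided p-value for a two-group comparison.

    ``t_test`` (Welch-free, pooled-variance two-sample t), Kruskal-Wallis
    rank test, or ``auto``: Shapiro-Wilk normality screen at alpha = 0.05
    in both groups chooses the t-test, otherwise Kruskal-Wallis.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need exactly two nonempty groups")
    a, b = groups
    if method == "auto":
        normal = all(len(g) >= 3 and (np.ptp(g) == 0 or
                                      sps.shapiro(g[:5000]).pvalue > 0.05)
                     for g in (a, b))
        method = "t_test" if normal else "kruskal_wallis"
    if method == "t_test":
        return float(sps.ttest_ind(a, b).pvalue)
    if method == "kruskal_wallis":
        if np.ptp(values) == 0:
            raise ValueError("constant data: rank test undefined")
        return float(sps.kruskal(a, b).pvalue)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("ROC undefined: one class absent")
    return y


def empirical_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney concordance AUC, ties counted 1/2.

    ``positive`` marks the class whose scores are expected higher.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(positive)
    ranks = sps.rankdata(scores)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (placement-value form)."""
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    # Placement of each positive among negatives and vice versa.
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def empirical_auc_ci(scores: np.ndarray, labels: np.ndarray,
                     positive_direction: str = "higher"
                     ) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% DeLong confidence interval.

    ``positive_direction``: ``"higher"`` if cases score higher,
    ``"lower"`` if cases score lower (the AUC of ``-scores``).
    """
    scores = np.asarray(scores, dtype=float)
    if positive_direction == "lower":
        scores = -scores
    elif positive_direction != "higher":
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    y = _check_binary(labels)
    auc = empirical_auc(scores, y)
    se = float(np.sqrt(_delong_variance(scores, y)))
    half = 1.959963984540054 * se
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def youden_operating_point(scores: np.ndarray, labels: np.ndarray,
                           positive_direction: str = "higher"
                           ) -> OperatingPoint:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between consecutive distinct scores
    (plus outer sentinels); a subject scores positive when on the case
    side of the cutoff.  Ties in J prefer the higher-specificity cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    flip = positive_direction == "lower"
    s = -scores if flip else scores
    y = _check_binary(labels)
    uniq = np.unique(s)
    mids = np.concatenate([[uniq[0] - 1.0], (uniq[1:] + uniq[:-1]) / 2.0,
                           [uniq[-1] + 1.0]])
    n_pos, n_neg = y.sum(), (~y).sum()
    best = None
    for c in mids:
        pred = s > c
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and spec > best[2]):
            acc = float((pred == y).mean())
            best = (j, sens, spec, acc, c)
    cutoff = -best[4] if flip else best[4]
    return OperatingPoint(cutoff=float(cutoff), sensitivity=best[1],
                          specificity=best[2], accuracy=best[3])


# --------------------------------------------------------------------------
# Correlation grid
# --------------------------------------------------------------------------

def spearman_bonferroni_table(features: pd.DataFrame, clinical: pd.DataFrame,
                              feature_cols: Sequence[str],
                              clinical_cols: Sequence[str],
                              alpha: float = 0.05) -> pd.DataFrame:
    """Spearman r with Bonferroni-screened significance flags.

    One row per (feature, clinical score) pair; the family is the full
    grid, so the adjusted threshold is ``alpha / (n_features x
    n_clinical)``.  Cells with fewer than 3 complete pairs are undefined.
    """
    family = len(feature_cols) * len(clinical_cols)
    rows = []
    for f in feature_cols:
        for c in clinical_cols:
            x = features[f].to_numpy(dtype=float)
            y = clinical[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                rows.append({"feature": f, "clinical": c, "r": np.nan,
                             "p": np.nan, "n": int(ok.sum()),
                             "significant": False})
                continue
            res = sps.spearmanr(x[ok], y[ok])
            rows.append({"feature": f, "clinical": c,
                         "r": float(res.statistic), "p": float(res.pvalue),
                         "n": int(ok.sum()),
                         "significant": bool(res.pvalue < alpha / family)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Agreement
# --------------------------------------------------------------------------

def icc_absolute_agreement(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix.
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings matrix must be complete")
    if np.allclose(ratings.mean(axis=1), ratings.mean()):
        raise ValueError("zero between-subject variance: ICC degenerate")
    n, k = ratings.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.ravel(),
    })
    icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score")
    # ICC(A,1): two-way, absolute agreement, single rater (aka ICC(2,1)).
    value = float(icc.loc[icc["Type"].isin(["ICC(A,1)", "ICC2"]),
                          "ICC"].iloc[0])
    return AgreementResult("icc", value, n, k)


def fleiss_kappa(ratings: np.ndarray,
                 categories: Optional[Sequence] = None) -> AgreementResult:
    """Fleiss' kappa for categorical ratings (subjects x raters)."""
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 2 raters")
    table, cats = aggregate_raters(ratings)
    if categories is not None:
        missing = [c for c in categories if c not in cats]
        if missing:
            table = np.hstack([table,
                               np.zeros((table.shape[0], len(missing)), int)])
    p_cat = table.sum(axis=0) / table.sum()
    if np.max(p_cat) == 1.0:
        raise ValueError("all ratings in one category: kappa undefined")
    value = float(sm_fleiss(table))
    return AgreementResult("fleiss_kappa", value, ratings.shape[0],
                           ratings.shape[1])


def cohen_kappa(ratings_a: np.ndarray, ratings_b: np.ndarray
                ) -> AgreementResult:
    """Cohen's kappa between two raters' paired categorical ratings."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length rating vectors")
    cats = np.unique(np.concatenate([a, b]))
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    if float(pa @ pb) == 1.0:
        raise ValueError("chance agreement is 1: kappa undefined")
    return AgreementResult("cohen_kappa", float(cohen_kappa_score(a, b)),
                           len(a), 2)


# --------------------------------------------------------------------------
# Relative contrasts
# --------------------------------------------------------------------------

def relative_difference_summary(group_means: dict[str, tuple[float, float]],
                                magnification_pairs: Optional[dict[str, tuple[str, str]]] = None
                                ) -> pd.DataFrame:
    """Percent and ratio contrasts between group means.

    ``group_means`` maps feature -> (control mean, patient mean).  Emits
    the percent reduction ``100 (m_c - m_p) / m_c`` and both mean ratios.
    ``magnification_pairs`` maps a label -> (feature before thresholding,
    feature after); the thresholding magnification is the ratio of
    absolute relative differences after/before.
    """
    rows = []
    for name, (mc, mp) in group_means.items():
        if mc <= 0 or mp <= 0:
            raise ValueError(f"{name}: group means must be positive")
        rows.append({
            "feature": name,
            "pct_reduction": 100.0 * (mc - mp) / mc,
            "ratio_patient_control": mp / mc,
            "ratio_control_patient": mc / mp,
            "magnification": np.nan,
        })
    out = pd.DataFrame(rows).set_index("feature")
    if magnification_pairs:
        for label, (before, after) in magnification_pairs.items():
            mc0, mp0 = group_means[before]
            mc1, mp1 = group_means[after]
            mag = abs((mc1 - mp1) / mc1) / abs((mc0 - mp0) / mc0)
            out.loc[after, "magnification"] = mag
    return out


# --------------------------------------------------------------------------
# Study-style group table
# --------------------------------------------------------------------------

def group_summary_table(features: pd.DataFrame,
                        feature_cols: Sequence[str],
                        group_col: str = "group",
                        method: str = "auto") -> pd.DataFrame:
    """Per-feature group summary: n/mean/sd per group, p, g, AUC (95% CI).

    The ROC direction per feature follows the group means (cases score
    lower when the patient mean is below the control mean), so every AUC
    is reported as a discrimination (>= 0.5 in expectation).
    """
    is_pat = (features[group_col] == "patient").to_numpy()
    rows = []
    for f in feature_cols:
        x = features[f].to_numpy(dtype=float)
        xc, xp = x[~is_pat], x[is_pat]
        direction = "lower" if xp.mean() < xc.mean() else "higher"
        auc, ci = empirical_auc_ci(x, is_pat, positive_direction=direction)
        rows.append({
            "feature": f,
            "n_control": len(xc), "mean_control": xc.mean(),
            "sd_control": xc.std(ddof=1),
            "n_patient": len(xp), "mean_patient": xp.mean(),
            "sd_patient": xp.std(ddof=1),
            "p_value": group_compare(x, features[group_col].to_numpy(),
                                     method=method),
            "hedges_g": hedges_g(xc.mean(), xc.std(ddof=1), len(xc),
                                 xp.mean(), xp.std(ddof=1), len(xp)),
            "direction": direction,
            "auc": auc, "auc_ci_low": ci[0], "auc_ci_high": ci[1],
        })
    return pd.DataFrame(rows)
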