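"""Default cohort calibration and the latent-severity copula fit.

The phantom's default parameters emulate a large single-centre 3T
case-control study of Parkinson's disease (111 healthy controls, 80
patients) whose substantia-nigra mask parameters, clinical summaries, and
pooled feature-clinical rank correlations serve as calibration targets.

Marginal families
-----------------
Signal intensities, mean susceptibility, unthresholded mask sizes, and age
are Gaussian per group.  Nonnegative skewed scores -- UPDRS, LEDD,
cognitive deficit (30 - MMSE), and the excess contrast ratio
(contrast_range - 1) -- use moment-matched gamma marginals: several print
a coefficient of variation above 1, which no zero-truncated normal can
reach, while a gamma matches any (mean, sd) exactly on nonnegative
support.  Each size-after-threshold parameter is modelled as (surviving
fraction) x (parent mask size), with the fraction a moment-matched beta:
this enforces thresholded <= unthresholded by construction while
reproducing the printed product moments exactly (independence of fraction
and parent size within group).

Dependence structure
--------------------
One latent severity per subject drives the four discriminant imaging
parameters and the clinical scores (Gaussian one-factor copula); each
marginal is an increasing transform of its latent Gaussian score, so rank
order is inherited.  Pooled-cohort rank correlations mix within-group
dependence with between-group separation, and the heavy skew of the
clinical marginals makes closed-form calibration inaccurate; loadings are
therefore initialised analytically (two-component Gaussian-mixture moment
algebra + rank-1 SVD) and refined by deterministic large-sample
simulation against the pooled Spearman targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps
from scipy.special import ndtr

# --------------------------------------------------------------------------
# Marginal summaries, (mean, sd) per group.
# --------------------------------------------------------------------------

#: Feature marginals: feature -> {"control": (mean, sd), "patient": (mean, sd)}.
DEFAULT_FEATURE_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "nm_signal": {"control": (226.8, 36.6), "patient": (211.2, 54.2)},
    "nm_contrast_range": {"control": (1.18, 0.12), "patient": (1.10, 0.25)},
    "nm_size": {"control": (556.8, 108.1), "patient": (580.34, 184.4)},
    "nm_size_high": {"control": (92.3, 65.6), "patient": (29.1, 30.6)},
    "qsm_chi_mean": {"control": (84.5, 27.5), "patient": (119.2, 33.5)},
    "qsm_size": {"control": (277.7, 45.9), "patient": (240.6, 56.7)},
    "qsm_size_low": {"control": (102.3, 55.9), "patient": (40.1, 42.1)},
    "smwi_signal": {"control": (171.2, 49.7), "patient": (145.9, 35.7)},
    "smwi_size": {"control": (277.7, 45.9), "patient": (240.6, 56.7)},
    "smwi_size_lowsig": {"control": (46.2, 70.4), "patient": (83.2, 76.6)},
}

DEFAULT_CLINICAL_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"control": (65.6, 6.5), "patient": (65.0, 9.3)},
    "mmse": {"control": (27.3, 2.1), "patient": (25.9, 3.0)},
    "updrs1": {"control": (1.6, 2.9), "patient": (5.6, 5.8)},
    "updrs2": {"control": (0.5, 1.7), "patient": (7.8, 6.2)},
    "updrs3": {"control": (3.4, 4.4), "patient": (29.4, 13.3)},
    "hy": {"control": (0.0, 0.0), "patient": (2.0, 0.5)},
    "ledd": {"patient": (452.9, 280.5)},
}

#: Fraction of males per group.
DEFAULT_MALE_FRACTION = {"control": 52 / 111, "patient": 55 / 80}

#: Marginal family per variable ("normal" unless listed here).
GAMMA_VARIABLES = frozenset({"updrs1", "updrs2", "updrs3", "ledd"})
#: 1 + gamma (a ratio of percentiles cannot fall below 1).
OFFSET_GAMMA_VARIABLES = frozenset({"nm_contrast_range"})
#: cap - gamma (bounded above; the deficit is the skewed quantity).
REVERSED_GAMMA_VARIABLES = frozenset({"mmse"})
MMSE_CAP = 30.0
CONTRAST_OFFSET = 1.0

#: thresholded-size feature -> parent (unthresholded) mask-size feature.
THRESHOLDED_PARENT = {
    "nm_size_high": "nm_size",
    "qsm_size_low": "qsm_size",
    "smwi_size_lowsig": "smwi_size",
}

#: Severity-coupled variables, in factorisation order.
COUPLED_FEATURES = ("nm_contrast_range", "nm_size_high", "qsm_chi_mean",
                    "qsm_size_low")
COUPLED_CLINICAL = ("mmse", "updrs1", "updrs2", "updrs3")
#: Column order of the pooled rank-correlation target grid.
TARGET_CLINICAL = ("age", "mmse", "updrs1", "updrs2", "updrs3")

#: Pooled-cohort Spearman targets (rows COUPLED_FEATURES x TARGET_CLINICAL).
DEFAULT_TARGET_RANK_CORRELATIONS = {
    "nm_contrast_range": {"age": -0.051, "mmse": 0.196, "updrs1": -0.274,
                          "updrs2": -0.466, "updrs3": -0.532},
    "nm_size_high": {"age": -0.220, "mmse": 0.126, "updrs1": -0.173,
                     "updrs2": -0.372, "updrs3": -0.417},
    "qsm_chi_mean": {"age": 0.027, "mmse": -0.273, "updrs1": 0.298,
                     "updrs2": 0.453, "updrs3": 0.443},
    "qsm_size_low": {"age": 0.012, "mmse": 0.272, "updrs1": -0.360,
                     "updrs2": -0.479, "updrs3": -0.445},
}

#: Pooled target for the age / unthresholded-NM-size association.
AGE_NM_SIZE_TARGET = -0.22

#: Latent loading of H&Y on severity (patients; not a printed target).
HY_SEVERITY_LOADING = 0.6

#: Internal seed for the deterministic calibration simulation (independent
#: of any cohort seed).
_CALIBRATION_SEED = 914751
_CALIBRATION_N = 24000


# --------------------------------------------------------------------------
# Marginal transforms (all increasing in the latent score g)
# --------------------------------------------------------------------------

def _gamma_ppf(u, mean: float, sd: float):
    if mean <= 0:
        raise ValueError("gamma marginal requires a positive mean")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return sps.gamma.ppf(u, shape, scale=scale)


def marginal_transform(name: str, g: np.ndarray, mean: float,
                       sd: float) -> np.ndarray:
    """Map standard-normal scores ``g`` to the marginal of ``name``.

    Thresholded sizes are handled separately (fraction x parent); this
    covers the scalar families.  ``sd == 0`` collapses to the constant
    ``mean``.
    """
    g = np.asarray(g, dtype=np.float64)
    if sd == 0:
        return np.full(g.shape, float(mean))
    if name in GAMMA_VARIABLES:
        return _gamma_ppf(ndtr(g), mean, sd)
    if name in OFFSET_GAMMA_VARIABLES:
        return CONTRAST_OFFSET + _gamma_ppf(ndtr(g), mean - CONTRAST_OFFSET, sd)
    if name in REVERSED_GAMMA_VARIABLES:
        out = MMSE_CAP - _gamma_ppf(ndtr(-g), MMSE_CAP - mean, sd)
        return np.clip(out, 0.0, MMSE_CAP)
    return mean + sd * g


def fraction_beta_params(product_mean: float, product_sd: float,
                         parent_mean: float, parent_sd: float
                         ) -> tuple[float, float] | None:
    """Beta(alpha, beta) for the surviving fraction of a thresholded size.

    Chosen so that fraction x parent (independent within group) matches
    the printed (mean, sd) of the thresholded size exactly.  Returns
    ``None`` for a degenerate (constant) fraction.
    """
    if parent_mean <= 0:
        raise ValueError("parent mask size must have a positive mean")
    m = product_mean / parent_mean
    if not 0 <= m <= 1:
        raise ValueError("thresholded size mean exceeds parent size mean")
    if product_sd == 0:
        return None
    e2_parent = parent_mean**2 + parent_sd**2
    e2_frac = (product_mean**2 + product_sd**2) / e2_parent
    var = e2_frac - m * m
    limit = m * (1 - m)
    if var <= 0 or var >= limit:
        warnings.warn("thresholded-size moments infeasible for a beta "
                      "fraction; clamping fraction variance")
        var = float(np.clip(var, 1e-6, 0.999 * limit))
    nu = limit / var - 1.0
    return m * nu, (1 - m) * nu


def fraction_transform(g: np.ndarray, ab: tuple[float, float] | None,
                       mean_fraction: float) -> np.ndarray:
    """Beta-quantile transform of latent scores into [0, 1] fractions."""
    g = np.asarray(g, dtype=np.float64)
    if ab is None:
        return np.full(g.shape, mean_fraction)
    return sps.beta.ppf(ndtr(g), ab[0], ab[1])


# --------------------------------------------------------------------------
# Pooled-correlation algebra (analytic initialisation)
# --------------------------------------------------------------------------

def pooled_sd(marg: dict[str, tuple[float, float]], pi_c: float) -> float:
    """SD of the two-group mixture implied by per-group (mean, sd)."""
    (mc, sc), (mp, sp) = marg["control"], marg["patient"]
    pi_p = 1.0 - pi_c
    var = pi_c * sc**2 + pi_p * sp**2 + pi_c * pi_p * (mc - mp) ** 2
    return float(np.sqrt(var))


def required_latent_corr(target: float,
                         marg_x: dict[str, tuple[float, float]],
                         marg_y: dict[str, tuple[float, float]],
                         pi_c: float) -> float:
    """Within-group latent correlation reproducing a pooled target.

    Solves ``target * sX * sY = rho * S + B`` with ``S`` the group-weighted
    product of within-group SDs and ``B`` the between-group covariance from
    the mean separation.  Raises ``ValueError`` when the target would
    require ``|rho| > 1`` (infeasible dependence structure).
    """
    (mxc, sxc), (mxp, sxp) = marg_x["control"], marg_x["patient"]
    (myc, syc), (myp, syp) = marg_y["control"], marg_y["patient"]
    pi_p = 1.0 - pi_c
    s_within = pi_c * sxc * syc + pi_p * sxp * syp
    if s_within == 0:
        # Zero within-group variance: values are group constants, so no
        # latent coupling can act; any loading is equivalent to zero.
        return 0.0
    b_between = pi_c * pi_p * (mxc - mxp) * (myc - myp)
    rho = (target * pooled_sd(marg_x, pi_c) * pooled_sd(marg_y, pi_c)
           - b_between) / s_within
    if abs(rho) > 1.0:
        raise ValueError(
            f"pooled target {target:+.3f} requires within-group latent "
            f"correlation {rho:+.3f}; dependence structure infeasible")
    return float(rho)


# --------------------------------------------------------------------------
# Shared latent-score assembly (used by both calibration and sampling)
# --------------------------------------------------------------------------

@dataclass
class CopulaCalibration:
    """Fitted latent loadings of the one-factor severity copula."""

    feature_loadings: dict[str, float]  # a_j on severity, per coupled feature
    clinical_loadings: dict[str, float]  # b_k on severity
    age_nm_size_high: float  # age-factor loading in the NM-high fraction
    age_nm_size: float  # age-factor loading in unthresholded NM size
    required_matrix: np.ndarray  # analytic-init latent targets (diagnostics)
    achieved: dict = field(default_factory=dict)  # simulated pooled Spearman
    #: (feature, group) -> (beta (alpha, beta) or None, mean fraction);
    #: moment-corrected where fraction and parent share a latent factor.
    fraction_params: dict = field(default_factory=dict)


def assemble_latent_scores(z: np.ndarray, eta: np.ndarray,
                           eps: dict[str, np.ndarray],
                           cop: CopulaCalibration,
                           gradient_strength: float = 1.0
                           ) -> dict[str, np.ndarray]:
    """Latent Gaussian scores for every coupled variable.

    ``z``: shared severity; ``eta``: age factor; ``eps``: one independent
    standard normal per variable.  For thresholded sizes the score drives
    the surviving *fraction*.  ``gradient_strength`` jointly scales the
    imaging-side severity loadings (1 = calibrated coupling).
    """
    scores: dict[str, np.ndarray] = {}
    for name in COUPLED_FEATURES:
        a = cop.feature_loadings[name] * gradient_strength
        extra = cop.age_nm_size_high if name == "nm_size_high" else 0.0
        resid = 1.0 - a * a - extra * extra
        if resid < 0:  # oversized gradient_strength: renormalise
            a = np.sign(a) * np.sqrt(max(0.0, 1.0 - extra * extra)) * 0.999
            resid = 1.0 - a * a - extra * extra
        scores[name] = a * z + extra * eta + np.sqrt(resid) * eps[name]
    for name in COUPLED_CLINICAL:
        b = cop.clinical_loadings[name]
        scores[name] = b * z + np.sqrt(1.0 - b * b) * eps[name]
    scores["age"] = eta
    c2 = cop.age_nm_size
    scores["nm_size"] = c2 * eta + np.sqrt(1.0 - c2 * c2) * eps["nm_size"]
    return scores


# --------------------------------------------------------------------------
# Simulation-refined copula fit
# --------------------------------------------------------------------------

_SIM_VARS = ("nm_contrast_range", "nm_size_high", "qsm_chi_mean",
             "qsm_size_low", "mmse", "updrs1", "updrs2", "updrs3",
             "nm_size", "qsm_size")


class _TransformTable:
    """Fast interpolated marginal transforms for the calibration simulation."""

    def __init__(self, feature_marginals, clinical_marginals):
        self.grid = np.linspace(-5.5, 5.5, 4097)
        u = ndtr(self.grid)
        self.tables: dict[tuple[str, str], np.ndarray] = {}
        self.frac_ab: dict[tuple[str, str], tuple | None] = {}
        self.frac_mean: dict[tuple[str, str], float] = {}
        for g in ("control", "patient"):
            for name in _SIM_VARS:
                marg = feature_marginals.get(name) or clinical_marginals[name]
                mean, sd = marg[g]
                if name in THRESHOLDED_PARENT:
                    pmean, psd = feature_marginals[THRESHOLDED_PARENT[name]][g]
                    ab = fraction_beta_params(mean, sd, pmean, psd)
                    self.frac_ab[(name, g)] = ab
                    self.frac_mean[(name, g)] = mean / pmean
                    if ab is None:
                        self.tables[(name, g)] = np.full_like(u, mean / pmean)
                    else:
                        self.tables[(name, g)] = sps.beta.ppf(u, ab[0], ab[1])
                else:
                    self.tables[(name, g)] = marginal_transform(
                        name, self.grid, mean, sd)

    def apply(self, name: str, group: str, g: np.ndarray) -> np.ndarray:
        return np.interp(g, self.grid, self.tables[(name, group)])


def _simulated_pooled_spearman(cop: CopulaCalibration, tt: _TransformTable,
                               draws: dict, is_pat: np.ndarray
                               ) -> dict[str, dict[str, float]]:
    """Realised pooled Spearman grid for a candidate calibration."""
    z, eta, eps = draws["z"], draws["eta"], draws["eps"]
    scores = assemble_latent_scores(z, eta, eps, cop)
    scores["qsm_size"] = eps["qsm_size"]
    values: dict[str, np.ndarray] = {}
    for name in _SIM_VARS:
        out = np.empty(len(z))
        for grp, sel in (("control", ~is_pat), ("patient", is_pat)):
            out[sel] = tt.apply(name, grp, scores[name][sel])
        values[name] = out
    for name, parent in (("nm_size_high", "nm_size"),
                         ("qsm_size_low", "qsm_size")):
        values[name] = values[name] * values[parent]
    values["age"] = scores["age"]  # rank-equivalent to any normal marginal
    ranks = {k: sps.rankdata(v) for k, v in values.items()
             if k in COUPLED_FEATURES or k in TARGET_CLINICAL}
    out: dict[str, dict[str, float]] = {}
    for f in COUPLED_FEATURES:
        out[f] = {}
        for c in TARGET_CLINICAL:
            out[f][c] = float(np.corrcoef(ranks[f], ranks[c])[0, 1])
    return out


def fit_copula(feature_marginals: dict, clinical_marginals: dict,
               targets: dict, n_controls: int, n_patients: int,
               refine: bool = True) -> CopulaCalibration:
    """Calibrate the one-factor copula to pooled rank-correlation targets.

    Analytic initialisation (mixture moment algebra + rank-1 SVD of the
    required within-group latent matrix), then a deterministic
    simulation-based least-squares refinement of the severity loadings and
    the age coupling against the pooled Spearman targets.
    """
    for row in targets.values():
        for t in row.values():
            if not -1.0 <= t <= 1.0:
                raise ValueError("correlation targets must lie in [-1, 1]")
    pi_c = n_controls / (n_controls + n_patients)
    req = np.empty((len(COUPLED_FEATURES), len(COUPLED_CLINICAL)))
    for i, f in enumerate(COUPLED_FEATURES):
        for j, c in enumerate(COUPLED_CLINICAL):
            req[i, j] = required_latent_corr(
                targets[f][c], feature_marginals[f], clinical_marginals[c],
                pi_c)
    u, s, vt = np.linalg.svd(req)
    a0 = u[:, 0] * np.sqrt(s[0])
    b0 = vt[0, :] * np.sqrt(s[0])
    if b0[COUPLED_CLINICAL.index("updrs3")] < 0:  # severity raises UPDRS-III
        a0, b0 = -a0, -b0
    cap = 0.97
    # Sign pattern from the targets (anchored on UPDRS-III): keeps the
    # fitted couplings scientifically oriented (e.g. severity never raises
    # NM thresholded size), which the monotonicity contract relies on.
    sign_a = np.array([np.sign(targets[f].get("updrs3", 0.0))
                       for f in COUPLED_FEATURES])
    sign_b = np.array([np.sign(sum(targets[f].get(c, 0.0) * sign_a[i]
                                   for i, f in enumerate(COUPLED_FEATURES)))
                       for c in COUPLED_CLINICAL])
    lo_a = np.where(sign_a > 0, 0.0, -cap)
    hi_a = np.where(sign_a < 0, 0.0, cap)
    lo_b = np.where(sign_b > 0, 0.0, -cap)
    hi_b = np.where(sign_b < 0, 0.0, cap)
    a0 = np.clip(a0, lo_a + 1e-6, hi_a - 1e-6)
    b0 = np.clip(b0, lo_b + 1e-6, hi_b - 1e-6)
    age_high0 = required_latent_corr(
        targets["nm_size_high"].get("age", 0.0),
        feature_marginals["nm_size_high"], clinical_marginals["age"], pi_c)
    age_size = required_latent_corr(
        AGE_NM_SIZE_TARGET, feature_marginals["nm_size"],
        clinical_marginals["age"], pi_c)

    def build(params: np.ndarray) -> CopulaCalibration:
        a = params[:4]
        b = params[4:8]
        age_high = params[8]
        i_high = COUPLED_FEATURES.index("nm_size_high")
        if a[i_high] ** 2 + age_high**2 > 0.995:
            age_high = np.sign(age_high) * np.sqrt(
                max(0.0, 0.995 - a[i_high] ** 2))
        return CopulaCalibration(
            feature_loadings=dict(zip(COUPLED_FEATURES, map(float, a))),
            clinical_loadings=dict(zip(COUPLED_CLINICAL, map(float, b))),
            age_nm_size_high=float(age_high),
            age_nm_size=float(age_size),
            required_matrix=req)

    sign_age = np.sign(targets["nm_size_high"].get("age", 0.0))
    lo = np.concatenate([lo_a, lo_b, [0.0 if sign_age > 0 else -cap]])
    hi = np.concatenate([hi_a, hi_b, [0.0 if sign_age < 0 else cap]])
    x0 = np.concatenate([a0, b0, [np.clip(age_high0, lo[-1] + 1e-6,
                                          hi[-1] - 1e-6)]])
    cal = build(x0)
    degenerate = any(
        (feature_marginals.get(v) or clinical_marginals[v])[g][1] == 0
        for v in _SIM_VARS for g in ("control", "patient"))
    if not refine or degenerate:
        _attach_fraction_params(cal, feature_marginals, pi_c)
        return cal

    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_N
    n_pat = int(round(n * (1 - pi_c)))
    is_pat = np.zeros(n, dtype=bool)
    is_pat[n - n_pat:] = True
    draws = {
        "z": rng.standard_normal(n),
        "eta": rng.standard_normal(n),
        "eps": {v: rng.standard_normal(n) for v in _SIM_VARS},
    }
    tt = _TransformTable(feature_marginals, clinical_marginals)
    tmat = np.array([[targets[f].get(c, 0.0) for c in TARGET_CLINICAL]
                     for f in COUPLED_FEATURES])

    def residuals(params: np.ndarray) -> np.ndarray:
        got = _simulated_pooled_spearman(build(params), tt, draws, is_pat)
        gmat = np.array([[got[f][c] for c in TARGET_CLINICAL]
                         for f in COUPLED_FEATURES])
        return (gmat - tmat).ravel()

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 diff_step=0.03, xtol=1e-4, ftol=1e-6,
                                 max_nfev=400)
    cal = build(sol.x)
    cal.achieved = _simulated_pooled_spearman(cal, tt, draws, is_pat)
    _attach_fraction_params(cal, feature_marginals, pi_c)
    return cal


def _attach_fraction_params(cal: CopulaCalibration, feature_marginals: dict,
                            pi_c: float) -> None:
    """Solve the beta fraction parameters for each thresholded size.

    For ``nm_size_high`` the fraction and its parent size share the age
    factor, so the naive independent-moment solution inflates the product
    SD; a deterministic fixed-point correction against a large simulated
    draw restores the target product moments.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    n = 60000
    n_pat = int(round(n * (1 - pi_c)))
    z = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    eps = {v: rng.standard_normal(n) for v in ("nm_contrast_range",
                                               "nm_size_high", "qsm_chi_mean",
                                               "qsm_size_low", "mmse",
                                               "updrs1", "updrs2", "updrs3",
                                               "nm_size")}
    scores = assemble_latent_scores(z, eta, eps, cal)
    is_pat = np.zeros(n, dtype=bool)
    is_pat[n - n_pat:] = True
    for name, parent in THRESHOLDED_PARENT.items():
        for grp, sel in (("control", ~is_pat), ("patient", is_pat)):
            mean, sd = feature_marginals[name][grp]
            pmean, psd = feature_marginals[parent][grp]
            ab = fraction_beta_params(mean, sd, pmean, psd)
            if name == "nm_size_high" and ab is not None and sd > 0:
                g_frac = scores[name][sel]
                parent_vals = np.clip(
                    marginal_transform(parent, scores[parent][sel],
                                       pmean, psd), 1.0, None)
                mt, st = mean, sd
                for _ in range(4):
                    frac = fraction_transform(g_frac, ab, mt / pmean)
                    prod = frac * parent_vals
                    got_m, got_s = prod.mean(), prod.std(ddof=1)
                    mt *= mean / got_m
                    st *= sd / got_s
                    ab = fraction_beta_params(mt, st, pmean, psd)
            cal.fraction_params[(name, grp)] = (ab, (mean if sd > 0 else mean)
                                                / pmean)
    # Degenerate-sd means use the uncorrected mean fraction directly.
    for name, parent in THRESHOLDED_PARENT.items():
        for grp in ("control", "patient"):
            mean, _sd = feature_marginals[name][grp]
            pmean, _psd = feature_marginals[parent][grp]
            ab, _ = cal.fraction_params[(name, grp)]
            cal.fraction_params[(name, grp)] = (ab, mean / pmean)


# Cache: refitting is deterministic but costs a few seconds.
_FIT_CACHE: dict[str, CopulaCalibration] = {}


def fit_copula_cached(feature_marginals: dict, clinical_marginals: dict,
                      targets: dict, n_controls: int,
                      n_patients: int) -> CopulaCalibration:
    """Memoised ``fit_copula`` keyed on the (proportional) study conditions.

    The fitted loadings depend on the group mix only through the control
    fraction, so cohorts that differ only in total size share a fit.
    """
    pi_c = n_controls / (n_controls + n_patients)
    key = repr((sorted(feature_marginals.items()),
                sorted(clinical_marginals.items()),
                sorted((k, sorted(v.items())) for k, v in targets.items()),
                round(pi_c, 6)))
    if key not in _FIT_CACHE:
        _FIT_CACHE[key] = fit_copula(feature_marginals, clinical_marginals,
                                     targets, n_controls, n_patients)
    return _FIT_CACHE[key]
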