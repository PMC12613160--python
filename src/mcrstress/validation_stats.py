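"""Three-part validation battery for the MCR index.

Face validity: ordinary least squares of the per-cell performance scores on
the ordinal motor and cognitive difficulty levels, a healthy-group indicator,
and difficulty x group interactions.  Known-groups validity: the area of
overlap between the two groups' score densities per difficulty cell, plus
discrimination of diagnosis by the index (AUC with DeLong 95% CI) and paired
one-sided DeLong tests of the index against each single proxy.  Construct
validity: Spearman correlations of the index with clinical proxies and
brain-volume surrogates, Benjamini-Hochberg adjusted within each family,
optionally age-adjusted through rank partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ComputationError, DomainError

# ---------------------------------------------------------------------------
# face validity


@dataclass(frozen=True)
class RegressionResult:
    """OLS estimates for the six-term face-validity design."""

    params: dict
    bse: dict
    tvalues: dict
    pvalues: dict
    nobs: int
    df_resid: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "t": self.tvalues,
            "p": self.pvalues,
        })


FACE_TERMS = ("intercept", "motor", "cognitive", "healthy",
              "motor:healthy", "cognitive:healthy")


def face_validity_ols(plane_scores_long: pd.DataFrame,
                      group_labels: pd.Series | dict | None = None) -> RegressionResult:
    """Fit score ~ motor + cognitive + healthy + motor:healthy + cognitive:healthy.

    ``plane_scores_long`` needs columns subject_id, motor_level,
    cognitive_level, score (and group, unless ``group_labels`` maps
    subject_id -> group).  The healthy indicator is 1 for the healthy group,
    so its main effect is the expected score advantage of healthy subjects at
    every challenge level.
    """
    df = plane_scores_long.copy()
    if "group" not in df.columns:
        if group_labels is None:
            raise DomainError("provide a 'group' column or group_labels")
        mapping = dict(group_labels) if not isinstance(group_labels, pd.Series) \
            else group_labels.to_dict()
        df["group"] = df["subject_id"].map(mapping)
    if df["group"].isna().any():
        raise DomainError("some subjects have no group label")
    for group in ("healthy", "diagnosed"):
        if df.loc[df["group"] == group, "subject_id"].nunique() < 2:
            raise DomainError(f"need at least two subjects in group {group!r}")

    healthy = (df["group"] == "healthy").astype(float).to_numpy()
    motor = df["motor_level"].to_numpy(dtype=float)
    cognitive = df["cognitive_level"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones_like(motor), motor, cognitive, healthy,
        motor * healthy, cognitive * healthy,
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ComputationError("rank-deficient face-validity design matrix")
    fit = sm.OLS(df["score"].to_numpy(dtype=float), X).fit()
    return RegressionResult(
        params=dict(zip(FACE_TERMS, fit.params)),
        bse=dict(zip(FACE_TERMS, fit.bse)),
        tvalues=dict(zip(FACE_TERMS, fit.tvalues)),
        pvalues=dict(zip(FACE_TERMS, fit.pvalues)),
        nobs=int(fit.nobs),
        df_resid=float(fit.df_resid),
    )


# ---------------------------------------------------------------------------
# known-groups validity: density overlap


def kde_overlap(scores_a, scores_b, n_grid: int = 512) -> float:
    """Area of overlap between two Gaussian kernel density estimates.

    Silverman-rule bandwidths; densities are evaluated on a common grid
    spanning both samples by three bandwidths and the overlap is the
    trapezoidal integral of their pointwise minimum, clipped to [0, 1].
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    for name, sample in (("scores_a", a), ("scores_b", b)):
        if sample.size < 2 or not np.isfinite(sample).all():
            raise ComputationError(f"{name}: need >= 2 finite values")
        if np.std(sample, ddof=1) == 0:
            raise ComputationError(f"{name}: zero variance, density undefined")
    kde_a = sps.gaussian_kde(a, bw_method="silverman")
    kde_b = sps.gaussian_kde(b, bw_method="silverman")
    h_a = kde_a.factor * np.std(a, ddof=1)
    h_b = kde_b.factor * np.std(b, ddof=1)
    lo = min(a.min() - 3 * h_a, b.min() - 3 * h_b)
    hi = max(a.max() + 3 * h_a, b.max() + 3 * h_b)
    grid = np.linspace(lo, hi, n_grid)
    overlap = np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid)
    return float(np.clip(overlap, 0.0, 1.0))


def overlap_by_cell(plane_scores_long: pd.DataFrame) -> pd.DataFrame:
    """Between-group density overlap of plane scores for every difficulty cell."""
    rows = []
    for (m, c), cell in plane_scores_long.groupby(["motor_level", "cognitive_level"]):
        healthy = cell.loc[cell["group"] == "healthy", "score"]
        diagnosed = cell.loc[cell["group"] == "diagnosed", "score"]
        rows.append({
            "motor_level": int(m),
            "cognitive_level": int(c),
            "overlap": kde_overlap(healthy, diagnosed),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# known-groups validity: ROC / DeLong


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    z: float
    p_one_sided: float


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ComputationError("both classes must be present")
    return y


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple:
    """AUC and DeLong structural components via midranks (ties count 1/2)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = sps.rankdata(combined)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc_delong_ci(scores, labels, alpha: float = 0.05) -> ROCResult:
    """AUC (Mann-Whitney with tie correction) and DeLong 95% CI.

    ``labels`` marks the positive class; higher scores are taken to indicate
    positives (AUC below 0.5 simply reports an anti-discriminating score).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise DomainError("scores and labels must have the same length")
    auc, v10, v01 = _delong_components(s[y], s[~y])
    m, n = int(y.sum()), int((~y).sum())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    return ROCResult(
        auc=auc,
        ci_low=float(np.clip(auc - zcrit * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + zcrit * se, 0.0, 1.0)),
        n_pos=m,
        n_neg=n,
    )


def delong_one_sided_test(scores_a, scores_b, labels) -> DeLongComparison:
    """Paired one-sided DeLong test of H1: AUC(a) > AUC(b).

    Both score vectors must be measured on the same subjects; the paired
    covariance of the two AUCs enters the variance of their difference.
    Identical classifiers give z = 0 and p = 0.5 by convention.
    """
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise DomainError("scores_a, scores_b and labels must share a length")
    auc_a, v10_a, v01_a = _delong_components(a[y], a[~y])
    auc_b, v10_b, v01_b = _delong_components(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            z, p = 0.0, 0.5
        else:
            z = np.inf if diff > 0 else -np.inf
            p = 0.0 if diff > 0 else 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(sps.norm.sf(z))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p_one_sided=float(p))


def fit_univariate_logistic(scores, labels) -> float:
    """Slope of a univariate logistic model of the labels on the scores.

    The AUC itself is invariant to this monotone link; the fit is retained to
    report the direction of discrimination.  Falls back to the sign of the
    group mean difference under perfect separation.
    """
    y = _check_labels(labels).astype(float)
    s = np.asarray(scores, dtype=float)
    X = sm.add_constant((s - s.mean()) / (s.std() or 1.0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(fit.params[1])
        if np.isfinite(slope):
            return slope
    except Exception:
        pass
    return float(np.sign(s[y == 1].mean() - s[y == 0].mean()))


# ---------------------------------------------------------------------------
# construct validity


def spearman(x, y) -> tuple:
    """Spearman rank correlation with midranks for ties; p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have the same length")
    if x.size < 3:
        raise DomainError("need at least three observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ComputationError("constant input vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("p_values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def partial_spearman_age(x, y, age) -> tuple:
    """Spearman correlation of x and y with the age ranks partialled out.

    All three variables are rank-transformed (midranks); the x and y ranks
    are residualized on the age ranks by least squares and the residuals are
    correlated.  The p-value uses a t approximation with n - 3 degrees of
    freedom.  A constant age vector leaves nothing to adjust for: the plain
    Spearman correlation is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (x.size == y.size == age.size):
        raise DomainError("x, y and age must have the same length")
    if x.size < 4:
        raise DomainError("need at least four observations")
    if np.std(age) == 0:
        warnings.warn("age is constant; returning the unadjusted Spearman "
                      "correlation", stacklevel=2)
        return spearman(x, y)
    rx, ry, ra = (sps.rankdata(v) for v in (x, y, age))
    design = np.column_stack([np.ones_like(ra), ra])
    resid_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    resid_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((resid_x ** 2).sum() * (resid_y ** 2).sum())
    if denom == 0:
        raise ComputationError("residual variance is zero after age adjustment")
    rho = float(np.clip((resid_x * resid_y).sum() / denom, -1.0, 1.0))
    df = x.size - 3
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2 * sps.t.sf(abs(t), df))
    return rho, p


#: Orientation of clinical proxies: sign making higher-is-better.
PROXY_ORIENTATION = {
    "age": -1,
    "education_years": +1,
    "MoCA": +1,
    "TMT_A_s": -1,
    "TMT_B_s": -1,
    "stroop_word": +1,
    "stroop_colour": +1,
    "stroop_interference": +1,
    "preferred_speed_kmh": +1,
}

DEFAULT_CLINICAL_PROXIES = ("age", "education_years", "MoCA", "TMT_A_s",
                            "TMT_B_s", "stroop_word", "stroop_colour",
                            "stroop_interference", "preferred_speed_kmh")


def construct_validity_report(mcr_results: pd.DataFrame, subjects: pd.DataFrame,
                              mri: pd.DataFrame | None = None,
                              clinical_proxies=DEFAULT_CLINICAL_PROXIES,
                              age_adjust_mri: bool = False) -> pd.DataFrame:
    """Spearman correlation table of the MCR index against proxies and volumes.

    Proxies are oriented higher-is-better before correlating.  BH adjustment
    is applied separately within the clinical family and the MRI family.
    Columns: family, variable, rho, p, p_adj (plus rho_age_adj, p_age_adj,
    p_age_adj_bh for the MRI family when requested).
    """
    merged = mcr_results.merge(subjects, on="subject_id", how="left", validate="1:1")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject_id"].tolist()
        raise DomainError(f"subjects missing from the subject table: {missing}")
    rows = []
    for proxy in clinical_proxies:
        if proxy not in merged.columns:
            raise DomainError(f"proxy column {proxy!r} missing from subject table")
        sign = PROXY_ORIENTATION.get(proxy, +1)
        rho, p = spearman(merged["mcr_index"], sign * merged[proxy])
        rows.append({"family": "clinical", "variable": proxy, "rho": rho, "p": p})
    clinical = pd.DataFrame(rows)
    clinical["p_adj"] = bh_adjust(clinical["p"].to_numpy())

    if mri is None:
        return clinical

    merged_mri = mcr_results.merge(mri, on="subject_id", how="inner", validate="1:1")
    merged_mri = merged_mri.merge(subjects[["subject_id", "age"]], on="subject_id")
    regions = [c for c in mri.columns if c != "subject_id"]
    rows = []
    for region in regions:
        rho, p = spearman(merged_mri["mcr_index"], merged_mri[region])
        row = {"family": "mri", "variable": region, "rho": rho, "p": p}
        if age_adjust_mri:
            rho_adj, p_adj_age = partial_spearman_age(
                merged_mri["mcr_index"], merged_mri[region], merged_mri["age"])
            row["rho_age_adj"] = rho_adj
            row["p_age_adj"] = p_adj_age
        rows.append(row)
    mri_table = pd.DataFrame(rows)
    mri_table["p_adj"] = bh_adjust(mri_table["p"].to_numpy())
    if age_adjust_mri:
        mri_table["p_age_adj_bh"] = bh_adjust(mri_table["p_age_adj"].to_numpy())
    return pd.concat([clinical, mri_table], ignore_index=True)


# ---------------------------------------------------------------------------
# full battery


@dataclass
class ValidationReport:
    """All validation tables for one analysed cohort."""

    regression: RegressionResult
    overlap: pd.DataFrame
    roc: dict
    delong: pd.DataFrame
    correlations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "face_validity": self.regression.to_frame().to_dict(orient="index"),
            "overlap_by_cell": self.overlap.to_dict(orient="records"),
            "roc": {name: vars(res) for name, res in self.roc.items()},
            "delong_vs_index": self.delong.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }


def validation_battery(plane_scores_long: pd.DataFrame, mcr_results: pd.DataFrame,
                       subjects: pd.DataFrame, test_ids,
                       mri: pd.DataFrame | None = None,
                       clinical_proxies=DEFAULT_CLINICAL_PROXIES,
                       age_adjust_mri: bool = False) -> ValidationReport:
    """Run the full battery.

    Face validity and per-cell overlap use the whole cohort's plane scores;
    ROC/DeLong discrimination uses the held-out test subjects (positives =
    healthy); correlations use the whole cohort.
    """
    scores = plane_scores_long.merge(subjects[["subject_id", "group"]], on="subject_id")
    regression = face_validity_ols(scores)
    overlap = overlap_by_cell(scores)

    test = mcr_results[mcr_results["subject_id"].isin(set(test_ids))].merge(
        subjects, on="subject_id")
    labels = (test["group"] == "healthy").to_numpy()
    roc = {"mcr_index": roc_auc_delong_ci(test["mcr_index"].to_numpy(), labels)}
    delong_rows = []
    for proxy in clinical_proxies:
        sign = PROXY_ORIENTATION.get(proxy, +1)
        proxy_scores = sign * test[proxy].to_numpy(dtype=float)
        roc[proxy] = roc_auc_delong_ci(proxy_scores, labels)
        cmp = delong_one_sided_test(test["mcr_index"].to_numpy(), proxy_scores, labels)
        delong_rows.append({
            "proxy": proxy,
            "auc_index": cmp.auc_a,
            "auc_proxy": cmp.auc_b,
            "z": cmp.z,
            "p_one_sided": cmp.p_one_sided,
        })
    correlations = construct_validity_report(
        mcr_results, subjects, mri=mri, clinical_proxies=clinical_proxies,
        age_adjust_mri=age_adjust_mri)
    return ValidationReport(
        regression=regression,
        overlap=overlap,
        roc=roc,
        delong=pd.DataFrame(delong_rows),
        correlations=correlations,
        meta={"n_test": int(len(test)), "n_total": int(len(mcr_results))},
    )
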