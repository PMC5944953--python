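"""Group comparisons and predictive-validity statistics.

Nonparametric group contrasts (Mann-Whitney U with a Lilliefors-corrected
Kolmogorov-Smirnov normality screen and Bonferroni-adjusted alpha within each
variable family), ROC analysis of single predictors and of unregularized
logistic-regression combinations, with cut-offs at the maximum of Youden's
J = specificity + sensitivity - 1.

The positive class is the faller group under comparison; predictor direction
is auto-oriented so the reported AUC is >= 0.5 (higher short-term instability
and lower Tinetti scores both point toward fallers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.diagnostic import lilliefors
import statsmodels.api as sm


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    u_statistic: float
    p_value: float
    medians: dict[str, float]
    quartiles: dict[str, tuple[float, float]]
    significant_adjusted: bool
    adjusted_alpha: float
    n: tuple[int, int] = (0, 0)


@dataclass
class RocResult:
    predictors: tuple[str, ...]
    auc: float
    cutoff: float
    specificity: float
    sensitivity: float
    youden_j: float
    direction: str  # higher-is-positive | lower-is-positive | probability
    coefficients: dict[str, float] | None = None
    separation_flag: bool = False
    n_pos: int = 0
    n_neg: int = 0


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Family-wise adjusted significance level alpha / k."""
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise StatsError(f"k must be >= 1, got {k}")
    return alpha / k


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def mann_whitney(
    a,
    b,
    variable: str = "",
    groups: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
    k: int = 1,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact enumeration when n1 + n2 <= 20 and there are no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size == 0 or b.size == 0:
        raise StatsError(f"both samples must be non-empty for '{variable}'")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn(f"'{variable}': all values identical across both samples; p = 1",
                      stacklevel=2)
        u, p = a.size * b.size / 2.0, 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
        res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                  use_continuity=True)
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    adj = bonferroni_alpha(alpha, k)
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        variable=variable,
        groups=groups,
        u_statistic=u,
        p_value=p,
        medians={groups[0]: float(qa[1]), groups[1]: float(qb[1])},
        quartiles={groups[0]: (float(qa[0]), float(qa[2])),
                   groups[1]: (float(qb[0]), float(qb[2]))},
        significant_adjusted=bool(p < adj),
        adjusted_alpha=adj,
        n=(int(a.size), int(b.size)),
    )


def ks_normality(x) -> float:
    """Kolmogorov-Smirnov normality p-value with estimated mean/SD (Lilliefors)."""
    x = _clean(x)
    if x.size < 5:
        raise StatsError(f"need n >= 5 for the normality screen, got {x.size}")
    if np.std(x) < 1e-14:
        raise StatsError("zero variance sample")
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def _youden_cutoff(labels: np.ndarray, score: np.ndarray) -> tuple[float, float, float, float]:
    """Cut-off maximizing J; ties resolve to higher specificity, then smaller J-index threshold."""
    fpr, tpr, thr = roc_curve(labels, score, drop_intermediate=False)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[np.argsort(fpr[best], kind="stable")]  # higher specificity first
    i = int(best[0])
    return float(thr[i]), float(1.0 - fpr[i]), float(tpr[i]), float(j[i])


def roc_single(scores, labels, direction: str = "auto",
               predictor: str = "score") -> RocResult:
    """ROC of one predictor; trapezoidal AUC over all empirical thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    if np.unique(labels).size < 2:
        raise StatsError("both classes must be present for ROC analysis")
    auc_hi = roc_auc_score(labels, scores)
    if direction == "auto":
        direction = "higher-is-positive" if auc_hi >= 0.5 else "lower-is-positive"
    if direction == "higher-is-positive":
        oriented = scores
        auc = float(auc_hi)
    elif direction == "lower-is-positive":
        oriented = -scores
        auc = float(1.0 - auc_hi)
    else:
        raise StatsError(f"unknown direction '{direction}'")
    cutoff, spec, sens, j = _youden_cutoff(labels, oriented)
    if direction == "lower-is-positive":
        cutoff = -cutoff
    return RocResult(
        predictors=(predictor,),
        auc=auc,
        cutoff=cutoff,
        specificity=spec,
        sensitivity=sens,
        youden_j=j,
        direction=direction,
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
    )


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    Xc = X - X.mean(axis=0)
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = Xc[:, [j]]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        if norm > tol * max(1.0, np.linalg.norm(Xc[:, j])):
            keep.append(j)
            basis = np.hstack([basis, col / norm])
    return keep


def roc_combined(features, labels, feature_names=None) -> RocResult:
    """ROC of the unregularized logistic combination of >= 2 predictors.

    The maximum-likelihood fit (intercept included) yields per-subject
    predicted probabilities, scored by the same trapezoidal ROC.  Complete
    separation is flagged and the ROC computed on the separating score.
    """
    X = np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame) and feature_names is None:
        feature_names = list(features.columns)
    if X.ndim != 2 or X.shape[1] < 2:
        raise StatsError("combined ROC needs >= 2 feature columns")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    labels = np.asarray(labels, dtype=int)
    mask = np.isfinite(X).all(axis=1)
    X, labels = X[mask], labels[mask]
    if np.unique(labels).size < 2:
        raise StatsError("both classes must be present for ROC analysis")
    keep = _independent_columns(X)
    Xk = X[:, keep]
    separated = False
    coefs = np.zeros(X.shape[1])
    intercept = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(labels, sm.add_constant(Xk, has_constant="add"))
            fit = model.fit(disp=0, method="newton", maxiter=200)
        params = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4 or not fit.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("degenerate logistic fit")
        intercept = float(params[0])
        for j, c in zip(keep, params[1:]):
            coefs[j] = float(c)
        score = intercept + X @ coefs
    except (np.linalg.LinAlgError, sstats.FitError, Exception) as exc:  # noqa: BLE001
        if isinstance(exc, StatsError):
            raise
        separated = True
        from sklearn.linear_model import LogisticRegression
        mu, sd = Xk.mean(axis=0), np.where(Xk.std(axis=0) > 0, Xk.std(axis=0), 1.0)
        lr = LogisticRegression(C=1e8, max_iter=5000)
        lr.fit((Xk - mu) / sd, labels)
        for j, c in zip(keep, lr.coef_[0] / sd):
            coefs[j] = float(c)
        intercept = float(lr.intercept_[0] - np.sum(lr.coef_[0] * mu / sd))
        score = intercept + X @ coefs
    prob = 1.0 / (1.0 + np.exp(-np.clip(score, -700, 700)))
    auc = float(roc_auc_score(labels, prob))
    cutoff, spec, sens, j = _youden_cutoff(labels, prob)
    return RocResult(
        predictors=tuple(feature_names),
        auc=auc,
        cutoff=cutoff,
        specificity=spec,
        sensitivity=sens,
        youden_j=j,
        direction="probability",
        coefficients={"intercept": intercept,
                      **{name: float(c) for name, c in zip(feature_names, coefs)}},
        separation_flag=separated,
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
    )


# ---------------------------------------------------------------------------
# cohort-level report

DEMOGRAPHIC_VARS = ("age", "height", "weight", "bmi", "baseline_falls")
CLINICAL_VARS = ("tinetti_balance", "tinetti_gait", "tinetti_total")
GAIT_VARS = ("gait_speed", "stride_frequency")
DEFAULT_PREDICTORS = ("tinetti_balance", "tinetti_total", "stle_trunk_ml")
GROUP_PAIRS = (("N", "F1"), ("N", "F2+"), ("F1", "F2+"))


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "groups": list(c.groups),
        "U": c.u_statistic,
        "p": c.p_value,
        "medians": c.medians,
        "quartiles": {k: list(v) for k, v in c.quartiles.items()},
        "significant_adjusted": c.significant_adjusted,
        "adjusted_alpha": c.adjusted_alpha,
        "n": list(c.n),
    }


def _roc_dict(r: RocResult) -> dict:
    return {
        "predictors": list(r.predictors),
        "auc": r.auc,
        "cutoff": r.cutoff,
        "specificity": r.specificity,
        "sensitivity": r.sensitivity,
        "youden_j": r.youden_j,
        "direction": r.direction,
        "coefficients": r.coefficients,
        "separation_flag": r.separation_flag,
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
    }


def reproduce_tables(
    cohort,
    compare: tuple[str, str] = ("N", "F2+"),
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    alpha: float = 0.05,
    family_k: int = 3,
) -> dict:
    """Demographics, clinical medians/quartiles and ROC rows for a cohort.

    Produces the three standard report blocks: group demographics with
    pairwise Mann-Whitney p-values, clinical/gait medians and quartiles with
    Bonferroni-adjusted significance, and single / two- / three-variable ROC
    rows for the fall-prediction comparison (positive class = the faller
    group).  Missing predictors leave explicit gaps rather than failing.
    """
    df = cohort.data
    report: dict = {"warnings": [], "group_sizes": cohort.group_sizes}
    for g, n in cohort.group_sizes.items():
        if n == 0:
            report["warnings"].append(f"group {g} is empty")
        elif n < 10:
            report["warnings"].append(f"group {g} has only {n} subject(s)")

    def pairwise(var: str, k: int) -> dict:
        out = {}
        for ga, gb in GROUP_PAIRS:
            a = df.loc[df["group"] == ga, var] if var in df else pd.Series(dtype=float)
            b = df.loc[df["group"] == gb, var] if var in df else pd.Series(dtype=float)
            if _clean(a).size == 0 or _clean(b).size == 0:
                out[f"{ga} vs {gb}"] = None
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[f"{ga} vs {gb}"] = _comparison_dict(
                    mann_whitney(a, b, variable=var, groups=(ga, gb), alpha=alpha, k=k)
                )
        return out

    def summaries(var: str, stat: str) -> dict:
        out = {}
        for g in ("N", "F1", "F2+"):
            v = _clean(df.loc[df["group"] == g, var]) if var in df else np.array([])
            if v.size == 0:
                out[g] = None
            elif stat == "mean_sd":
                out[g] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0}
            else:
                q = np.percentile(v, [25, 50, 75])
                out[g] = {"median": float(q[1]), "lq": float(q[0]), "uq": float(q[2])}
        return out

    report["demographics"] = {
        var: {"summary": summaries(var, "mean_sd"), "comparisons": pairwise(var, 1)}
        for var in DEMOGRAPHIC_VARS
    }
    report["clinical"] = {
        var: {"summary": summaries(var, "quartiles"), "comparisons": pairwise(var, family_k)}
        for var in CLINICAL_VARS
    }
    report["gait"] = {
        var: {"summary": summaries(var, "quartiles"), "comparisons": pairwise(var, 1)}
        for var in GAIT_VARS
    }

    # ROC block: positive class = the faller group of the comparison
    neg, pos = compare
    sub = df[df["group"].isin(compare)]
    labels = (sub["group"] == pos).astype(int).to_numpy()
    roc: dict = {"comparison": f"{neg} vs {pos}", "single": {}, "pairs": {}, "triple": None}
    usable = []
    for var in predictors:
        if var not in sub.columns or _clean(sub[var]).size == 0:
            roc["single"][var] = None
            report["warnings"].append(f"predictor '{var}' missing; ROC gap left")
            continue
        usable.append(var)
        if labels.min() == labels.max():
            roc["single"][var] = None
            continue
        roc["single"][var] = _roc_dict(roc_single(sub[var].to_numpy(), labels, predictor=var))
    if labels.min() != labels.max():
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                pair = (usable[i], usable[j])
                roc["pairs"][" + ".join(pair)] = _roc_dict(
                    roc_combined(sub[list(pair)], labels, feature_names=list(pair))
                )
        if len(usable) >= 3:
            roc["triple"] = _roc_dict(
                roc_combined(sub[list(usable[:3])], labels, feature_names=list(usable[:3]))
            )
    else:
        report["warnings"].append("comparison groups missing a class; ROC skipped")
    report["roc"] = roc
    return report
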