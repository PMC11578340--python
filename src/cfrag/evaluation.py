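"""Discrimination analysis and shared nonparametric tests.

ROC/AUC uses the rank (Mann-Whitney) formulation with ties contributing
one half, a stratified-bootstrap 95% CI, and the non-responder group as
the positive class throughout. The clinical classifier is a multiple
logistic regression on the four binarized covariates, fitted by IRLS and
evaluated in-sample by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

NON_RESPONDER = "non-responder"
RESPONDER = "responder"


class EvaluationError(ValueError):
    pass


class MissingDataError(EvaluationError):
    pass


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str

    def __iter__(self):
        return iter((self.u_statistic, self.p_value))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; exact null when min(n) <= 8 and there
    are no ties, tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(a.size, b.size) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    n_zero_dropped: int
    method: str


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (and counted); if every difference is zero
    the test is degenerate and p = 1. The exact null distribution is used
    for n <= 12 with untied |differences|, otherwise a normal approximation
    with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise EvaluationError("paired samples must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    n_zero = int(diffs.size - nonzero.size)
    if nonzero.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate")
    abs_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    exact = nonzero.size <= 12 and not abs_ties
    res = sps.wilcoxon(
        nonzero,
        zero_method="wilcox",
        alternative="two-sided",
        correction=True,
        method="exact" if exact else "approx",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_used=int(nonzero.size),
        n_zero_dropped=n_zero,
        method="exact" if exact else "asymptotic",
    )


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups; returns (H, p)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise EvaluationError("need >= 2 non-empty groups")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    feature_name: str
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    orientation: str  # which score direction indicates the positive class

    def as_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "orientation": self.orientation,
        }


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC via mean ranks; ties contribute 1/2 (equals normalized U)."""
    ranks = sps.rankdata(scores)
    n_pos = int(positive.sum())
    n_neg = int(positive.size - n_pos)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    positive_label=NON_RESPONDER,
    feature_name: str = "feature",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Rank-based AUC with a stratified-bootstrap percentile 95% CI.

    Higher scores are read as indicating the positive class; pass
    transformed scores to flip orientation.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int(positive.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present")
    auc = _rank_auc(scores, positive)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos_scores = scores[positive]
        neg_scores = scores[~positive]
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            ps = rng.choice(pos_scores, n_pos, replace=True)
            ns = rng.choice(neg_scores, n_neg, replace=True)
            resampled = np.concatenate([ps, ns])
            mask = np.zeros(n_pos + n_neg, dtype=bool)
            mask[:n_pos] = True
            boots[i] = _rank_auc(resampled, mask)
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low = min(float(ci_low), auc)
        ci_high = max(float(ci_high), auc)
    else:
        ci_low = ci_high = auc
    return RocResult(
        feature_name=feature_name,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pos=n_pos,
        n_neg=n_neg,
        orientation="higher score indicates positive class",
    )


def roc_curve_points(
    scores: Sequence[float], labels: Sequence, positive_label=NON_RESPONDER
) -> pd.DataFrame:
    """Full ROC curve (threshold, fpr, tpr) at every distinct score."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    n_pos = positive.sum()
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = positive[order]
    distinct = np.append(np.flatnonzero(np.diff(sorted_scores) != 0), len(scores) - 1)
    tps = np.cumsum(sorted_pos)[distinct]
    fps = distinct + 1 - tps
    return pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], sorted_scores[distinct]]),
            "fpr": np.concatenate([[0.0], fps / n_neg]),
            "tpr": np.concatenate([[0.0], tps / n_pos]),
        }
    )


# ---------------------------------------------------------------------------
# clinical covariates and logistic classifier
# ---------------------------------------------------------------------------

_FIGO_MAJOR = {"I": 1, "II": 2, "III": 3, "IV": 4}
_FIGO_LETTER = {"": 0, "A": 1, "B": 2, "C": 3}

CLINICAL_FEATURES = ("age_gt_50", "stage_ge_IIB", "tumor_size_ge_4cm", "scc_ag")


def figo_stage_rank(stage: str) -> tuple[int, int, int]:
    """Orderable rank of a FIGO stage string like 'IB3', 'IIB', 'IIIC1'."""
    s = str(stage).strip().upper()
    for major in ("IV", "III", "II", "I"):
        if s.startswith(major):
            rest = s[len(major) :]
            letter = rest[0] if rest and rest[0] in "ABC" else ""
            digits = rest[len(letter) :]
            sub = int(digits) if digits.isdigit() and digits else 0
            return (_FIGO_MAJOR[major], _FIGO_LETTER[letter], sub)
    raise EvaluationError(f"unparseable FIGO stage {stage!r}")


def stage_at_least(stage: str, cutoff: str = "IIB") -> bool:
    return figo_stage_rank(stage) >= figo_stage_rank(cutoff)


def binarize_clinical(record: Mapping) -> dict[str, float]:
    """Encode age (>50), stage (>=IIB), tumor size (>=4 cm) as 0/1 and carry
    pretreatment SCC-Ag as a number."""
    required = ("age", "figo_stage", "initial_diameter_cm", "scc_ag_pretreatment")
    missing = [
        f for f in required if f not in record or record[f] is None or pd.isna(record[f])
    ]
    if missing:
        raise MissingDataError(f"missing clinical covariates: {missing}")
    return {
        "age_gt_50": 1.0 if float(record["age"]) > 50 else 0.0,
        "stage_ge_IIB": 1.0 if stage_at_least(record["figo_stage"]) else 0.0,
        "tumor_size_ge_4cm": 1.0 if float(record["initial_diameter_cm"]) >= 4.0 else 0.0,
        "scc_ag": float(record["scc_ag_pretreatment"]),
    }


_COEF_CAP = 30.0


@dataclass
class ClinicalClassifier:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    intercept: float = 0.0
    fitted: bool = False
    separated: bool = False
    n_iter: int = 0
    converged: bool = False
    dropped_features: tuple[str, ...] = ()

    def predict_proba(self, X) -> np.ndarray:
        if not self.fitted:
            raise EvaluationError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        return expit(self.intercept + X @ self.coefficients)

    def as_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "separated": self.separated,
            "converged": self.converged,
        }


def fit_clinical_classifier(
    X,
    y: Sequence,
    feature_names: Sequence[str] | None = None,
    positive_label=NON_RESPONDER,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClinicalClassifier:
    """Maximum-likelihood logistic regression by IRLS.

    Constant features are dropped with a warning. Perfect separation is
    flagged and coefficient magnitudes are capped instead of diverging.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = tuple(feature_names or (f"x{i}" for i in range(X.shape[1])))
    yb = np.asarray([lab == positive_label for lab in y], dtype=float)
    if yb.sum() == 0 or yb.sum() == yb.size:
        raise EvaluationError("both classes must be present to fit the classifier")

    keep = np.array([np.ptp(X[:, j]) > 0 for j in range(X.shape[1])])
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"dropping constant clinical features: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    design = np.column_stack([np.ones(len(Xk)), Xk])

    beta = np.zeros(design.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(design @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        hessian = design.T @ (design * w[:, None]) + 1e-12 * np.eye(design.shape[1])
        grad = design.T @ (yb - p)
        delta = np.linalg.solve(hessian, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 5 * _COEF_CAP:
            break

    separated = bool(np.max(np.abs(beta)) > _COEF_CAP or not converged)
    if separated:
        warnings.warn(
            "possible perfect separation: capping coefficient magnitudes",
            stacklevel=2,
        )
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)

    coefficients = np.zeros(X.shape[1])
    coefficients[keep] = beta[1:]
    return ClinicalClassifier(
        feature_names=names,
        coefficients=coefficients,
        intercept=float(beta[0]),
        fitted=True,
        separated=separated,
        n_iter=n_iter,
        converged=converged,
        dropped_features=dropped,
    )


def cross_validated_probabilities(
    X, y: Sequence, positive_label=NON_RESPONDER
) -> np.ndarray:
    """Leave-one-out predicted probabilities from the logistic classifier."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = list(y)
    n = len(y)
    probs = np.empty(n)
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask = idx != i
            clf = fit_clinical_classifier(
                X[mask], [y[j] for j in idx[mask]], positive_label=positive_label
            )
            probs[i] = clf.predict_proba(X[i : i + 1])[0]
    return probs
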