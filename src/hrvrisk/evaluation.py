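"""Model evaluation: LOOCV scoring, ROC/AUC, cutoffs, model comparison.

The harness mirrors the evaluation design of a rare-outcome triage study:
leave-one-out cross-validation so every patient is scored by a model that
never saw them; AUC with a DeLong (default) or bootstrap confidence
interval; the operating point nearest the ROC upper-left corner with Wald
intervals on sensitivity and specificity; an AUC sweep over ranked-variable
prefixes; and paired, class-stratified bootstrap comparison of two score
sets on the same patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .riskscore import DistanceRiskModel
from .selection import mann_whitney_p

__all__ = [
    "ROCResult",
    "CutoffResult",
    "ComparisonResult",
    "loocv_scores",
    "roc_auc",
    "optimal_cutoff",
    "prefix_performance",
    "compare_auc_bootstrap",
    "summarize_groups",
]


def _auc_mw(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability (ties count one half)."""
    ranks = stats.rankdata(scores)
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = float(psi.mean())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return auc, float(var)


@dataclass
class ROCResult:
    """ROC curve, AUC and its confidence interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_var: float
    ci: tuple[float, float]
    ci_level: float
    ci_method: str
    n_positive: int
    n_negative: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def pvalue_vs(self, auc0: float = 0.5) -> float:
        """Two-sided DeLong z-test of AUC against a reference value."""
        if self.auc_var <= 0:
            return 0.0 if self.auc != auc0 else 1.0
        z = (self.auc - auc0) / np.sqrt(self.auc_var)
        return float(2.0 * stats.norm.sf(abs(z)))


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, with +/-inf sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_auc(
    scores,
    labels,
    ci_level: float = 0.95,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> ROCResult:
    """ROC curve and AUC with a confidence interval.

    AUC is the Mann-Whitney concordance probability; the CI is DeLong by
    default, or a class-stratified bootstrap percentile interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")
    thr = _threshold_grid(scores)[::-1]  # descending: curve runs (0,0) -> (1,1)
    pos, neg = labels == 1, labels == 0
    tpr = np.array([(scores[pos] >= t).mean() for t in thr])
    fpr = np.array([(scores[neg] >= t).mean() for t in thr])
    auc, var = _delong_auc_variance(scores, labels)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    if ci_method == "delong":
        half = z * np.sqrt(var)
        ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = _stratified_boot_auc(rng, scores, labels, n_boot)
        lo, hi = np.percentile(reps, [100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, auc_var=var, ci=ci,
        ci_level=ci_level, ci_method=ci_method,
        n_positive=int(pos.sum()), n_negative=int(neg.sum()),
        scores=scores, labels=labels,
    )


def _stratified_boot_auc(rng, scores, labels, n_boot):
    pos_i = np.flatnonzero(labels == 1)
    neg_i = np.flatnonzero(labels == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_i, size=len(pos_i), replace=True)
        ni = rng.choice(neg_i, size=len(neg_i), replace=True)
        idx = np.concatenate([pi, ni])
        reps[b] = _auc_mw(scores[idx], labels[idx])
    return reps


def wald_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald normal-approximation interval for a proportion."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


@dataclass
class CutoffResult:
    """Operating point nearest the ROC upper-left corner."""

    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    distance: float


def optimal_cutoff(roc: ROCResult, ci_level: float = 0.95) -> CutoffResult:
    """Threshold minimizing the distance to (FPR 0, sensitivity 1).

    Distance is Euclidean, sqrt((1 - sens)^2 + (1 - spec)^2); ties break
    toward higher sensitivity.  Sensitivity/specificity intervals are Wald.
    """
    sens = roc.tpr
    spec = 1.0 - roc.fpr
    dist = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    order = np.lexsort((-sens, dist))  # distance asc, then sensitivity desc
    i = order[0]
    return CutoffResult(
        threshold=float(roc.thresholds[i]),
        sensitivity=float(sens[i]),
        sensitivity_ci=wald_ci(float(sens[i]), roc.n_positive, ci_level),
        specificity=float(spec[i]),
        specificity_ci=wald_ci(float(spec[i]), roc.n_negative, ci_level),
        distance=float(dist[i]),
    )


def loocv_scores(
    X: pd.DataFrame,
    y,
    builder=None,
    seed: int | None = None,
    **model_kw,
) -> np.ndarray:
    """Leave-one-out cross-validated scores.

    Each patient is scored by a model fitted on the other n - 1 patients;
    the held-out row never enters its own training fold.  ``builder`` is a
    callable ``(X_train, y_train, fold_seed) -> fitted`` with a
    ``predict``; the default fits :class:`DistanceRiskModel` with
    ``model_kw`` forwarded.
    """
    y = np.asarray(y)
    if len(X) < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("LOOCV would leave a training fold without a class")
    if builder is None:
        def builder(Xtr, ytr, s):
            return DistanceRiskModel(Xtr, ytr, **model_kw).fit(s)

    out = np.empty(len(X))
    mask = np.ones(len(X), dtype=bool)
    for i in range(len(X)):
        mask[i] = False
        fitted = builder(X.iloc[mask], y[mask], seed)
        out[i] = np.asarray(fitted.predict(X.iloc[[i]]))[0]
        mask[i] = True
    return out


def prefix_performance(
    X: pd.DataFrame,
    y,
    ranked_variables,
    lam: float = 0.5,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """LOOCV AUC of the risk model on each ranked-variable prefix.

    Row k uses the first k variables; the best prefix is flagged in the
    ``best`` column.
    """
    ranked = list(ranked_variables)
    if not ranked:
        raise ValueError("ranked variable list is empty")
    rows = []
    for k in range(1, len(ranked) + 1):
        vars_k = ranked[:k]
        s = loocv_scores(X, y, variables=vars_k, lam=lam, seed=seed)
        r = roc_auc(s, y, ci_level=ci_level)
        rows.append(
            {
                "prefix": ", ".join(vars_k),
                "k": k,
                "auc": r.auc,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
            }
        )
    df = pd.DataFrame(rows).set_index("k")
    df["best"] = df["auc"] == df["auc"].max()
    return df


@dataclass
class ComparisonResult:
    """Paired bootstrap comparison of two score sets on the same patients."""

    auc_a: float
    auc_b: float
    difference: float
    p_value: float
    n_boot: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"AUC A = {self.auc_a:.3f}, AUC B = {self.auc_b:.3f}, "
            f"diff = {self.difference:+.3f}, p = {self.p_value:.3g} "
            f"({self.n_boot} bootstrap replicates)"
        )


def compare_auc_bootstrap(
    scores_a,
    scores_b,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ComparisonResult:
    """Two-sided paired bootstrap test of AUC_A - AUC_B.

    Patients are resampled with replacement, stratified by class and
    *paired* (the same patients enter both score sets in a replicate).  The
    p-value is the normal approximation: z = observed difference over the
    bootstrap standard deviation of the difference.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score sets must cover the same patients")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates", UserWarning, stacklevel=2)
    auc_a = _auc_mw(scores_a, labels)
    auc_b = _auc_mw(scores_b, labels)
    diff = auc_a - auc_b
    rng = np.random.default_rng(seed)
    pos_i = np.flatnonzero(labels == 1)
    neg_i = np.flatnonzero(labels == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_i, size=len(pos_i), replace=True),
                rng.choice(neg_i, size=len(neg_i), replace=True),
            ]
        )
        lab = labels[idx]
        reps[b] = _auc_mw(scores_a[idx], lab) - _auc_mw(scores_b[idx], lab)
    sd = float(np.std(reps, ddof=1))
    if sd == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(diff) / sd))
    return ComparisonResult(auc_a, auc_b, diff, p, n_boot, seed)


def summarize_groups(
    frame: pd.DataFrame,
    variables=None,
    outcome: str = "outcome",
    median_vars=("GCS", "pain"),
) -> pd.DataFrame:
    """Group-wise summary table: mean (SD) or median (IQR) plus p-value.

    ``median_vars`` are summarized as ``median (q1 to q3)``; everything
    else as ``mean (sd)``.  The p-value is the two-sided Mann-Whitney test
    between outcome groups.
    """
    y = frame[outcome].to_numpy()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    if variables is None:
        variables = [
            c for c in frame.columns
            if c != outcome and pd.api.types.is_numeric_dtype(frame[c])
        ]
    rows = {}
    for v in variables:
        col = frame[v].to_numpy(dtype=float)
        cells = {}
        for name, grp in (("no_mace", col[y == 0]), ("mace", col[y == 1])):
            if v in median_vars:
                q1, med, q3 = np.percentile(grp, [25, 50, 75])
                cells[name] = f"{med:g} ({q1:g} to {q3:g})"
            else:
                cells[name] = f"{grp.mean():.3f} ({grp.std(ddof=1):.3f})"
        cells["p_value"] = mann_whitney_p(col[y == 1], col[y == 0])
        rows[v] = cells
    return pd.DataFrame.from_dict(rows, orient="index")
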