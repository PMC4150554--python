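"""Ensemble variable selection for imbalanced cohorts.

The selector de-biases tree-based variable ranking on a rare-outcome cohort
by repeated balanced subsampling: each of ``n_subsets`` subsets combines all
positives with an equal-size random draw of negatives; a random forest is
fitted to each subset and its ``top_k`` variables by importance are
recorded; variables are then ranked by how often they appear across the
ensemble ("occurrence"), and the top-``top_k`` by occurrence are refined by
a per-variable two-sided Mann-Whitney test on the full cohort — variables
that do not separate the outcome groups at ``alpha`` are excluded.

Exposed as a Model/Results pair: :class:`EnsembleSelector` holds the data
and parameters, ``fit`` returns a :class:`SelectionResult` with the
occurrence table, p-values, the final variable set and an audit log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = [
    "SelectionParams",
    "SelectionResult",
    "EnsembleSelector",
    "build_balanced_subsets",
    "rank_subset",
    "ensemble_occurrences",
    "mann_whitney_p",
    "select_variables",
]


@dataclass(frozen=True)
class SelectionParams:
    """Ensemble-selection knobs.

    Defaults follow the reference procedure: 500 balanced subsets, forests
    of 500 trees, top-8 variables per subset, significance refinement at
    alpha = 0.05.  ``importance`` chooses mean-decrease-in-impurity (the
    random-forest default) or permutation importance.
    """

    n_subsets: int = 500
    trees_per_forest: int = 500
    top_k: int = 8
    importance: str = "gini"
    alpha: float = 0.05
    max_features: str | float = "sqrt"
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.importance not in ("gini", "permutation"):
            raise ValueError("importance must be 'gini' or 'permutation'")


def build_balanced_subsets(
    X: pd.DataFrame,
    y: np.ndarray,
    n_subsets: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Index sets combining all positives with equal-size negative draws.

    Negatives are drawn without replacement within a subset; subsets are
    drawn independently of one another.
    """
    y = np.asarray(y)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0:
        raise ValueError("cohort has no positive patients")
    if len(neg_idx) < len(pos_idx):
        raise ValueError("fewer negatives than positives; cannot balance")
    subsets = []
    for _ in range(n_subsets):
        sampled = rng.choice(neg_idx, size=len(pos_idx), replace=False)
        subsets.append(np.sort(np.concatenate([pos_idx, sampled])))
    return subsets


def rank_subset(
    X: pd.DataFrame,
    y: np.ndarray,
    params: SelectionParams,
    seed: int,
) -> list[str]:
    """Top-``top_k`` variables of one balanced subset by forest importance.

    Features are standardized (harmless for trees, keeps the feature matrix
    on one scale for any downstream use); ties in importance break by fixed
    column order.
    """
    cols = list(X.columns)
    k = min(params.top_k, len(cols))
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    rf = RandomForestClassifier(
        n_estimators=params.trees_per_forest,
        max_features=params.max_features,
        max_depth=params.max_depth,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xs.to_numpy(), np.asarray(y))
    if params.importance == "gini":
        imp = rf.feature_importances_
    else:
        res = permutation_importance(
            rf, Xs.to_numpy(), np.asarray(y), n_repeats=5,
            random_state=seed, n_jobs=1,
        )
        imp = res.importances_mean
    order = np.lexsort((np.arange(len(cols)), -imp))  # importance desc, then column order
    return [cols[i] for i in order[:k]]


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value for a group difference.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction.
    Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class OccurrenceRecord:
    counts: pd.Series  # variable -> occurrence
    mean_rank: pd.Series  # variable -> mean within-subset rank (1 = best)
    n_subsets: int


@dataclass
class SelectionResult:
    """Outcome of the ensemble selection.

    ``occurrence`` counts, per-variable Mann-Whitney ``p_values`` on the
    full cohort, the occurrence-ranked ``candidates`` (top-k), the final
    ``selected`` list after significance refinement, and an ``audit`` log
    of exclusions.
    """

    occurrence: pd.Series
    mean_rank: pd.Series
    n_subsets: int
    top_k: int
    alpha: float
    candidates: list[str]
    p_values: pd.Series
    selected: list[str]
    audit: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Ensemble variable selection",
            "===========================",
            f"subsets: {self.n_subsets}   top-k per subset: {self.top_k}   "
            f"alpha: {self.alpha}",
            "",
            f"{'variable':<18}{'occurrence':>11}{'p-value':>12}  selected",
        ]
        for v in self.occurrence.sort_values(ascending=False).index:
            p = self.p_values.get(v, np.nan)
            mark = "yes" if v in self.selected else ""
            ptxt = f"{p:.4g}" if np.isfinite(p) else "-"
            lines.append(f"{v:<18}{int(self.occurrence[v]):>11}{ptxt:>12}  {mark}")
        if self.audit:
            lines += ["", "exclusions:"] + [f"  - {a}" for a in self.audit]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"occurrence": self.occurrence})
        df["p_value"] = self.p_values.reindex(df.index)
        df["selected"] = [v in self.selected for v in df.index]
        return df.sort_values("occurrence", ascending=False)


class EnsembleSelector:
    """Balanced-subsampling random-forest variable selector.

    Parameters
    ----------
    X : DataFrame
        Candidate predictors, one row per patient.
    y : array-like of 0/1
        Binary outcome.
    params : SelectionParams, optional
    """

    def __init__(self, X: pd.DataFrame, y, params: SelectionParams | None = None):
        self.X = X
        self.y = np.asarray(y)
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        self.params = params or SelectionParams()
        if self.params.top_k > X.shape[1]:
            raise ValueError("top_k exceeds the number of candidate variables")

    # -- occurrence stage ---------------------------------------------------
    def occurrences(self, seed: int | None = None) -> OccurrenceRecord:
        """Run the subset ensemble and aggregate top-k appearances."""
        p = self.params
        rng = np.random.default_rng(seed)
        subsets = build_balanced_subsets(self.X, self.y, p.n_subsets, rng)
        forest_seeds = rng.integers(0, 2**31 - 1, size=p.n_subsets)
        counts = pd.Series(0, index=self.X.columns, dtype=int)
        rank_sum = pd.Series(0.0, index=self.X.columns)
        for idx, fseed in zip(subsets, forest_seeds):
            top = rank_subset(self.X.iloc[idx], self.y[idx], p, int(fseed))
            for r, v in enumerate(top, start=1):
                counts[v] += 1
                rank_sum[v] += r
        with np.errstate(invalid="ignore"):
            mean_rank = rank_sum / counts.replace(0, np.nan)
        return OccurrenceRecord(counts, mean_rank, p.n_subsets)

    # -- full procedure -----------------------------------------------------
    def fit(self, seed: int | None = None) -> SelectionResult:
        """Occurrence ranking plus Mann-Whitney significance refinement."""
        p = self.params
        occ = self.occurrences(seed)
        # sort: occurrence desc, then better (lower) mean within-subset
        # rank, then fixed column order
        order = sorted(
            range(len(self.X.columns)),
            key=lambda i: (
                -occ.counts.iloc[i],
                occ.mean_rank.iloc[i] if np.isfinite(occ.mean_rank.iloc[i]) else np.inf,
                i,
            ),
        )
        ranked = [self.X.columns[i] for i in order]
        candidates = ranked[: p.top_k]
        pos = self.y == 1
        p_values = pd.Series(
            {
                v: mann_whitney_p(
                    self.X.loc[pos, v].to_numpy(), self.X.loc[~pos, v].to_numpy()
                )
                for v in candidates
            }
        )
        audit = []
        selected = []
        for v in candidates:
            if p_values[v] < p.alpha:
                selected.append(v)
            else:
                audit.append(
                    f"{v}: excluded, Mann-Whitney p = {p_values[v]:.4g} >= {p.alpha}"
                )
        if not selected:
            warnings.warn(
                "significance refinement excluded every candidate variable",
                UserWarning,
                stacklevel=2,
            )
        return SelectionResult(
            occurrence=occ.counts,
            mean_rank=occ.mean_rank,
            n_subsets=p.n_subsets,
            top_k=p.top_k,
            alpha=p.alpha,
            candidates=candidates,
            p_values=p_values,
            selected=selected,
            audit=audit,
        )


# -- functional conveniences -------------------------------------------------

def ensemble_occurrences(X, y, params=None, seed=None) -> pd.Series:
    """Occurrence counts only (variable -> appearances in the ensemble)."""
    return EnsembleSelector(X, y, params).occurrences(seed).counts


def select_variables(X, y, params=None, seed=None) -> SelectionResult:
    """One-call form of :meth:`EnsembleSelector.fit`."""
    return EnsembleSelector(X, y, params).fit(seed)
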