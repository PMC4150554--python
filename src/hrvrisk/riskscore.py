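"""Geometric distance-based 0-100 risk score with SVM refinement.

The score places a patient in a normalized feature space and asks which
class centroid they sit closer to:

1. each selected variable is min-max normalized to [-1, 1] using training
   bounds (test values are clipped into the interval);
2. the positive (MACE) and negative class centroids are computed in the
   normalized space;
3. the initial score is ``S0 = 100 * d_neg / (d_pos + d_neg)`` with
   Euclidean distances to the two centroids — 100 at the positive centroid,
   0 at the negative one, 50 on the midline;
4. a soft-margin SVM (RBF by default, class-weighted for imbalance) is
   fitted on the normalized data and its decision values are mapped to
   [0, 1] with a Platt-style logistic calibration, giving a refined score
   ``S1 = 100 * p``;
5. the emitted score blends the two: ``S = (1 - lam) * S0 + lam * S1``,
   clipped to [0, 100].  ``lam = 0`` is the pure distance score, ``lam = 1``
   the pure calibrated SVM.

The blend weight parameterizes an ambiguity in how the refinement combines
with the geometric score; 0.5 is the default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "MinMaxBounds",
    "fit_minmax",
    "cluster_centers",
    "distance_score",
    "DistanceRiskModel",
    "DistanceRiskResults",
]


@dataclass(frozen=True)
class MinMaxBounds:
    """Per-variable training (min, max) and the [-1, 1] transform."""

    variables: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: pd.DataFrame, clip: bool = True) -> np.ndarray:
        Z = 2.0 * (X[list(self.variables)].to_numpy(float) - self.mins) / (
            self.maxs - self.mins
        ) - 1.0
        return np.clip(Z, -1.0, 1.0) if clip else Z


def fit_minmax(X: pd.DataFrame) -> MinMaxBounds:
    """Training min/max per variable; constant variables are dropped."""
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    keep = [c for c in X.columns if maxs[c] > mins[c]]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(
            f"dropping constant variable(s) from normalization: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if not keep:
        raise ValueError("no variable has two distinct training values")
    return MinMaxBounds(
        tuple(keep), mins[keep].to_numpy(float), maxs[keep].to_numpy(float)
    )


def cluster_centers(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class centroids (positive, negative) in the normalized space."""
    y = np.asarray(y)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    return Z[y == 1].mean(axis=0), Z[y == 0].mean(axis=0)


def distance_score(Z: np.ndarray, pos_center: np.ndarray, neg_center: np.ndarray) -> np.ndarray:
    """Initial score S0 = 100 * d_neg / (d_pos + d_neg), elementwise."""
    Z = np.atleast_2d(Z)
    if Z.shape[1] != len(pos_center):
        raise ValueError("sample dimension does not match the fitted centers")
    d_pos = np.linalg.norm(Z - pos_center, axis=1)
    d_neg = np.linalg.norm(Z - neg_center, axis=1)
    denom = d_pos + d_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        s0 = 100.0 * d_neg / denom
    return np.where(denom == 0, 50.0, s0)


class DistanceRiskModel:
    """Distance-based risk score model for a binary outcome.

    Parameters
    ----------
    X : DataFrame
        Training features (raw scale), one row per patient.
    y : array-like of 0/1
        Outcome labels.
    variables : sequence of str, optional
        Predictors to use (defaults to all columns of ``X``).
    lam : float in [0, 1]
        Blend weight between the distance score (0) and the calibrated SVM
        score (1).
    C, gamma, kernel : SVM hyperparameters.  ``gamma`` defaults to ``1/p``
        for ``p`` predictors; class weights are inversely proportional to
        class frequency.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        variables=None,
        lam: float = 0.5,
        C: float = 1.0,
        gamma: float | str | None = None,
        kernel: str = "rbf",
    ):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        self.variables = list(variables) if variables is not None else list(X.columns)
        self.X = X[self.variables]
        self.y = np.asarray(y)
        self.lam = lam
        self.C = C
        self.gamma = gamma if gamma is not None else 1.0 / len(self.variables)
        self.kernel = kernel

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, outcome: str = "outcome", **kw):
        y = frame[outcome].to_numpy()
        X = frame.drop(columns=[outcome])
        return cls(X, y, **kw)

    def fit(self, seed: int | None = None) -> "DistanceRiskResults":
        bounds = fit_minmax(self.X)
        Z = bounds.transform(self.X, clip=False)  # training data defines the range
        pos_c, neg_c = cluster_centers(Z, self.y)
        svm = platt = None
        if self.lam > 0.0:
            svm = SVC(
                C=self.C,
                kernel=self.kernel,
                gamma=self.gamma,
                class_weight="balanced",
                random_state=seed,
            )
            svm.fit(Z, self.y)
            dec = svm.decision_function(Z).reshape(-1, 1)
            # Platt-style map: logistic regression of the labels on the
            # training decision values
            platt = LogisticRegression(C=1e3)
            platt.fit(dec, self.y)
        return DistanceRiskResults(self, bounds, pos_c, neg_c, svm, platt)


class DistanceRiskResults:
    """Fitted normalization bounds, centroids and SVM refiner."""

    def __init__(self, model, bounds, pos_center, neg_center, svm, platt):
        self.model = model
        self.bounds = bounds
        self.pos_center = np.asarray(pos_center)
        self.neg_center = np.asarray(neg_center)
        self.svm = svm
        self.platt = platt

    # -- scoring ------------------------------------------------------------
    def initial_score(self, X: pd.DataFrame) -> np.ndarray:
        """Distance-only score S0 on new data."""
        Z = self.bounds.transform(X)
        return distance_score(Z, self.pos_center, self.neg_center)

    def refined_score(self, X: pd.DataFrame) -> np.ndarray:
        """Calibrated-SVM score S1 on new data."""
        if self.svm is None:
            raise ValueError("no SVM refiner was fitted (lam = 0)")
        Z = self.bounds.transform(X)
        dec = self.svm.decision_function(Z).reshape(-1, 1)
        return 100.0 * self.platt.predict_proba(dec)[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Blended risk score in [0, 100]."""
        lam = self.model.lam
        s0 = self.initial_score(X) if lam < 1.0 else 0.0
        s1 = self.refined_score(X) if lam > 0.0 else 0.0
        return np.clip((1.0 - lam) * s0 + lam * s1, 0.0, 100.0)

    # -- reporting / persistence --------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Distance-based risk score model",
            "===============================",
            f"variables: {', '.join(self.bounds.variables)}",
            f"blend weight lam: {m.lam}   SVM: {m.kernel}, C={m.C}, gamma={m.gamma:.4g}"
            if m.lam > 0
            else f"blend weight lam: {m.lam} (pure distance score)",
            "",
            f"{'variable':<18}{'train min':>12}{'train max':>12}"
            f"{'pos center':>12}{'neg center':>12}",
        ]
        for i, v in enumerate(self.bounds.variables):
            lines.append(
                f"{v:<18}{self.bounds.mins[i]:>12.4g}{self.bounds.maxs[i]:>12.4g}"
                f"{self.pos_center[i]:>12.4g}{self.neg_center[i]:>12.4g}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        """Persist the geometric part of the model (bounds, centers, blend)."""
        payload = {
            "variables": list(self.bounds.variables),
            "mins": self.bounds.mins.tolist(),
            "maxs": self.bounds.maxs.tolist(),
            "pos_center": self.pos_center.tolist(),
            "neg_center": self.neg_center.tolist(),
            "lam": self.model.lam,
            "svm": None
            if self.svm is None
            else {"kernel": self.model.kernel, "C": self.model.C, "gamma": self.model.gamma,
                  "n_support": self.svm.n_support_.tolist()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))
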