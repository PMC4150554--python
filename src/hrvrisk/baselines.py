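"""Comparator clinical scores: TIMI, MEWS, and forward-selection logistic.

TIMI (UA/NSTEMI variant) is a 7-item additive score, one point per item.
MEWS sums banded points over vital signs plus a consciousness level; the
band tables ship as data-driven configuration (YAML-serializable dicts),
not code constants, so local variants can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "TIMI_ITEMS",
    "timi_score",
    "DEFAULT_MEWS_TABLE",
    "GCS_TO_AVPU",
    "gcs_to_avpu",
    "mews_score",
    "mews_from_frame",
    "timi_from_frame",
    "ForwardLogitResults",
    "logistic_forward",
]

TIMI_ITEMS = (
    "timi_age65",
    "timi_risk_factors",
    "timi_known_cad",
    "timi_aspirin",
    "timi_angina",
    "timi_st_deviation",
    "timi_markers",
)


def timi_score(items) -> int:
    """TIMI UA/NSTEMI score: one point per positive item, 0-7."""
    if isinstance(items, dict) or hasattr(items, "keys"):
        vals = [bool(items[k]) for k in TIMI_ITEMS]
    else:
        vals = list(items)
    if len(vals) != 7:
        raise ValueError("TIMI needs exactly 7 item flags")
    return int(sum(bool(v) for v in vals))


# MEWS band tables: list of (lower, upper, points) with half-open
# [lower, upper) bands covering the physiological range; None = unbounded.
DEFAULT_MEWS_TABLE: dict = {
    "SBP": [(None, 71, 3), (71, 81, 2), (81, 101, 1), (101, 200, 0), (200, None, 2)],
    "pulse_rate": [
        (None, 40, 2), (40, 51, 1), (51, 101, 0), (101, 111, 1),
        (111, 130, 2), (130, None, 3),
    ],
    "resp_rate": [(None, 9, 2), (9, 15, 0), (15, 21, 1), (21, 30, 2), (30, None, 3)],
    "temperature": [(None, 35.0, 2), (35.0, 38.5, 0), (38.5, None, 2)],
    "avpu": {"alert": 0, "voice": 1, "pain": 2, "unresponsive": 3},
}

#: GCS bands mapped to AVPU levels (a cohort records GCS, MEWS wants AVPU)
GCS_TO_AVPU = [(15, 16, "alert"), (13, 15, "voice"), (9, 13, "pain"), (0, 9, "unresponsive")]


def gcs_to_avpu(gcs: float, table=None) -> str:
    for lo, hi, level in table or GCS_TO_AVPU:
        if lo <= gcs < hi:
            return level
    raise ValueError(f"GCS {gcs} outside every band")


def _band_points(value: float, bands, name: str) -> int:
    for lo, hi, pts in bands:
        if (lo is None or value >= lo) and (hi is None or value < hi):
            return pts
    raise ValueError(f"{name} = {value} falls outside every configured band")


@dataclass(frozen=True)
class MEWSInputs:
    SBP: float
    pulse_rate: float
    resp_rate: float
    temperature: float
    avpu: str


def mews_score(vitals: MEWSInputs | dict, table: dict | None = None) -> int:
    """Modified early warning score: banded points summed over vitals."""
    table = table or DEFAULT_MEWS_TABLE
    v = vitals if isinstance(vitals, dict) else vitals.__dict__
    total = 0
    for name in ("SBP", "pulse_rate", "resp_rate", "temperature"):
        total += _band_points(float(v[name]), table[name], name)
    avpu = v["avpu"]
    if avpu not in table["avpu"]:
        raise ValueError(f"unknown consciousness level {avpu!r}")
    return total + int(table["avpu"][avpu])


def mews_from_frame(frame: pd.DataFrame, table: dict | None = None) -> pd.Series:
    """MEWS per patient from cohort columns (GCS is mapped to AVPU)."""
    scores = {}
    for pid, row in frame.iterrows():
        scores[pid] = mews_score(
            {
                "SBP": row["SBP"],
                "pulse_rate": row["pulse_rate"],
                "resp_rate": row["resp_rate"],
                "temperature": row["temperature"],
                "avpu": gcs_to_avpu(row["GCS"]),
            },
            table,
        )
    return pd.Series(scores, name="MEWS")


def timi_from_frame(frame: pd.DataFrame) -> pd.Series:
    """TIMI per patient from the 7 item-flag columns."""
    return frame[list(TIMI_ITEMS)].sum(axis=1).astype(int).rename("TIMI")


class ForwardLogitResults:
    """Forward-selection logistic regression fit.

    Carries the selected variable list, the statsmodels results (or the
    penalized fallback), and predicted probabilities on the training data.
    """

    def __init__(self, selected, results, trace, X, y, fallback=None):
        self.selected = list(selected)
        self.results = results
        self.trace = trace  # list of (variable, p_entry)
        self._X = X
        self._y = np.asarray(y)
        self._fallback = fallback

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        X = self._X if X is None else X
        if not self.selected:  # intercept-only: prevalence for everyone
            return np.full(len(X), self._y.mean())
        if self._fallback is not None:
            return self._fallback.predict_proba(X[self.selected].to_numpy())[:, 1]
        design = sm.add_constant(X[self.selected], has_constant="add")
        return np.asarray(self.results.predict(design))

    def summary(self) -> str:
        lines = ["Forward-selection logistic regression", "=" * 37]
        if not self.selected:
            lines.append("no variable met the entry criterion; intercept-only model")
        for v, p in self.trace:
            lines.append(f"entered {v:<20} (LR p = {p:.4g})")
        if self.results is not None and self.selected:
            lines += ["", str(self.results.summary2())]
        return "\n".join(lines)


def logistic_forward(
    X: pd.DataFrame,
    y,
    candidates=None,
    entry_alpha: float = 0.05,
) -> ForwardLogitResults:
    """Forward stepwise logistic regression by likelihood-ratio entry test.

    At each step the candidate with the smallest likelihood-ratio p-value
    enters if p < ``entry_alpha``; there is no removal step.  Perfect
    separation triggers a warning and an L2-penalized refit of the selected
    set.
    """
    y = np.asarray(y)
    candidates = list(candidates) if candidates is not None else list(X.columns)
    if len(set(np.unique(y))) < 2:
        raise ValueError("both outcome classes must be present")
    selected: list[str] = []
    trace: list[tuple[str, float]] = []

    def _fit(cols):
        design = sm.add_constant(X[cols] if cols else pd.DataFrame(index=X.index),
                                 has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.Logit(y, design).fit(disp=0, maxiter=200)

    try:
        current = _fit(selected)
        while True:
            remaining = [c for c in candidates if c not in selected]
            if not remaining:
                break
            best = None
            for c in remaining:
                try:
                    cand = _fit(selected + [c])
                except Exception:
                    continue
                lr = 2.0 * (cand.llf - current.llf)
                p = stats.chi2.sf(max(lr, 0.0), df=1)
                if best is None or p < best[1]:
                    best = (c, p, cand)
            if best is None or best[1] >= entry_alpha:
                break
            selected.append(best[0])
            trace.append((best[0], best[1]))
            current = best[2]
        unstable = selected and (
            not np.all(np.isfinite(current.bse))
            or np.nanmax(current.bse) > 1e4
            or not current.mle_retvals.get("converged", True)
        )
        if unstable:  # (quasi-)separation: ML estimates diverge
            raise np.linalg.LinAlgError("unstable fit")
        return ForwardLogitResults(selected, current if selected else None, trace, X, y)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        warnings.warn(
            "separation or unstable fit; refitting selected set with L2 penalty",
            UserWarning,
            stacklevel=2,
        )
        fb = LogisticRegression(C=1.0, max_iter=1000)
        cols = selected or candidates
        fb.fit(X[cols].to_numpy(), y)
        return ForwardLogitResults(cols, None, trace, X, y, fallback=fb)
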