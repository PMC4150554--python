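"""Synthetic ED chest-pain cohort generator.

Emulates an imbalanced prospective cohort (by default 702 patients, 29 of
whom meet a composite MACE outcome within 72 h) whose group-conditional
variable distributions match published summary statistics: 8 clinical signs
and 15 HRV parameters per patient, plus demographics, medical history, TIMI
item flags and the binary outcome.

Design of the generator
-----------------------
* Each continuous variable is a truncated normal within physiological
  bounds; the location is re-calibrated so the *truncated* mean equals the
  configured target (naive truncation would bias skew-bounded variables).
* The positive count is exact, not binomial: generation conditions on the
  configured number of MACE patients.  Demographic and history flags are
  likewise assigned as exact per-group counts (scaled to group size), so
  cohort composition arithmetic is deterministic.
* Structural couplings are enforced rather than sampled: avHR is derived
  from aRR (with a per-group calibration factor so its mean hits the
  configured target) and HF_norm = 100 - LF_norm always; by default
  (``couple_spectral``) LF is additionally derived from HF and LF_norm so
  that LF/HF = LF_norm/HF_norm holds exactly.
* Variables outside ``signal_variables`` share the negative-group
  distribution across outcome groups; derived variables inherit signal
  status from their parents (avHR from aRR, HF_norm from LF_norm, and —
  when coupled — LF and LF/HF from LF_norm).
* Cross-variable correlation is independence by default; a Gaussian-copula
  correlation hook is available for sensitivity analyses.

An ``rr_series`` mode additionally synthesizes a 5-min RR-interval series
per patient (sinusoidal LF/HF modulation plus white noise around the
patient's drawn mean RR) and recomputes the HRV columns from those series,
so the whole pipeline can be exercised from raw tachograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hrv import HRVConfig, hrv_profile
from .rr import RRSeries

__all__ = [
    "VarSpec",
    "GeneratorConfig",
    "Cohort",
    "default_config",
    "generate_cohort",
    "generate_rr_series",
    "read_cohort",
]


@dataclass
class VarSpec:
    """Group-conditional location/scale for one variable.

    ``neg``/``pos`` are (mean, sd) for the no-MACE and MACE groups; ``lo``
    and ``hi`` are truncation bounds; ``kind`` 'count' rounds draws to
    integers.
    """

    neg: tuple[float, float]
    pos: tuple[float, float]
    lo: float
    hi: float
    kind: Literal["continuous", "count"] = "continuous"


# Group-conditional summaries (mean, sd) per outcome group, with
# physiological truncation bounds.  Defaults reproduce the published
# cohort's printed group statistics.
def _default_varspecs() -> dict[str, VarSpec]:
    return {
        "temperature": VarSpec((36.4, 0.6), (36.4, 0.5), 34.0, 41.0),
        "pulse_rate": VarSpec((79.0, 17.0), (86.0, 15.0), 30.0, 200.0),
        "resp_rate": VarSpec((18.0, 3.0), (20.0, 5.0), 6.0, 50.0),
        "SBP": VarSpec((142.0, 28.0), (124.0, 31.0), 60.0, 260.0),
        "DBP": VarSpec((77.0, 15.0), (67.0, 17.0), 30.0, 160.0),
        "SpO2": VarSpec((98.0, 4.0), (97.0, 4.0), 70.0, 100.0),
        "aRR": VarSpec((0.831, 0.171), (0.723, 0.139), 0.35, 1.9),
        "STD": VarSpec((0.038, 0.028), (0.034, 0.020), 0.002, 0.30),
        # avHR is derived from aRR; these are its calibration targets
        "avHR": VarSpec((75.545, 15.862), (86.122, 15.927), 30.0, 200.0),
        "sdHR": VarSpec((3.618, 2.735), (4.328, 2.886), 0.1, 30.0),
        # positive-group RMSSD sd taken as 0.0307 s (a printed 0.307 would
        # exceed any plausible 5-min RMSSD by an order of magnitude)
        "RMSSD": VarSpec((0.037, 0.039), (0.039, 0.0307), 0.002, 0.40),
        "pNN50": VarSpec((7.294, 12.617), (7.978, 9.695), 0.0, 100.0),
        "NN50": VarSpec((23.0, 41.0), (31.0, 44.0), 0.0, 400.0, kind="count"),
        "triangular_index": VarSpec((3.009, 1.233), (2.481, 0.969), 1.0, 20.0),
        "TINN": VarSpec((0.134, 0.086), (0.105, 0.069), 0.0, 0.80),
        "LF": VarSpec((0.128, 0.074), (0.106, 0.092), 0.002, 2.0),
        "HF": VarSpec((0.125, 0.075), (0.139, 0.080), 0.002, 2.0),
        "LF_HF": VarSpec((1.641, 1.869), (1.018, 0.910), 0.05, 20.0),
        "total_power": VarSpec((0.489, 0.110), (0.434, 0.177), 0.01, 5.0),
        "LF_norm": VarSpec((51.173, 20.535), (40.947, 22.966), 1.0, 99.0),
        "age": VarSpec((60.6, 13.0), (61.0, 11.6), 30.0, 100.0),
    }


#: drawn variables whose group distributions may differ (parents of derived
#: variables stand in for them)
_DERIVED_PARENT = {
    "avHR": "aRR",
    "HF_norm": "LF_norm",
    "LF_HF": "LF_norm",
    "LF": "LF_norm",
}

#: the 23 candidate predictors: 8 clinical signs + 15 HRV parameters
FEATURES = [
    "GCS", "temperature", "pulse_rate", "resp_rate", "SBP", "DBP", "SpO2",
    "pain",
    "aRR", "STD", "avHR", "sdHR", "RMSSD", "pNN50", "NN50",
    "triangular_index", "TINN", "LF", "HF", "total_power",
    "LF_norm", "HF_norm", "LF_HF",
]

#: variables separating the outcome groups in the reference cohort
#: (group-wise p < 0.05)
DEFAULT_SIGNAL = [
    "GCS", "pulse_rate", "resp_rate", "SBP", "DBP",
    "aRR", "avHR", "triangular_index", "LF", "LF_norm", "HF_norm", "LF_HF",
]

# GCS levels and per-group probabilities (medians 15 in both groups, heavier
# sub-15 tail among MACE patients)
_GCS_LEVELS = np.array([15, 14, 13, 12, 10, 8])
_GCS_P_NEG = np.array([0.960, 0.020, 0.010, 0.005, 0.0035, 0.0015])
_GCS_P_POS = np.array([0.850, 0.070, 0.040, 0.020, 0.015, 0.005])

# pain score 0-10, shared across groups (group difference not significant)
_PAIN_LOC, _PAIN_SD = 2.5, 2.5

# exact per-group counts at reference group sizes (673 negatives, 29
# positives); scaled proportionally for other cohort sizes
_REF_N = {"neg": 673, "pos": 29}
_COUNT_FLAGS = {
    "male": (445, 18),
    "hx_ihd": (292, 10),
    "hx_diabetes": (241, 13),
    "hx_hypertension": (432, 17),
    "hx_dyslipidemia": (403, 13),
    "hx_stroke": (50, 3),
    "hx_cancer": (28, 1),
    "hx_renal_failure": (79, 9),
    "hx_chf": (37, 3),
    "hx_respiratory": (18, 0),
    "hx_mi": (96, 6),
    "hx_pci": (149, 4),
    "hx_cabg": (62, 1),
}
_RACE_COUNTS = {  # (neg, pos)
    "Chinese": (434, 20), "Malay": (132, 6), "Indian": (89, 2), "Others": (18, 1),
}
# MACE subtype counts among the 29 positives (overlapping composite)
_MACE_SUBTYPES = {
    "mace_death": 9, "mace_cardiac_arrest": 10, "mace_vt": 8,
    "mace_hypotension": 16,
}

_TIMI_ITEMS = [
    "timi_age65", "timi_risk_factors", "timi_known_cad", "timi_aspirin",
    "timi_angina", "timi_st_deviation", "timi_markers",
]
_TIMI_RATES = {  # per-item Bernoulli rates; medians land near 2-3 points
    "neg": [0.40, 0.25, 0.30, 0.45, 0.25, 0.15, 0.20],
    "pos": [0.45, 0.35, 0.40, 0.50, 0.35, 0.30, 0.35],
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    The defaults reproduce the reference cohort's composition: 702 patients,
    29 positives, group-conditional summaries as tabulated.
    """

    n_total: int = 702
    n_positive: int = 29
    variables: dict[str, VarSpec] = field(default_factory=_default_varspecs)
    signal_variables: list[str] = field(default_factory=lambda: list(DEFAULT_SIGNAL))
    mode: Literal["feature_table", "rr_series"] = "feature_table"
    duration_s: float = 300.0
    correlation: pd.DataFrame | None = None  # Gaussian-copula hook
    avHR_jitter: float = 0.02
    #: enforce LF = HF * LF_norm / HF_norm so that LF/HF = LF_norm/HF_norm
    #: exactly; when False, LF and LF/HF are drawn from their own
    #: group-conditional summaries (marginals match the reference table but
    #: the ratio identity holds only in distributional tendency)
    couple_spectral: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n_positive < self.n_total):
            raise ValueError("need 0 < n_positive < n_total")
        universe = set(self.variables) | set(_DERIVED_PARENT) | {"GCS", "pain"}
        unknown = set(self.signal_variables) - universe
        if unknown:
            raise ValueError(f"unknown signal variables: {sorted(unknown)}")
        for name, spec in self.variables.items():
            if spec.neg[1] < 0 or spec.pos[1] < 0:
                raise ValueError(f"{name}: scales must be non-negative")
            if spec.lo >= spec.hi:
                raise ValueError(f"{name}: inconsistent truncation bounds")


def default_config(**overrides) -> GeneratorConfig:
    """The reference-cohort configuration (702 patients, 29 positives)."""
    return GeneratorConfig(**overrides)


@dataclass
class Cohort:
    """A generated cohort: one row per patient plus provenance.

    ``frame`` carries the 23 candidate predictors, demographics, TIMI item
    flags and the 0/1 ``outcome`` column, indexed by patient id.
    """

    frame: pd.DataFrame
    config: GeneratorConfig
    seed: int | None
    rr_series: dict[str, RRSeries] | None = None

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[FEATURES]

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy()

    @property
    def n_positive(self) -> int:
        return int(self.frame["outcome"].sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _calibrated_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location such that the [lo, hi]-truncated normal has mean ``target``."""
    if sd == 0:
        return target

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    lo_b, hi_b = target - 6 * sd, target + 6 * sd
    try:
        return float(optimize.brentq(f, lo_b, hi_b))
    except ValueError:  # target unreachable within bracket; fall back
        return target


def _trunc_draw(rng, mean, sd, lo, hi, size, u=None):
    """Truncated-normal draws with mean-preserving recentring.

    If ``u`` (uniforms from the copula hook) is given, invert the CDF.
    """
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    loc = _calibrated_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    if u is not None:
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _mean_inverse(mean, sd, lo, hi) -> float:
    """E[1/X] for the mean-calibrated truncated normal (numerical)."""
    loc = _calibrated_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    x = np.linspace(lo, hi, 4001)
    pdf = stats.truncnorm.pdf(x, a, b, loc=loc, scale=sd)
    return float(np.trapezoid(pdf / x, x))


def _exact_count_flags(rng, n, ref_count, ref_n) -> np.ndarray:
    """0/1 vector with an exact (proportionally scaled) number of ones."""
    k = int(round(ref_count * n / ref_n))
    flags = np.zeros(n, dtype=int)
    flags[: min(k, n)] = 1
    rng.shuffle(flags)
    return flags


def _draw_group(rng, cfg: GeneratorConfig, group: str, n: int) -> pd.DataFrame:
    """Draw all per-patient variables for one outcome group."""
    signal = set(cfg.signal_variables)
    derived_map = (
        _DERIVED_PARENT if cfg.couple_spectral else {"avHR": "aRR", "HF_norm": "LF_norm"}
    )
    for derived, parent in derived_map.items():
        if derived in signal:
            signal.add(parent)

    def params(name):
        spec = cfg.variables[name]
        return spec.pos if (group == "pos" and name in signal) else spec.neg

    out = {}
    skip = ("avHR", "LF", "LF_HF") if cfg.couple_spectral else ("avHR",)
    drawn = [v for v in cfg.variables if v not in skip]
    # optional Gaussian copula across the drawn continuous variables
    u_cols = {}
    if cfg.correlation is not None:
        corr = cfg.correlation
        z = rng.multivariate_normal(np.zeros(len(corr)), corr.to_numpy(), size=n)
        u = stats.norm.cdf(z)
        u_cols = {v: u[:, i] for i, v in enumerate(corr.columns)}
    for name in drawn:
        spec = cfg.variables[name]
        mean, sd = params(name)
        vals = _trunc_draw(rng, mean, sd, spec.lo, spec.hi, n, u_cols.get(name))
        if spec.kind == "count":
            vals = np.round(vals).clip(spec.lo, spec.hi)
        out[name] = vals

    # avHR derived from aRR: mean instantaneous HR tracks 60/aRR up to a
    # calibration factor absorbing the Jensen gap and targeting the
    # configured group mean
    arr_mean, arr_sd = params("aRR")
    arr_spec = cfg.variables["aRR"]
    target_avhr = params("avHR")[0]
    e_inv = _mean_inverse(arr_mean, arr_sd, arr_spec.lo, arr_spec.hi)
    c = target_avhr / (60.0 * e_inv)
    jitter = 1.0 + cfg.avHR_jitter * rng.standard_normal(n)
    out["avHR"] = np.clip((60.0 / out["aRR"]) * c * jitter, 30.0, 200.0)

    # spectral identities: normalized units partition 100; when coupled,
    # the LF power is made consistent with the drawn HF power and LF_norm
    # so that LF/HF = LF_norm/HF_norm holds exactly
    out["HF_norm"] = 100.0 - out["LF_norm"]
    if cfg.couple_spectral:
        out["LF"] = out["HF"] * out["LF_norm"] / out["HF_norm"]
        out["LF_HF"] = out["LF"] / out["HF"]

    # discrete clinical variables
    gcs_p = _GCS_P_POS if (group == "pos" and "GCS" in signal) else _GCS_P_NEG
    out["GCS"] = rng.choice(_GCS_LEVELS, size=n, p=gcs_p / gcs_p.sum())
    out["pain"] = np.round(
        _trunc_draw(rng, _PAIN_LOC, _PAIN_SD, -0.49, 10.49, n)
    ).clip(0, 10)

    # demographics / history / TIMI items with exact scaled counts
    ref_n = _REF_N[group]
    gi = 0 if group == "neg" else 1
    for flag, counts in _COUNT_FLAGS.items():
        out[flag] = _exact_count_flags(rng, n, counts[gi], ref_n)
    race = np.concatenate(
        [
            np.full(int(round(c[gi] * n / ref_n)), r)
            for r, c in _RACE_COUNTS.items()
        ]
    )
    race = np.concatenate([race, np.full(max(n - len(race), 0), "Chinese")])[:n]
    rng.shuffle(race)
    out["race"] = race
    for i, item in enumerate(_TIMI_ITEMS):
        out[item] = (rng.random(n) < _TIMI_RATES[group][i]).astype(int)
    if group == "pos":
        for flag, count in _MACE_SUBTYPES.items():
            out[flag] = _exact_count_flags(rng, n, count, _REF_N["pos"])
    else:
        for flag in _MACE_SUBTYPES:
            out[flag] = np.zeros(n, dtype=int)
    out["outcome"] = np.full(n, gi)
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a cohort with exactly ``n_positive`` MACE patients.

    Deterministic given ``seed`` (falls back to ``config.seed``).
    """
    cfg = config or default_config()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_pos = cfg.n_positive
    n_neg = cfg.n_total - n_pos
    neg = _draw_group(rng, cfg, "neg", n_neg)
    pos = _draw_group(rng, cfg, "pos", n_pos)
    frame = pd.concat([neg, pos], ignore_index=True)
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    frame.index = [f"P{i:04d}" for i in range(len(frame))]
    frame.index.name = "patient_id"
    cohort = Cohort(frame=frame, config=cfg, seed=seed)
    if cfg.mode == "rr_series":
        _attach_rr_series(cohort, rng)
    return cohort


def _attach_rr_series(cohort: Cohort, rng: np.random.Generator) -> None:
    """Synthesize per-patient tachograms and recompute HRV columns."""
    series: dict[str, RRSeries] = {}
    hrv_cfg = HRVConfig()
    rows = {}
    for pid, row in cohort.frame.iterrows():
        std = float(row["STD"])
        lf_frac = float(row["LF_norm"]) / 100.0
        mod_var = 0.8 * std**2
        s = generate_rr_series(
            mean_rr=float(row["aRR"]),
            lf_amp=np.sqrt(2.0 * mod_var * lf_frac),
            hf_amp=np.sqrt(2.0 * mod_var * (1.0 - lf_frac)),
            noise_sd=np.sqrt(0.2) * std,
            duration_s=cohort.config.duration_s,
            rng=rng,
        )
        series[pid] = s
        prof = hrv_profile(s, hrv_cfg)
        rows[pid] = {
            k: getattr(prof, k)
            for k in (
                "aRR", "STD", "avHR", "sdHR", "RMSSD", "pNN50", "NN50",
                "triangular_index", "TINN", "LF", "HF", "total_power",
                "LF_norm", "HF_norm", "LF_HF",
            )
        }
    hrv_frame = pd.DataFrame.from_dict(rows, orient="index")
    cohort.frame.loc[hrv_frame.index, hrv_frame.columns] = hrv_frame
    cohort.rr_series = series


def generate_rr_series(
    mean_rr: float,
    lf_amp: float = 0.0,
    hf_amp: float = 0.0,
    noise_sd: float = 0.0,
    duration_s: float = 300.0,
    f_lf: float = 0.10,
    f_hf: float = 0.25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RRSeries:
    """Synthesize a tachogram: sinusoidal LF/HF modulation plus white noise.

    RR_i = mu + a_LF sin(2 pi f_LF t_i) + a_HF sin(2 pi f_HF t_i) + eps_i,
    evaluated at the (self-consistent) beat times, truncated positive, until
    the cumulative duration reaches ``duration_s``.
    """
    if mean_rr <= 0 or duration_s <= 0:
        raise ValueError("mean_rr and duration_s must be positive")
    if noise_sd >= mean_rr:
        raise ValueError("noise_sd must be smaller than the mean RR interval")
    if rng is None:
        rng = np.random.default_rng(seed)
    floor = max(0.1, 0.2 * mean_rr)
    intervals = []
    t = 0.0
    while t < duration_s:
        rr = (
            mean_rr
            + lf_amp * np.sin(2 * np.pi * f_lf * t)
            + hf_amp * np.sin(2 * np.pi * f_hf * t)
            + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        )
        rr = max(rr, floor)
        intervals.append(rr)
        t += rr
    return RRSeries(np.asarray(intervals))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort feature table written by :meth:`Cohort.to_csv`."""
    return pd.read_csv(path, index_col="patient_id")
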