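"""Short-recording heart rate variability (HRV) parameters.

Computes the classical 5-minute HRV panel from an RR-interval series:

* time domain — mean/SD of RR and instantaneous heart rate, RMSSD, NN50,
  pNN50;
* geometric domain — triangular index and TINN from the RR histogram;
* frequency domain — VLF / LF / HF band powers, normalized LF/HF units and
  the LF/HF ratio, from a Lomb-Scargle periodogram of the unevenly sampled
  tachogram (or, alternatively, cubic resampling + Welch).

Band conventions follow the short-recording standards: VLF 0.003-0.04 Hz,
LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.  Powers are reported in s^2 (the intervals
are in seconds); normalized units are invariant to this choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

from .rr import RRSeries, filter_rr

__all__ = [
    "HRVConfig",
    "HRVProfile",
    "time_domain",
    "geometric_domain",
    "frequency_domain",
    "hrv_profile",
    "profiles_to_frame",
]

#: (low, high) band edges in Hz
DEFAULT_BANDS = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.40)}

NN50_THRESHOLD_S = 0.050


@dataclass(frozen=True)
class HRVConfig:
    """Knobs for the HRV computation.

    bin_width: RR histogram bin width in seconds (1/128 s by convention).
    method: spectral estimator for the tachogram.
    bands: band edges in Hz.
    resample_hz: resampling rate for the Welch route.
    """

    bin_width: float = 1.0 / 128.0
    method: Literal["lomb_scargle", "resample_welch"] = "lomb_scargle"
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    resample_hz: float = 4.0
    filter_min_s: float = 0.3
    filter_max_s: float = 2.0
    filter_max_rel_jump: float = 0.2


@dataclass
class HRVProfile:
    """The standard short-recording HRV panel for one patient.

    Frequency-domain fields are NaN when undefined (e.g. a constant series
    has zero spectral power, so normalized units do not exist).
    """

    aRR: float
    STD: float
    avHR: float
    sdHR: float
    RMSSD: float
    NN50: int
    pNN50: float
    triangular_index: float
    TINN: float
    VLF: float
    LF: float
    HF: float
    total_power: float
    LF_norm: float
    HF_norm: float
    LF_HF: float

    #: the 15 tabulated parameters, in conventional order
    PARAMS = (
        "aRR", "STD", "avHR", "sdHR", "RMSSD", "NN50", "pNN50",
        "triangular_index", "TINN", "LF", "HF", "total_power",
        "LF_norm", "HF_norm", "LF_HF",
    )

    def as_dict(self) -> dict:
        return asdict(self)


def time_domain(series: RRSeries) -> dict:
    """Time-domain statistics of the RR series.

    Instantaneous heart rate is 60/RR_i (beats/min).  NN50 counts successive
    interval pairs differing by more than 50 ms; pNN50 expresses it as a
    percentage of the ``n - 1`` successive pairs.  Standard deviations are
    population SDs (ddof=0), matching the usual HRV software convention.
    """
    rr = series.intervals
    hr = 60.0 / rr
    diffs = np.diff(rr)
    nn50 = int(np.sum(np.abs(diffs) > NN50_THRESHOLD_S))
    return {
        "aRR": float(rr.mean()),
        "STD": float(rr.std()),
        "avHR": float(hr.mean()),
        "sdHR": float(hr.std()),
        "RMSSD": float(np.sqrt(np.mean(diffs**2))),
        "NN50": nn50,
        "pNN50": 100.0 * nn50 / (len(rr) - 1),
    }


def _rr_histogram(rr: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram with edges aligned to multiples of bin_width."""
    lo = math.floor(rr.min() / bin_width) * bin_width
    hi = math.ceil(rr.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    counts, _ = np.histogram(rr, bins=edges)
    return counts.astype(float), edges


def _tinn_search(counts: np.ndarray, edges: np.ndarray, pad_bins: int = 8):
    """Exhaustive least-squares triangular fit to the RR histogram.

    The triangle is zero outside [N', M], rises linearly to the histogram
    peak (mode-bin center, modal count) and falls back to zero; (N', M) run
    over a grid of bin-edge positions padded beyond the histogram support.
    Returns (TINN, N', M).
    """
    bw = edges[1] - edges[0]
    centers = (edges[:-1] + edges[1:]) / 2.0
    k = int(np.argmax(counts))
    x0, y0 = centers[k], counts[k]
    left = edges[0] - pad_bins * bw + bw * np.arange(pad_bins + k + 1)
    left = left[left < x0]
    right = edges[k + 1] + bw * np.arange(len(centers) - k + pad_bins)
    right = right[right > x0]
    best = (np.inf, x0, x0)
    for n_ in left:
        up = np.where(
            (centers > n_) & (centers <= x0), y0 * (centers - n_) / (x0 - n_), 0.0
        )
        for m in right:
            down = np.where(
                (centers > x0) & (centers < m), y0 * (m - centers) / (m - x0), 0.0
            )
            tri = np.where(centers <= x0, up, down)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0] - 1e-12:
                best = (err, n_, m)
    _, n_, m = best
    return float(m - n_), float(n_), float(m)


def geometric_domain(series: RRSeries, bin_width: float = 1.0 / 128.0) -> dict:
    """Histogram-based (geometric) HRV measures.

    triangular_index = N / (modal bin count); TINN is the base width of the
    least-squares triangular interpolation of the histogram.  A degenerate
    single-bin histogram yields TINN = 0 by convention.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rr = series.intervals
    counts, edges = _rr_histogram(rr, bin_width)
    tri_index = len(rr) / counts.max()
    if np.count_nonzero(counts) <= 1:
        return {"triangular_index": float(tri_index), "TINN": 0.0}
    tinn, _, _ = _tinn_search(counts, edges)
    return {"triangular_index": float(tri_index), "TINN": tinn}


def _band_powers_from_psd(freqs, psd, bands):
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0
    return out


def frequency_domain(
    series: RRSeries,
    method: str = "lomb_scargle",
    bands: dict | None = None,
    resample_hz: float = 4.0,
) -> dict:
    """Spectral band powers of the tachogram and their normalized units.

    The tachogram RR(t) is treated as an unevenly sampled signal at the beat
    times.  The default estimator is the Lomb-Scargle periodogram, which
    avoids the low-pass bias of interpolation; the alternative resamples the
    tachogram with a cubic spline at ``resample_hz`` and applies Welch.
    Total power is the sum of the three band powers, so
    LF_norm + HF_norm = 100 holds by construction whenever the denominator
    ``total_power - VLF`` is positive.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    rr = series.intervals
    if len(rr) < 16:
        raise ValueError("frequency-domain analysis needs at least 16 intervals")
    if series.duration < 60.0:
        raise ValueError("frequency-domain analysis needs at least 60 s of data")
    t = series.times
    x = rr - rr.mean()
    f_lo = min(lo for lo, _ in bands.values())
    f_hi = max(hi for _, hi in bands.values())
    if method == "lomb_scargle":
        T = t[-1] - t[0]
        df = 1.0 / (4.0 * T)  # 4x oversampled frequency grid
        freqs = np.arange(max(f_lo, df), f_hi + df, df)
        pgram = lombscargle(t, x, 2.0 * np.pi * freqs)
        # scale to a one-sided density (s^2/Hz): a sinusoid of amplitude a
        # gives a peak ~ n a^2/4 of width ~ 1/T, so density = pgram * 2T/n
        psd = pgram * 2.0 * T / len(rr)
    elif method == "resample_welch":
        fs = resample_hz
        tg = np.arange(t[0], t[-1], 1.0 / fs)
        xs = CubicSpline(t, x)(tg)
        nperseg = min(len(tg), 256 * int(fs))
        freqs, psd = welch(xs, fs=fs, nperseg=nperseg, detrend="constant")
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    bp = _band_powers_from_psd(freqs, psd, bands)
    vlf, lf, hf = bp["VLF"], bp["LF"], bp["HF"]
    total = vlf + lf + hf
    out = {"VLF": vlf, "LF": lf, "HF": hf, "total_power": total}
    denom = total - vlf
    if denom <= 0 or hf == 0:
        out.update({"LF_norm": np.nan, "HF_norm": np.nan, "LF_HF": np.nan})
    else:
        out.update(
            {
                "LF_norm": 100.0 * lf / denom,
                "HF_norm": 100.0 * hf / denom,
                "LF_HF": lf / hf,
            }
        )
    return out


def hrv_profile(
    series: RRSeries, config: HRVConfig | None = None, prefiltered: bool = False
) -> HRVProfile:
    """Assemble the full HRV panel for one recording.

    Applies the artifact filter first (unless ``prefiltered``), then the
    three domain computations.  Frequency-domain parameters that cannot be
    computed (too few beats, too short, or zero variability) are NaN rather
    than an error, so a profile is always produced for a usable recording.
    """
    config = config or HRVConfig()
    if not prefiltered:
        series, _ = filter_rr(
            series, config.filter_min_s, config.filter_max_s, config.filter_max_rel_jump
        )
    vals = time_domain(series)
    vals.update(geometric_domain(series, config.bin_width))
    try:
        vals.update(
            frequency_domain(series, config.method, config.bands, config.resample_hz)
        )
    except ValueError:
        vals.update(
            {k: np.nan for k in ("VLF", "LF", "HF", "total_power", "LF_norm", "HF_norm", "LF_HF")}
        )
    return HRVProfile(**vals)


def profiles_to_frame(profiles: dict[str, HRVProfile]) -> pd.DataFrame:
    """One row per patient, columns in the conventional tabulated order."""
    rows = {pid: {k: getattr(p, k) for k in HRVProfile.PARAMS} for pid, p in profiles.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
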