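"""Time-series measures: autocorrelation, period detection, Δp, diagnostics.

The period of an oscillator is read off its normalized autocorrelation
R(k): the period is τ = k̃·Δt where k̃ is the smallest lag at which R has a
strict local maximum exceeding a threshold (0.7 by default).  With the
series mean-centered and the normalization by the lag-0 term, R(0) = 1 and
a clean oscillator's first peak sits at one period.

Synchronization of the three oscillators is summarized by

    Δp = Σ_{i>j} (τ_i − τ_j)²

over the three unordered pairs; Δp = 0 means full period synchronization.
Periods are measured on the first mRNA species (j = 1) of each repressilator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal

from .simulate import Trajectory

__all__ = [
    "AutocorrResult",
    "PeriodEstimate",
    "SyncResult",
    "autocorrelation",
    "detect_period",
    "delta_p",
    "measure_sync",
    "phase_lag",
    "power_spectrum",
    "spectral_peaks",
    "write_sync_report",
]


@dataclass
class AutocorrResult:
    """Normalized autocorrelation values at lags 0..max_lag."""

    lags: np.ndarray
    values: np.ndarray
    dt: float


@dataclass(frozen=True)
class PeriodEstimate:
    """Detected period τ = lag_index·dt, or an explicit undetected marker."""

    period: Optional[float]
    lag_index: Optional[int]
    peak_value: Optional[float]

    @property
    def detected(self) -> bool:
        return self.period is not None

    @classmethod
    def undetected(cls) -> "PeriodEstimate":
        return cls(period=None, lag_index=None, peak_value=None)


@dataclass
class SyncResult:
    """Per-repressilator periods plus the Δp synchronization statistic."""

    periods: tuple[PeriodEstimate, PeriodEstimate, PeriodEstimate]
    delta_p: Optional[float]
    n_undetected: int


def autocorrelation(series: np.ndarray, max_lag: Optional[int] = None) -> AutocorrResult:
    """Normalized autocorrelation of a uniformly sampled scalar series.

    The series is mean-centered; the lag-k product sum is truncated to the
    overlapping samples (l = 0..N−1−k) and normalized by the lag-0 term, so
    R(0) = 1 exactly.  ``max_lag`` defaults to floor(N/2) so at least two
    cycles support every reportable peak.

    Raises
    ------
    ValueError
        On a constant series (zero variance: autocorrelation undefined).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be a 1-D array of length >= 2")
    n = len(x)
    if max_lag is None:
        max_lag = n // 2
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be < series length {n}")
    xbar = x - x.mean()
    # FFT autocovariance; zero-padding makes the circular product equal the
    # truncated linear sum. A brute-force O(N^2) oracle pins this in tests.
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xbar, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    if acov[0] <= 0 or not np.isfinite(acov[0]) or np.allclose(xbar, 0.0):
        raise ValueError("undefined autocorrelation: series is constant")
    values = acov / acov[0]
    return AutocorrResult(lags=np.arange(max_lag + 1), values=values, dt=1.0)


def autocorrelation_of(series: np.ndarray, dt: float,
                       max_lag: Optional[int] = None) -> AutocorrResult:
    """:func:`autocorrelation` with the sampling interval attached."""
    res = autocorrelation(series, max_lag=max_lag)
    res.dt = float(dt)
    return res


def detect_period(acorr: AutocorrResult, threshold: float = 0.7) -> PeriodEstimate:
    """First strict local autocorrelation maximum above ``threshold``.

    Returns the period τ = k̃·Δt where k̃ is the minimum k ≥ 1 with
    R(k) > R(k−1), R(k) > R(k+1) and R(k) > threshold; comparisons are
    strict, so plateaus do not qualify.  If no such lag exists within the
    computed range, the period is reported as undetected.
    """
    r = acorr.values
    if len(r) < 3:
        return PeriodEstimate.undetected()
    interior = r[1:-1]
    is_peak = (interior > r[:-2]) & (interior > r[2:]) & (interior > threshold)
    idx = np.flatnonzero(is_peak)
    if len(idx) == 0:
        return PeriodEstimate.undetected()
    k = int(idx[0]) + 1
    return PeriodEstimate(period=k * acorr.dt, lag_index=k, peak_value=float(r[k]))


def delta_p(periods: Sequence[float]) -> float:
    """Sum of squared pairwise period differences over the three pairs.

    Raises
    ------
    ValueError
        If any period is missing/undetected (Δp undefined); the caller
        decides the aggregation policy.
    """
    vals = []
    for tau in periods:
        if isinstance(tau, PeriodEstimate):
            if not tau.detected:
                raise ValueError("delta_p undefined: undetected period")
            vals.append(tau.period)
        else:
            if tau is None or not np.isfinite(tau):
                raise ValueError("delta_p undefined: undetected period")
            vals.append(float(tau))
    if len(vals) != 3:
        raise ValueError(f"delta_p needs exactly 3 periods, got {len(vals)}")
    t1, t2, t3 = vals
    return (t2 - t1) ** 2 + (t3 - t1) ** 2 + (t3 - t2) ** 2


def measure_sync(traj: Trajectory, threshold: float = 0.7,
                 species: int = 0) -> SyncResult:
    """Periods of the three repressilators (mRNA of one species) and Δp.

    ``species`` selects which cycle element is measured; the first (j = 1,
    index 0) by default.  Replicates in which an oscillator's period cannot
    be detected yield ``delta_p=None`` with ``n_undetected`` counting them.
    """
    estimates = []
    for i in range(3):
        x = traj.mrna(i, species)
        try:
            ac = autocorrelation_of(x, traj.dt)
            est = detect_period(ac, threshold=threshold)
        except ValueError:  # constant series: no oscillation at all
            est = PeriodEstimate.undetected()
        estimates.append(est)
    n_undet = sum(not e.detected for e in estimates)
    dp = delta_p(estimates) if n_undet == 0 else None
    return SyncResult(periods=tuple(estimates), delta_p=dp, n_undetected=n_undet)


def phase_lag(series_a: np.ndarray, series_b: np.ndarray, dt: float) -> float:
    """Lag of ``series_b`` relative to ``series_a`` (time units).

    Maximizes the normalized cross-correlation over lags restricted to half
    the dominant period of ``series_a`` in magnitude; positive means ``b``
    is delayed relative to ``a``.  Returns 0 for identical series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("phase lag undefined for a constant series")
    ac = autocorrelation_of(a, dt)
    est = detect_period(ac)
    if est.detected:
        period = est.period
    else:  # fall back on the dominant spectral peak
        freqs, power = power_spectrum(a, dt)
        fpeak = freqs[1:][np.argmax(power[1:])]
        period = 1.0 / fpeak
    max_shift = max(1, int(round(0.5 * period / dt)))
    abar = a - a.mean()
    bbar = b - b.mean()
    full = signal.correlate(bbar, abar, mode="full")  # index n-1+L ~ lag L
    mid = len(a) - 1
    lo, hi = mid - max_shift, mid + max_shift + 1
    window = full[lo:hi]
    lag = int(np.argmax(window)) - max_shift
    return lag * dt


def power_spectrum(series: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (frequency, power) of a mean-removed series."""
    x = np.asarray(series, dtype=float)
    freqs, power = signal.periodogram(x, fs=1.0 / dt, detrend="constant")
    return freqs, power


def spectral_peaks(freqs: np.ndarray, power: np.ndarray, q: int = 3) -> list[tuple[float, float]]:
    """Top-``q`` local spectral maxima as (frequency, power), power-sorted."""
    idx, _ = signal.find_peaks(power)
    top = idx[np.argsort(power[idx])[::-1][:q]]
    return [(float(freqs[i]), float(power[i])) for i in top]


def write_autocorrelation_csv(acorr: AutocorrResult, path: Union[str, Path]) -> None:
    """CSV of the autocorrelation curve: lag index, lag time, R."""
    import pandas as pd

    pd.DataFrame({
        "lag": acorr.lags,
        "lag_time": acorr.lags * acorr.dt,
        "autocorrelation": acorr.values,
    }).to_csv(path, index=False)


def write_spectrum_csv(freqs: np.ndarray, power: np.ndarray,
                       path: Union[str, Path]) -> None:
    """CSV of a periodogram: frequency, power."""
    import pandas as pd

    pd.DataFrame({"frequency": freqs, "power": power}).to_csv(path, index=False)


def write_sync_report(result: SyncResult, path: Union[str, Path]) -> None:
    """JSON report: per-repressilator period, lag index, peak value, Δp."""
    payload = {
        "periods": [
            {
                "repressilator": i + 1,
                "detected": est.detected,
                "period": est.period,
                "lag_index": est.lag_index,
                "peak_value": est.peak_value,
            }
            for i, est in enumerate(result.periods)
        ],
        "delta_p": result.delta_p,
        "n_undetected": result.n_undetected,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
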