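"""Software multi-tau autocorrelator for FCS photon traces.

Emulates the quasi-logarithmic lag structure of commercial hardware
correlators: the first stage correlates the raw bins at lags 1..m; every
subsequent stage halves the time resolution (averaging pairs of bins) and
adds lags m/2+1..m in coarsened units.  Normalization is symmetric: each
lag uses the means of the actually overlapping direct and delayed windows,
G(τ) = <F(t)·F(t+τ)> / (<F>_direct·<F>_delayed) − 1, which suppresses bias
from slow intensity drifts.  The zero-lag (shot-noise) channel is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import IntensityTrace

__all__ = ["FCSCurve", "autocorrelate", "write_curve_csv", "read_curve_csv"]


@dataclass
class FCSCurve:
    """Normalized autocorrelation G(τ) on a quasi-logarithmic lag grid."""

    lags: np.ndarray          # s, strictly increasing
    g: np.ndarray             # dimensionless
    n_samples_per_lag: np.ndarray  # products averaged at each lag
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.n_samples_per_lag = np.asarray(self.n_samples_per_lag)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")


def _g_symmetric(trace: np.ndarray, lag_bins: int) -> tuple[float, int]:
    """Symmetrically normalized correlation of a (possibly coarsened) trace."""
    m = len(trace) - lag_bins
    direct = trace[:m]
    delayed = trace[lag_bins:]
    mu_d = direct.mean()
    mu_l = delayed.mean()
    return float(direct @ delayed) / (m * mu_d * mu_l) - 1.0, m


def autocorrelate(trace: IntensityTrace, channels_per_stage: int = 16,
                  n_stages: int | None = None) -> FCSCurve:
    """Multi-tau autocorrelation of an intensity trace.

    Parameters
    ----------
    trace : IntensityTrace
        Binned photon counts.
    channels_per_stage : int
        Lag channels in the first stage (classic layout: 16); later stages
        contribute ``channels_per_stage // 2`` new lags each.
    n_stages : int, optional
        Number of coarsening stages after the first.  Default: enough that
        the largest lag reaches at least 10% of the trace duration, capped
        so every lag still averages >= 10 products.
    """
    counts = np.asarray(trace.counts, dtype=float)
    m = channels_per_stage
    if len(counts) < 2 * m:
        raise ValueError(f"trace too short: need at least {2 * m} bins")
    if counts.mean() == 0:
        raise ValueError("zero mean intensity: nothing to correlate")

    n_bins = len(counts)
    if n_stages is None:
        # largest lag = m * 2^s bins; want >= 0.1 * n_bins, but keep
        # n_bins/2^s - m*... >= 10 samples at the longest lag
        s = 0
        while m * 2 ** (s + 1) < 0.1 * n_bins:
            s += 1
        while s > 0 and n_bins // 2 ** s - m < 10:
            s -= 1
        n_stages = s

    lags_bins: list[float] = []
    gs: list[float] = []
    ns: list[int] = []

    coarse = counts
    factor = 1
    for stage in range(n_stages + 1):
        first = 1 if stage == 0 else m // 2 + 1
        for k in range(first, m + 1):
            if k >= len(coarse):
                break
            g, n = _g_symmetric(coarse, k)
            lags_bins.append(k * factor)
            gs.append(g)
            ns.append(n)
        if len(coarse) // 2 < m + 10:
            break
        coarse = 0.5 * (coarse[: len(coarse) // 2 * 2 : 2]
                        + coarse[1: len(coarse) // 2 * 2 : 2])
        factor *= 2

    lags = np.asarray(lags_bins) * trace.bin_time
    return FCSCurve(lags=lags, g=np.asarray(gs), n_samples_per_lag=np.asarray(ns),
                    meta={"bin_time": trace.bin_time, **trace.meta})


# -- curve CSV I/O --------------------------------------------------------

def write_curve_csv(curve: FCSCurve, path: str | Path) -> None:
    """Columns lag_s, g, n_samples; full float precision (exact round trip)."""
    df = pd.DataFrame({"lag_s": curve.lags, "g": curve.g,
                       "n_samples": curve.n_samples_per_lag})
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path: str | Path) -> FCSCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return FCSCurve(lags=df["lag_s"].to_numpy(), g=df["g"].to_numpy(),
                    n_samples_per_lag=df["n_samples"].to_numpy())
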