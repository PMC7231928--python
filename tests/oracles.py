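"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops / closed forms,
independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def effective_area_nm2(lateral_fwhm: float) -> float:
    """FCS effective area of a Gaussian profile exp(−4 ln2 r²/ω²).

    A_eff = (∫W)²/∫W² = π·ω²/(2 ln2); equivalently π·w0² for the e⁻²
    parameterization W = exp(−2r²/w0²) with ω = w0·√(2 ln2).
    """
    return math.pi * lateral_fwhm**2 / (2.0 * math.log(2.0))


def coarsen(counts, factor: int):
    """Average consecutive groups of ``factor`` bins (drop the remainder)."""
    counts = list(counts)
    n = len(counts) // factor
    return [sum(counts[i * factor:(i + 1) * factor]) / factor for i in range(n)]


def g_direct(counts, lag: int) -> float:
    """Symmetrically normalized correlation at one lag, explicit loops."""
    m = len(counts) - lag
    num = 0.0
    mu_d = 0.0
    mu_l = 0.0
    for t in range(m):
        num += counts[t] * counts[t + lag]
        mu_d += counts[t]
        mu_l += counts[t + lag]
    mu_d /= m
    mu_l /= m
    return num / (m * mu_d * mu_l) - 1.0


def multitau_direct(counts, bin_time: float, channels_per_stage: int = 16,
                    n_stages: int = 3):
    """Brute-force multi-tau curve: (lags_s, g) on the classic lag grid.

    Stage 0 correlates the raw bins at lags 1..m; stage s >= 1 correlates
    the trace coarsened by 2**s at lags m/2+1..m (coarse units).
    """
    m = channels_per_stage
    lags = []
    gs = []
    for stage in range(n_stages + 1):
        factor = 2 ** stage
        c = coarsen(counts, factor) if factor > 1 else list(counts)
        first = 1 if stage == 0 else m // 2 + 1
        for k in range(first, m + 1):
            lags.append(k * factor * bin_time)
            gs.append(g_direct(c, k))
    return np.array(lags), np.array(gs)


def gaussian_box_average(lateral_fwhm: float, box_side: float) -> float:
    """Box average of the lateral Gaussian profile (box >> FWHM): π·ω²/(4 ln2·L²)."""
    return math.pi * lateral_fwhm**2 / (4.0 * math.log(2.0)) / box_side**2
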