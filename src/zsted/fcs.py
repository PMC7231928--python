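"""FCS model fitting and observation-area calibration.

The fluctuation autocorrelation of freely diffusing membrane fluorophores
seen through a 2-D Gaussian observation area obeys

    G(τ) = (1/N) · (1 + T/(1−T) · exp(−τ/τ_T)) · 1/(1 + τ/τ_xy)

with N the mean number of molecules in the observation area, T the triplet
amplitude, τ_T the triplet correlation time (fixed to 5 μs by default, the
value appropriate for red-emitting STED dyes) and τ_xy the lateral transit
time.  From the transit time and the lateral FWHM ω of the observation area
the diffusion coefficient follows as D = ω² / (8 ln2 · τ_xy).

Because a free-diffusion D is the same whether measured confocally or with
STED, the STED lateral FWHM can be calibrated on a supported lipid bilayer
from the transit-time ratio, ω_s = ω_c · sqrt(τ_s/τ_c); and molecule counts
measured through differently sized areas are compared via the area-normalized
density N_norm = (N/ω²) / (N_c/ω_c²) with a confocal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .correlator import FCSCurve

__all__ = [
    "FCSModelParams",
    "FitResult",
    "CalibrationResult",
    "model_g",
    "fit_curve",
    "diffusion_coefficient",
    "calibrate_sted_fwhm",
    "normalized_density",
]

_8LN2 = 8.0 * math.log(2.0)


@dataclass(frozen=True)
class FCSModelParams:
    """Parameter set of the 2-D diffusion + triplet correlation model."""

    n_molecules: float           # N
    transit_time: float          # tau_xy, s
    triplet_amp: float = 0.0     # T
    triplet_tau: float = 5e-6    # tau_T, s

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not (0.0 <= self.triplet_amp < 1.0):
            raise ValueError("triplet_amp must lie in [0, 1)")
        if self.transit_time <= 0:
            raise ValueError("transit_time must be positive")
        if self.triplet_tau <= 0:
            raise ValueError("triplet_tau must be positive")


@dataclass
class FitResult:
    params: FCSModelParams
    stderr: dict[str, float]
    converged: bool
    residual_norm: float


@dataclass
class CalibrationResult:
    """Observation-size calibration and derived quantities for one pairing."""

    fwhm_sted: float   # omega_s, nm
    fwhm_conf: float   # omega_c, nm
    tau_sted: float    # s
    tau_conf: float    # s
    d_coeff: float     # um^2/s, from the confocal pair
    n_norm: float
    n_conf_ref: float


def model_g(params: FCSModelParams, lag) -> np.ndarray | float:
    """Evaluate the 2-D diffusion + triplet model at lag times (s)."""
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be >= 0")
    p = params
    triplet = 1.0
    if p.triplet_amp > 0:
        triplet = 1.0 + p.triplet_amp / (1.0 - p.triplet_amp) * np.exp(-lag / p.triplet_tau)
    g = (1.0 / p.n_molecules) * triplet / (1.0 + lag / p.transit_time)
    return float(g) if g.ndim == 0 else g


def fit_curve(curve: FCSCurve, fixed_triplet_tau: float = 5e-6,
              lag_window: tuple[float, float] = (2e-6, 0.5),
              fit_triplet_tau: bool = False) -> FitResult:
    """Weighted least-squares fit of the correlation model to a curve.

    τ_T is held fixed (``fit_triplet_tau=True`` releases it).  Points are
    weighted by the square root of the number of products averaged at each
    lag (σ_i ∝ 1/√n_i).  Initial guesses come from the curve itself:
    N₀ = 1/g at the first lag, τ_xy,0 = lag where g falls to half its
    initial amplitude.
    """
    sel = (curve.lags >= lag_window[0]) & (curve.lags <= lag_window[1])
    if sel.sum() < 8:
        raise ValueError("need at least 8 lags inside the fit window")
    lags = curve.lags[sel]
    g = curve.g[sel]
    nspl = np.asarray(curve.n_samples_per_lag, dtype=float)[sel]
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite correlation values in fit window")
    g0 = g[0]
    if not np.isfinite(g0) or g0 <= 0:
        raise ValueError("non-positive correlation amplitude at the first lag")

    half_idx = np.argmin(np.abs(g - g0 / 2.0))
    tau0 = float(lags[half_idx]) if g[half_idx] < g0 else float(np.median(lags))

    pars = lmfit.Parameters()
    pars.add("n_molecules", value=1.0 / g0, min=1e-12)
    pars.add("triplet_amp", value=0.05, min=0.0, max=0.9)
    pars.add("transit_time", value=max(tau0, lags[0]), min=1e-12)
    pars.add("triplet_tau", value=fixed_triplet_tau, min=1e-9,
             vary=fit_triplet_tau)

    weights = np.sqrt(nspl)

    def residual(p):
        mp = FCSModelParams(n_molecules=p["n_molecules"].value,
                            transit_time=p["transit_time"].value,
                            triplet_amp=p["triplet_amp"].value,
                            triplet_tau=p["triplet_tau"].value)
        return (model_g(mp, lags) - g) * weights

    out = lmfit.minimize(residual, pars, method="leastsq")
    v = out.params
    fitted = FCSModelParams(n_molecules=v["n_molecules"].value,
                            transit_time=v["transit_time"].value,
                            triplet_amp=v["triplet_amp"].value,
                            triplet_tau=v["triplet_tau"].value)
    stderr = {name: (v[name].stderr if v[name].stderr is not None else float("nan"))
              for name in ("n_molecules", "triplet_amp", "transit_time", "triplet_tau")}
    return FitResult(params=fitted, stderr=stderr, converged=bool(out.success),
                     residual_norm=float(np.sqrt(np.mean(out.residual**2))))


def diffusion_coefficient(transit_time: float, lateral_fwhm: float) -> float:
    """Diffusion coefficient D = ω²/(8 ln2 · τ) in μm²/s (ω in nm, τ in s)."""
    if transit_time <= 0 or lateral_fwhm <= 0:
        raise ValueError("transit_time and lateral_fwhm must be positive")
    d_nm2_per_s = lateral_fwhm**2 / (_8LN2 * transit_time)
    return d_nm2_per_s * 1e-6


def calibrate_sted_fwhm(tau_sted: float, tau_conf: float, fwhm_conf: float) -> float:
    """STED lateral FWHM from the SLB transit-time ratio: ω_s = ω_c·√(τ_s/τ_c).

    Valid under free diffusion, where the confocal and STED recordings share
    one diffusion coefficient and the transit time scales with the area.
    """
    if tau_sted <= 0 or tau_conf <= 0 or fwhm_conf <= 0:
        raise ValueError("transit times and fwhm_conf must be positive")
    return fwhm_conf * math.sqrt(tau_sted / tau_conf)


def normalized_density(n: float, fwhm: float, n_conf_ref: float,
                       fwhm_conf: float) -> float:
    """Area-normalized molecule density N_norm = (N/ω²)/(N_c/ω_c²).

    The confocal reference (n_conf_ref, fwhm_conf) should come from the same
    cell or sample as the measurement being normalized; choosing it is the
    caller's responsibility.
    """
    if min(n, fwhm, n_conf_ref, fwhm_conf) <= 0:
        raise ValueError("all inputs must be positive")
    return (n / fwhm**2) / (n_conf_ref / fwhm_conf**2)
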