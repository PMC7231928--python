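"""Brownian-dynamics simulator for membrane FCS photon-count traces.

Lipid analogues diffuse in one or two planar membranes (fixed z offsets from
the focal plane) inside a periodic square box.  Each time bin every particle
takes an isotropic 2-D Gaussian step with per-axis variance 2·D·Δt; emission
may be gated by a two-state triplet (bright/dark) telegraph process; expected
counts per bin follow the observation-volume profile at the particle position
and realized counts are Poisson draws.

Positions update once per bin with no sub-bin integration: at the default
2 μs bin the r.m.s. step (≈ 6 nm at D = 5 μm²/s) is tiny compared with the
lateral observation size (>100 nm), so intra-bin blur is negligible compared
with the ~ms transit time being measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .psf import ObservationVolume

__all__ = [
    "DiffusionSimConfig",
    "IntensityTrace",
    "simulate_trace",
    "brownian_trajectories",
    "write_trace_csv",
    "read_trace_csv",
]

#: bins simulated per vectorized chunk; bounds peak memory to ~100 MB
_CHUNK_BINS = 32768


@dataclass(frozen=True)
class DiffusionSimConfig:
    """Parameters of one simulated FCS acquisition.

    diffusion_coeff is in μm²/s, lengths in nm, times in s, rates in
    counts/s.  ``membrane_z_nm`` holds one or two membrane plane offsets from
    the focal plane.  ``triplet_fraction`` is the equilibrium dark-state
    fraction and ``triplet_tau`` the telegraph correlation time
    1/(k_on + k_off).
    """

    diffusion_coeff: float = 5.0
    n_particles: int = 220
    box_side: float = 2400.0
    bin_time: float = 2e-6
    duration: float = 5.0
    brightness_peak: float = 150_000.0
    background_rate: float = 0.0
    triplet_fraction: float = 0.0
    triplet_tau: float = 5e-6
    membrane_z_nm: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.bin_time <= 0:
            raise ValueError("bin_time must be positive")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if not (0.0 <= self.triplet_fraction < 1.0):
            raise ValueError("triplet_fraction must lie in [0, 1)")
        if self.triplet_tau <= 0:
            raise ValueError("triplet_tau must be positive")
        zs = self.membrane_z_nm
        if np.isscalar(zs):
            object.__setattr__(self, "membrane_z_nm", (float(zs),))
        else:
            object.__setattr__(self, "membrane_z_nm", tuple(float(z) for z in zs))
        if not 1 <= len(self.membrane_z_nm) <= 2:
            raise ValueError("membrane_z_nm takes one or two plane offsets")
        n_bins = self.duration / self.bin_time
        if abs(n_bins - round(n_bins)) > 1e-9 * max(1.0, n_bins) or round(n_bins) < 2:
            raise ValueError("duration must be an integer number (>= 2) of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    def validate_box(self, vol: ObservationVolume) -> None:
        """Guard against periodic-image artifacts: box >= 10 lateral FWHMs."""
        if self.box_side < 10.0 * vol.lateral_fwhm:
            raise ValueError(
                f"box_side={self.box_side} nm is below 10x the lateral FWHM "
                f"({vol.lateral_fwhm} nm); periodic images would correlate"
            )


@dataclass
class IntensityTrace:
    """Binned photon counts versus time."""

    bin_time: float
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_time

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        return float(self.counts.mean()) / self.bin_time


def _telegraph_step(dark: np.ndarray, p_bd: float, p_db: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One bin of the bright/dark telegraph chain for all particles."""
    u = rng.random(dark.shape)
    flip = np.where(dark, u < p_db, u < p_bd)
    return dark ^ flip


def simulate_trace(config: DiffusionSimConfig, vol: ObservationVolume) -> IntensityTrace:
    """Simulate one photon-count trace for the given observation volume.

    Particles are initialized uniformly in the box, split evenly over the
    configured membrane planes; the observation volume is centred laterally
    in the box and axially at z = 0.  Reproducible for a fixed config seed.
    """
    config.validate_box(vol)
    rng = np.random.default_rng(config.seed)
    n_bins = config.n_bins
    n_p = config.n_particles
    box = config.box_side
    dt = config.bin_time

    # per-axis Brownian step, nm
    step_sd = math.sqrt(2.0 * config.diffusion_coeff * 1e6 * dt)

    x = rng.uniform(0.0, box, size=n_p)
    y = rng.uniform(0.0, box, size=n_p)
    init_xy = np.column_stack([x, y])
    # membranes get equal particle shares; axial weight is fixed per particle
    planes = np.asarray(config.membrane_z_nm)
    plane_idx = np.arange(n_p) % len(planes)
    z_weight = vol.axial_profile(planes)[plane_idx]

    cx = cy = box / 2.0
    inv_lat2 = 4.0 * math.log(2.0) / vol.lateral_fwhm**2
    bright_bt = config.brightness_peak * dt
    bg_bt = config.background_rate * dt

    use_triplet = config.triplet_fraction > 0.0
    if use_triplet:
        # dark->bright and bright->dark per-bin probabilities of the
        # discretized telegraph process with correlation time triplet_tau
        decay = 1.0 - math.exp(-dt / config.triplet_tau)
        p_bd = config.triplet_fraction * decay
        p_db = (1.0 - config.triplet_fraction) * decay
        dark = rng.random(n_p) < config.triplet_fraction

    counts = np.empty(n_bins, dtype=np.int64)
    z_weight32 = z_weight.astype(np.float32)
    for start in range(0, n_bins, _CHUNK_BINS):
        m = min(_CHUNK_BINS, n_bins - start)
        # float32 path arithmetic: position round-off (~1e-4 nm) is far below
        # the ~6 nm r.m.s. step and the >100 nm observation size
        steps = rng.standard_normal((2, m, n_p), dtype=np.float32)
        steps *= step_sd
        np.cumsum(steps, axis=1, out=steps)
        x_path, y_path = steps
        x_path += x.astype(np.float32)
        y_path += y.astype(np.float32)
        x_path %= box
        y_path %= box
        x = x_path[-1].astype(float)
        y = y_path[-1].astype(float)

        x_path -= cx
        y_path -= cy
        np.square(x_path, out=x_path)
        np.square(y_path, out=y_path)
        x_path += y_path
        x_path *= -inv_lat2
        w = np.exp(x_path, out=x_path)
        w *= z_weight32  # (m, n_p)
        if use_triplet:
            bright = np.empty((m, n_p), dtype=bool)
            for t in range(m):
                dark = _telegraph_step(dark, p_bd, p_db, rng)
                bright[t] = ~dark
            w = w * bright
        lam = bright_bt * w.sum(axis=1) + bg_bt
        counts[start:start + m] = rng.poisson(lam)

    meta = {"config": config, "seed": config.seed, "label": vol.label,
            "initial_positions": init_xy, "plane_weights": z_weight}
    return IntensityTrace(bin_time=dt, counts=counts, meta=meta)


def brownian_trajectories(n_steps: int, n_particles: int, diffusion_coeff: float,
                          bin_time: float, seed: int = 0) -> np.ndarray:
    """Unwrapped free 2-D Brownian trajectories, shape (n_steps+1, n_particles, 2), nm.

    Same step statistics as :func:`simulate_trace` (per-axis variance
    2·D·Δt per step) without the periodic wrap, for direct MSD checks.
    """
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2.0 * diffusion_coeff * 1e6 * bin_time)
    steps = rng.normal(0.0, step_sd, size=(n_steps, n_particles, 2))
    traj = np.concatenate([np.zeros((1, n_particles, 2)), np.cumsum(steps, axis=0)])
    return traj


# -- trace CSV I/O --------------------------------------------------------

def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    """Write a trace: ``# bin_time_s=``, ``# seed=`` headers, one count/line."""
    path = Path(path)
    seed = trace.meta.get("seed", 0)
    with path.open("w") as fh:
        fh.write(f"# bin_time_s={trace.bin_time!r}\n")
        fh.write(f"# seed={int(seed)}\n")
        fh.write("\n".join(str(int(c)) for c in trace.counts))
        fh.write("\n")


def read_trace_csv(path: str | Path) -> IntensityTrace:
    """Read a trace written by :func:`write_trace_csv` (exact round trip)."""
    path = Path(path)
    bin_time = None
    seed = 0
    counts: list[int] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "bin_time_s":
                    bin_time = float(val)
                elif key.strip() == "seed":
                    seed = int(val)
            else:
                counts.append(int(line))
    if bin_time is None:
        raise ValueError(f"{path}: missing '# bin_time_s=' header")
    return IntensityTrace(bin_time=bin_time, counts=np.array(counts, dtype=np.int64),
                          meta={"seed": seed})
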