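"""Membrane scene ground truth and confocal/STED image formation.

Scenes are collections of idealized membrane surfaces — planes, spherical
vesicle shells, tubes and tori — rasterized onto a voxel grid at the
acquisition pitch of a STED stack (40 nm lateral, 20 nm axial by default).
A real bilayer is ~5 nm thick, far below the axial voxel, so every surface
rasterizes to a voxel-thin sheet whose voxel values carry the membrane
surface area inside the voxel times the label density.

Imaging convolves the ground truth with the observation-volume kernel
sampled on the same grid (unit sum, so total expected intensity is
conserved), scales to photons and optionally applies Poisson noise.
Convolutions reflect-pad the stack explicitly, so edge behaviour is the
mirror condition throughout.

Axis order is (z, y, x), z index 0 at the smallest z; voxel values represent
integrals over the voxel, not point samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .psf import ObservationVolume

__all__ = [
    "Plane", "SphereShell", "Tube", "Torus",
    "MembraneScene", "ImageStack", "SpectralImagePair",
    "render_scene", "image_scene", "make_spectral_scene",
    "psf_kernel", "convolve_reflect",
    "write_tiff", "read_tiff",
]

DEFAULT_VOXEL_SIZE = (20.0, 40.0, 40.0)  # (dz, dy, dx) nm


# -- primitives -----------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """Membrane plane normal to the optical axis at height z0 (nm)."""
    z0: float
    label_density: float = 1.0
    kind: str = field(default="plane", init=False)


@dataclass(frozen=True)
class SphereShell:
    """Spherical membrane shell (vesicle), center (z, y, x) nm, radius nm."""
    center: tuple[float, float, float]
    radius: float
    label_density: float = 1.0
    kind: str = field(default="sphere_shell", init=False)


@dataclass(frozen=True)
class Tube:
    """Cylindrical membrane tube with axis along y, center (z, x) nm."""
    center_zx: tuple[float, float]
    radius: float
    length: float
    y_mid: float = 0.0
    label_density: float = 1.0
    kind: str = field(default="tube", init=False)


@dataclass(frozen=True)
class Torus:
    """Toroidal membrane (red-blood-cell-like), ring in the xy plane.

    ring_radius is the distance from the torus center to the tube center;
    tube_radius is the radius of the tube cross-section.
    """
    center: tuple[float, float, float]
    ring_radius: float
    tube_radius: float
    label_density: float = 1.0
    kind: str = field(default="torus", init=False)


Primitive = Plane | SphereShell | Tube | Torus


@dataclass(frozen=True)
class MembraneScene:
    """Ground-truth membrane geometry inside a bounding box.

    extent is ((zmin, zmax), (ymin, ymax), (xmin, xmax)) in nm.
    """
    primitives: tuple[Primitive, ...]
    extent: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "primitives", tuple(self.primitives))
        if len(self.extent) != 3:
            raise ValueError("extent must give (z, y, x) ranges")
        for prim in self.primitives:
            if prim.label_density <= 0:
                raise ValueError("label_density must be positive")
            lo, hi = _primitive_bounds(prim)
            for ax in range(3):
                if np.isnan(lo[ax]):  # axis unconstrained (plane spans laterally)
                    continue
                if lo[ax] < self.extent[ax][0] - 1e-9 or hi[ax] > self.extent[ax][1] + 1e-9:
                    raise ValueError(
                        f"{prim.kind} primitive extends outside the scene extent "
                        f"on axis {'zyx'[ax]}")


def _primitive_bounds(prim: Primitive) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(prim, Plane):
        nan = float("nan")
        return (np.array([prim.z0, nan, nan]), np.array([prim.z0, nan, nan]))
    if isinstance(prim, SphereShell):
        c = np.asarray(prim.center)
        return c - prim.radius, c + prim.radius
    if isinstance(prim, Tube):
        cz, cx = prim.center_zx
        lo = np.array([cz - prim.radius, prim.y_mid - prim.length / 2, cx - prim.radius])
        hi = np.array([cz + prim.radius, prim.y_mid + prim.length / 2, cx + prim.radius])
        return lo, hi
    if isinstance(prim, Torus):
        c = np.asarray(prim.center)
        r_out = prim.ring_radius + prim.tube_radius
        lo = c - np.array([prim.tube_radius, r_out, r_out])
        hi = c + np.array([prim.tube_radius, r_out, r_out])
        return lo, hi
    raise TypeError(f"unknown primitive {type(prim)!r}")


# -- image container ------------------------------------------------------

@dataclass
class ImageStack:
    """Voxel image, axis order (z, y, x); voxel centers at origin + i*voxel."""
    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (nm) along a given axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    @property
    def total(self) -> float:
        return float(self.voxels.sum())


@dataclass
class SpectralImagePair:
    """Green (510–590 nm) and red (650–730 nm) channel stacks of one scene."""
    green: ImageStack
    red: ImageStack

    def __post_init__(self) -> None:
        if self.green.voxels.shape != self.red.voxels.shape:
            raise ValueError("green and red stacks must share one shape")
        if self.green.voxel_size != self.red.voxel_size:
            raise ValueError("green and red stacks must share one voxel size")


# -- rasterization --------------------------------------------------------

def _grid_arrays(scene: MembraneScene, voxel_size) -> tuple[tuple, tuple]:
    vz, vy, vx = voxel_size
    shape = []
    origin = []
    for (lo, hi), v in zip(scene.extent, (vz, vy, vx)):
        n = int(round((hi - lo) / v))
        if n < 1:
            raise ValueError("scene extent smaller than one voxel")
        shape.append(n)
        origin.append(lo + v / 2.0)
    return tuple(shape), tuple(origin)


def _deposit(vox: np.ndarray, pts: np.ndarray, weights: np.ndarray,
             origin, voxel_size) -> None:
    """Accumulate weighted surface points into nearest voxels."""
    idx = np.empty((len(pts), 3), dtype=np.int64)
    for ax in range(3):
        idx[:, ax] = np.round((pts[:, ax] - origin[ax]) / voxel_size[ax])
    ok = np.all((idx >= 0) & (idx < np.array(vox.shape)), axis=1)
    np.add.at(vox, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), weights[ok] if weights.ndim else weights)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack([cos_t, sin_t * np.sin(phi), sin_t * np.cos(phi)])


def render_scene(scene: MembraneScene,
                 voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE) -> ImageStack:
    """Rasterize a scene: voxel value = label density x membrane area (nm²).

    Curved surfaces are sampled with deterministic area-weighted point
    lattices much finer than the voxel pitch, so total rendered intensity
    equals label_density times the analytic surface area.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    shape, origin = _grid_arrays(scene, voxel_size)
    vox = np.zeros(shape)
    vmin = min(voxel_size)
    # target linear sampling pitch: several points per voxel in each direction
    pitch = vmin / 4.0

    for prim in scene.primitives:
        if isinstance(prim, Plane):
            iz = int(round((prim.z0 - origin[0]) / voxel_size[0]))
            if not 0 <= iz < shape[0]:
                raise ValueError(f"plane z0={prim.z0} falls outside the grid")
            vox[iz] += prim.label_density * voxel_size[1] * voxel_size[2]
        elif isinstance(prim, SphereShell):
            area = 4.0 * math.pi * prim.radius**2
            n = max(int(area / pitch**2), 100)
            pts = prim.radius * _fibonacci_sphere(n) + np.asarray(prim.center)
            w = np.full(n, prim.label_density * area / n)
            _deposit(vox, pts, w, origin, voxel_size)
        elif isinstance(prim, Tube):
            n_theta = max(int(2 * math.pi * prim.radius / pitch), 12)
            n_y = max(int(prim.length / pitch), 2)
            theta = (np.arange(n_theta) + 0.5) * 2 * math.pi / n_theta
            ys = prim.y_mid + (np.arange(n_y) + 0.5) * prim.length / n_y - prim.length / 2
            cz, cx = prim.center_zx
            zz = cz + prim.radius * np.sin(theta)
            xx = cx + prim.radius * np.cos(theta)
            pts = np.column_stack([
                np.repeat(zz, n_y), np.tile(ys, n_theta), np.repeat(xx, n_y)])
            area = 2 * math.pi * prim.radius * prim.length
            w = np.full(len(pts), prim.label_density * area / len(pts))
            _deposit(vox, pts, w, origin, voxel_size)
        elif isinstance(prim, Torus):
            R, r = prim.ring_radius, prim.tube_radius
            n_phi = max(int(2 * math.pi * R / pitch), 12)   # around the ring
            n_theta = max(int(2 * math.pi * r / pitch), 12)  # around the tube
            phi = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
            theta = (np.arange(n_theta) + 0.5) * 2 * math.pi / n_theta
            th, ph = np.meshgrid(theta, phi, indexing="ij")
            cz, cy, cx = prim.center
            zz = cz + r * np.sin(th)
            yy = cy + (R + r * np.cos(th)) * np.sin(ph)
            xx = cx + (R + r * np.cos(th)) * np.cos(ph)
            # exact area element r*(R + r cos(theta)) dtheta dphi
            w = (prim.label_density * r * (R + r * np.cos(th))
                 * (2 * math.pi / n_theta) * (2 * math.pi / n_phi))
            pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
            _deposit(vox, pts, w.ravel(), origin, voxel_size)
        else:
            raise TypeError(f"unknown primitive {type(prim)!r}")

    return ImageStack(voxels=vox, voxel_size=voxel_size, origin=tuple(origin),
                      meta={"kind": "ground_truth"})


# -- image formation ------------------------------------------------------

def psf_kernel(vol: ObservationVolume, voxel_size: Sequence[float],
               cutoff_fwhm: float = 2.0) -> np.ndarray:
    """Sample the observation volume on a voxel grid, normalized to unit sum.

    The kernel extends ``cutoff_fwhm`` FWHMs beyond the main lobe on every
    axis (and beyond the side-lobe offset axially), where the Gaussian has
    fallen below ~1e-5 of the peak; odd-sized so the peak voxel is central.
    """
    vz, vy, vx = (float(v) for v in voxel_size)
    half_lat = cutoff_fwhm * vol.lateral_fwhm
    half_ax = cutoff_fwhm * vol.axial_fwhm + (
        vol.side_lobe_offset if vol.side_lobe_rel_amp > 0 else 0.0)
    nz = int(math.ceil(half_ax / vz))
    ny = int(math.ceil(half_lat / vy))
    nx = int(math.ceil(half_lat / vx))
    z = np.arange(-nz, nz + 1) * vz
    y = np.arange(-ny, ny + 1) * vy
    x = np.arange(-nx, nx + 1) * vx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    k = vol.evaluate(xx, yy, zz)
    return k / k.sum()


def convolve_reflect(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution with explicit mirror (reflect) padding.

    Raises if the kernel's half-extent exceeds the array on any axis, in
    which case the stack should be padded/enlarged by the caller.
    """
    half = [s // 2 for s in kernel.shape]
    for ax, h in enumerate(half):
        if h >= arr.shape[ax]:
            raise ValueError(
                f"PSF kernel half-extent ({h} voxels) exceeds the stack size "
                f"({arr.shape[ax]}) on axis {ax}; enlarge or pad the stack")
    padded = np.pad(arr, [(h, h) for h in half], mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    sl = tuple(slice(h, h + s) for h, s in zip(half, arr.shape))
    return np.clip(out[sl], 0.0, None)


def image_scene(truth: ImageStack, vol: ObservationVolume,
                photons_per_unit: float = 1.0, noise: bool = False,
                seed: int = 0) -> ImageStack:
    """Image a ground-truth stack through an observation volume.

    The expected image is truth ⊛ kernel scaled by ``photons_per_unit``
    (kernel normalized to unit sum, so total expected intensity is
    conserved up to edge reflection); Poisson noise is applied if
    ``noise`` is set, reproducibly for a given seed.
    """
    kernel = psf_kernel(vol, truth.voxel_size)
    expected = convolve_reflect(truth.voxels, kernel) * photons_per_unit
    if noise:
        rng = np.random.default_rng(seed)
        out = rng.poisson(expected).astype(float)
    else:
        out = expected
    meta = dict(truth.meta)
    meta.update(kind="simulated_image", mode=vol.label, noise=bool(noise), seed=seed)
    return ImageStack(voxels=out, voxel_size=truth.voxel_size,
                      origin=truth.origin, meta=meta)


def make_spectral_scene(scene: MembraneScene, gp_map: Sequence[float],
                        total_intensity: float = 1.0,
                        voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE,
                        ) -> SpectralImagePair:
    """Split a scene into green/red channel ground truths with known GP.

    ``gp_map`` assigns one generalized-polarization value in [-1, 1] per
    primitive; per voxel I_G = I·(1+GP)/2 and I_R = I·(1−GP)/2, so the GP
    computed from the noiseless pair returns gp_map exactly.
    """
    if len(gp_map) != len(scene.primitives):
        raise ValueError("gp_map must provide one GP value per primitive")
    for gp in gp_map:
        if not -1.0 <= gp <= 1.0:
            raise ValueError(f"GP value {gp} outside [-1, 1]")
    voxel_size = tuple(float(v) for v in voxel_size)
    shape, origin = _grid_arrays(scene, voxel_size)
    green = np.zeros(shape)
    red = np.zeros(shape)
    for prim, gp in zip(scene.primitives, gp_map):
        sub = MembraneScene(primitives=(prim,), extent=scene.extent)
        vox = render_scene(sub, voxel_size).voxels * total_intensity
        green += vox * (1.0 + gp) / 2.0
        red += vox * (1.0 - gp) / 2.0
    mk = lambda v: ImageStack(voxels=v, voxel_size=voxel_size, origin=tuple(origin))
    return SpectralImagePair(green=mk(green), red=mk(red))


# -- TIFF I/O -------------------------------------------------------------

def write_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a 32-bit float multi-page TIFF plus a plain-text metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32),
                     photometric="minisblack")
    side = path.with_suffix(path.suffix + ".meta.txt")
    with side.open("w") as fh:
        fh.write("axis_order=z,y,x\n")
        fh.write(f"voxel_size_nm={stack.voxel_size[0]},{stack.voxel_size[1]},{stack.voxel_size[2]}\n")
        fh.write(f"origin_nm={stack.origin[0]},{stack.origin[1]},{stack.origin[2]}\n")
        for key in ("mode", "noise", "seed", "kind"):
            if key in stack.meta:
                fh.write(f"{key}={stack.meta[key]}\n")


def read_tiff(path: str | Path) -> ImageStack:
    import tifffile

    path = Path(path)
    vox = np.asarray(tifffile.imread(path), dtype=float)
    if vox.ndim == 2:
        vox = vox[None]
    voxel_size = DEFAULT_VOXEL_SIZE
    origin = (0.0, 0.0, 0.0)
    meta: dict = {}
    side = path.with_suffix(path.suffix + ".meta.txt")
    if side.exists():
        for line in side.read_text().splitlines():
            key, _, val = line.partition("=")
            if key == "voxel_size_nm":
                voxel_size = tuple(float(v) for v in val.split(","))
            elif key == "origin_nm":
                origin = tuple(float(v) for v in val.split(","))
            elif key and key != "axis_order":
                meta[key] = val
    return ImageStack(voxels=vox, voxel_size=voxel_size, origin=origin, meta=meta)
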