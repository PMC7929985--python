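"""Ground-truthed synthetic data for exercising the full analysis pipeline.

Two generators:

* :func:`generate_stack` emulates a paired two-photon acquisition of a
  collagen slab seeded with cells — a nuclei channel containing blurred
  bright spheres at known 3D positions and a collagen channel with signal
  confined to the slab z-range — together with the ground-truth centroids.
* :func:`generate_clonogenic_data` draws Poisson colony counts per dish
  under a linear-quadratic survival law.

Both are pure functions of their spec (which carries the RNG seed):
identical spec means bit-identical output.

Default geometry mirrors the reference acquisitions: a 350 µm square field,
0.192 µm lateral pixels, 1 µm z-steps and a ~122 µm collagen slab. Nuclei
are hard spheres rasterized onto the anisotropic voxel grid and Gaussian
blurred — the simplest intensity model whose centroid is analytically the
sphere centre. Placement is uniform within the slab with minimum-separation
rejection sampling, matching the observed homogeneous cell distribution
along z. Noise is additive Gaussian clipped at zero; this stresses the
thresholding step without modelling detector physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stacks import ImageStack
from .survival import ClonogenicTable

__all__ = [
    "StackSpec",
    "GroundTruth",
    "ClonoSimSpec",
    "PackingError",
    "generate_stack",
    "generate_clonogenic_data",
    "lq_survival",
]


@dataclass(frozen=True)
class StackSpec:
    """Parameters of a synthetic two-channel acquisition.

    The defaults emulate a HeLa-seeded collagen slab: 900 nuclei of 5 µm
    radius per field with a 10 µm hard-core separation, which yields a
    median nearest-neighbour spacing of ~15 µm, and the acquisition grid of
    the reference instrument (350 µm field, 0.192 µm pixels, 1 µm z-step).
    A fibroblast-like sample (~22 µm median spacing) corresponds to
    ``n_nuclei=350, min_separation_um=14``. At the 10 µm hard core nuclei
    may nearly touch, and the blurred spheres can then merge into a single
    connected component downstream — mirroring the behaviour of the real
    pipeline on touching nuclei.
    ``foreground_level`` / ``background_level`` / ``noise_sd`` set the
    signal-to-noise regime; the defaults (100 over a background of 10 with
    sd 5) give a clearly bimodal histogram so automatic thresholding works.
    """

    field_size_um: float = 350.0
    pixel_size_um: float = 0.192
    z_step_um: float = 1.0
    slab_thickness_um: float = 122.0
    n_nuclei: int = 900
    nucleus_radius_um: float = 5.0
    min_separation_um: float = 10.0
    blur_sigma_um: float = 0.5
    noise_sd: float = 5.0
    background_level: float = 10.0
    foreground_level: float = 100.0
    collagen_level: float = 60.0
    z_margin_um: float = 10.0
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (self.pixel_size_um > 0 and self.z_step_um > 0 and self.slab_thickness_um > 0):
            raise ValueError("pixel_size_um, z_step_um and slab_thickness_um must be positive")
        if self.field_size_um <= 0 or self.n_nuclei < 0:
            raise ValueError("field_size_um must be positive and n_nuclei >= 0")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be positive")
        if not self.allow_overlap and self.min_separation_um < 2 * self.nucleus_radius_um:
            raise ValueError(
                "min_separation_um must be >= 2 * nucleus_radius_um when overlap is disallowed"
            )
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be non-negative")


@dataclass
class GroundTruth:
    """True nucleus centres (x, y, z, µm) and the slab z-range of a stack."""

    centroids_um: np.ndarray
    slab_z_range_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.centroids_um = np.asarray(self.centroids_um, dtype=float).reshape(-1, 3)


class PackingError(RuntimeError):
    """Raised when minimum-separation placement cannot fit all nuclei."""


def _sample_centers(spec: StackSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform placement in the slab with rejection for minimum separation.

    Centres keep one nucleus radius away from the lateral field edges so
    spheres are fully contained in the image. Attempts are bounded; an
    infeasible packing raises :class:`PackingError` naming the achieved
    count rather than looping forever.
    """
    r = spec.nucleus_radius_um
    lo_xy, hi_xy = r, spec.field_size_um - r
    if hi_xy <= lo_xy and spec.n_nuclei > 0:
        raise PackingError("field too small to contain a single nucleus")
    z_lo = spec.z_margin_um
    z_hi = spec.z_margin_um + spec.slab_thickness_um
    pts: list[np.ndarray] = []
    max_attempts = max(1000, 500 * max(spec.n_nuclei, 1))
    attempts = 0
    min_sep2 = spec.min_separation_um**2
    while len(pts) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(pts)} of {spec.n_nuclei} nuclei at "
                f"min separation {spec.min_separation_um} um after {attempts} attempts"
            )
        attempts += 1
        cand = np.array(
            [
                rng.uniform(lo_xy, hi_xy),
                rng.uniform(lo_xy, hi_xy),
                rng.uniform(z_lo, z_hi),
            ]
        )
        if not spec.allow_overlap and pts:
            d2 = np.sum((np.asarray(pts) - cand) ** 2, axis=1)
            if d2.min() < min_sep2:
                continue
        pts.append(cand)
    return np.asarray(pts).reshape(-1, 3)


def _rasterize_nuclei(
    spec: StackSpec, centers: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Blurred hard spheres on a zero background, float32, combined by max."""
    nz, ny, nx = shape
    vol = np.zeros(shape, dtype=np.float32)
    px, dz = spec.pixel_size_um, spec.z_step_um
    r, sigma = spec.nucleus_radius_um, spec.blur_sigma_um
    pad_xy = int(math.ceil((r + 4 * sigma) / px)) + 1
    pad_z = int(math.ceil((r + 4 * sigma) / dz)) + 1
    sig_vox = (sigma / dz, sigma / px, sigma / px)
    for cx, cy, cz in centers:
        ix, iy, iz = int(round(cx / px)), int(round(cy / px)), int(round(cz / dz))
        x0, x1 = max(ix - pad_xy, 0), min(ix + pad_xy + 1, nx)
        y0, y1 = max(iy - pad_xy, 0), min(iy + pad_xy + 1, ny)
        z0, z1 = max(iz - pad_z, 0), min(iz + pad_z + 1, nz)
        zz = (np.arange(z0, z1) * dz - cz)[:, None, None]
        yy = (np.arange(y0, y1) * px - cy)[None, :, None]
        xx = (np.arange(x0, x1) * px - cx)[None, None, :]
        sphere = (zz**2 + yy**2 + xx**2 <= r**2).astype(np.float32)
        sphere *= spec.foreground_level
        if sigma > 0:
            sphere = gaussian_filter(sphere, sigma=sig_vox)
        patch = vol[z0:z1, y0:y1, x0:x1]
        np.maximum(patch, sphere, out=patch)
    return vol


def generate_stack(spec: StackSpec) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Generate paired nuclei (2PEF-like) and collagen (SHG-like) stacks.

    Returns the two calibrated stacks plus the :class:`GroundTruth` used to
    build them. The collagen channel is a top-hat along z over the slab
    range with soft (partial-volume) edges; the nuclei channel is background
    plus blurred spheres; both receive additive Gaussian noise clipped at 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx = ny = int(round(spec.field_size_um / spec.pixel_size_um))
    z_extent = spec.slab_thickness_um + 2 * spec.z_margin_um
    nz = int(round(z_extent / spec.z_step_um))
    shape = (nz, ny, nx)

    centers = (
        _sample_centers(spec, rng) if spec.n_nuclei > 0 else np.empty((0, 3))
    )
    nuclei = _rasterize_nuclei(spec, centers, shape)
    nuclei += spec.background_level
    if spec.noise_sd > 0:
        nuclei += rng.standard_normal(shape, dtype=np.float32) * spec.noise_sd
    np.clip(nuclei, 0, None, out=nuclei)

    z_lo = spec.z_margin_um
    z_hi = spec.z_margin_um + spec.slab_thickness_um
    dz = spec.z_step_um
    z_centers = np.arange(nz) * dz
    # fractional overlap of each slice interval [z - dz/2, z + dz/2] with the slab
    overlap = (
        np.minimum(z_centers + dz / 2, z_hi) - np.maximum(z_centers - dz / 2, z_lo)
    ) / dz
    weight = np.clip(overlap, 0.0, 1.0).astype(np.float32)
    collagen = np.empty(shape, dtype=np.float32)
    collagen[:] = (spec.background_level + spec.collagen_level * weight)[:, None, None]
    if spec.noise_sd > 0:
        collagen += rng.standard_normal(shape, dtype=np.float32) * spec.noise_sd
    np.clip(collagen, 0, None, out=collagen)

    truth = GroundTruth(centroids_um=centers, slab_z_range_um=(z_lo, z_hi))
    mk = lambda v, ch: ImageStack(
        voxels=v, pixel_size_um=spec.pixel_size_um, z_step_um=spec.z_step_um, channel=ch
    )
    return mk(nuclei, "nuclei"), mk(collagen, "collagen"), truth


def lq_survival(dose: np.ndarray | float, alpha: float, beta: float) -> np.ndarray | float:
    """Linear-quadratic survival fraction SF(D) = exp(-(alpha*D + beta*D^2))."""
    dose = np.asarray(dose, dtype=float)
    out = np.exp(-(alpha * dose + beta * dose**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClonoSimSpec:
    """Parameters of a simulated clonogenic assay.

    Defaults follow the reference 3D experiment: linear-quadratic
    coefficients alpha = 0.48 / Gy, beta = 0.03 / Gy^2, a plating efficiency
    of 0.37, three dishes per dose, and doses spanning 0-6 Gy.
    """

    alpha: float = 0.48
    beta: float = 0.03
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)
    cells_seeded: int = 10_000
    plating_efficiency: float = 0.37
    dishes_per_dose: int = 3
    arm: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not (0 < self.plating_efficiency <= 1):
            raise ValueError("plating_efficiency must be in (0, 1]")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.cells_seeded < 1 or self.dishes_per_dose < 1:
            raise ValueError("cells_seeded and dishes_per_dose must be >= 1")


def generate_clonogenic_data(spec: ClonoSimSpec) -> ClonogenicTable:
    """Draw Poisson colony counts per dish under the LQ survival law.

    Each dish at dose D receives a count drawn from
    ``Poisson(cells_seeded * PE * SF(D))`` — the standard colony-count noise
    model for maximum-likelihood survival-curve analysis.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for dose in spec.doses:
        mean = (
            spec.cells_seeded
            * spec.plating_efficiency
            * lq_survival(dose, spec.alpha, spec.beta)
        )
        counts = rng.poisson(mean, size=spec.dishes_per_dose)
        for dish, c in enumerate(counts, start=1):
            rows.append(
                dict(
                    arm=spec.arm,
                    dose_gy=float(dose),
                    cells_seeded=spec.cells_seeded,
                    colonies=int(c),
                    dish_id=f"{spec.arm}-D{dose:g}-{dish}",
                )
            )
    return ClonogenicTable(pd.DataFrame(rows))
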