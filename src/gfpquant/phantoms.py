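"""Synthetic embryo and cell-drop phantoms with exact ground truth.

These stand in for real micrographs, which are not publicly deposited.  An
embryo phantom is a dim elliptical "yolk" whose autofluorescence sits on a
plateau ``a`` and falls off smoothly to zero at the ellipse edge, plus one or
more bright compact disks (the GFP cell masses) at intensity ``c > a``, plus
optional additive Gaussian noise clipped to [0, 255].  The falloff profile is
deliberately plateau-heavy (``a * (1 - d**falloff_power)`` in the normalized
elliptical radius d) so the threshold sweep shows the characteristic
steep-then-flat decay: most yolk pixels vanish within one threshold step of
``a``, after which only the mass remains.

Ground truth (mass area, mass mean intensity, autofluorescent area, cell
centers) is computed from the noise-free geometry, before noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PlacementError
from .image import IntensityImage

__all__ = [
    "Ellipse",
    "MassDisk",
    "EmbryoPhantomSpec",
    "PhantomGroundTruth",
    "render_embryo",
    "render_pair",
    "render_cell_drop",
]


@dataclass(frozen=True)
class Ellipse:
    """Yolk geometry: center (row, col), semi-axes (rows, cols), plateau a."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    plateau: float  # autofluorescence intensity a, in [0, 60]
    falloff_power: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.plateau <= 60:
            raise ValueError(f"autofluorescence plateau must be in [0, 60], got {self.plateau}")
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.falloff_power <= 0:
            raise ValueError("falloff_power must be positive")


@dataclass(frozen=True)
class MassDisk:
    """One bright GFP cell mass: disk center (row, col), radius, intensity c."""

    center: tuple[float, float]
    radius: float
    intensity: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("mass radius must be positive")
        if not 0 < self.intensity <= 255:
            raise ValueError(f"mass intensity must be in (0, 255], got {self.intensity}")


@dataclass(frozen=True)
class EmbryoPhantomSpec:
    image_size: tuple[int, int]
    yolk: Ellipse | None = None
    masses: tuple[MassDisk, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", tuple(self.masses))
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        a = self.yolk.plateau if self.yolk is not None else 0.0
        for m in self.masses:
            if m.intensity <= a:
                raise ValueError(
                    f"mass intensity {m.intensity} must strictly exceed the "
                    f"autofluorescence plateau {a}"
                )
            r0, c0 = m.center
            if not (m.radius <= r0 <= h - 1 - m.radius and m.radius <= c0 <= w - 1 - m.radius):
                raise ValueError(f"mass at {m.center} (radius {m.radius}) exceeds the frame")


@dataclass(frozen=True)
class PhantomGroundTruth:
    mass_area: int
    mass_mean_intensity: float
    autofluor_area: int
    cell_centers: tuple[tuple[float, float], ...] = ()


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")


def _render_noise_free(spec: EmbryoPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (noise-free image, boolean mass mask)."""
    h, w = spec.image_size
    rr, cc = _grid(h, w)
    img = np.zeros((h, w), dtype=np.float64)

    if spec.yolk is not None and spec.yolk.plateau > 0:
        (yr, yc), (sr, sc) = spec.yolk.center, spec.yolk.semi_axes
        d2 = ((rr - yr) / sr) ** 2 + ((cc - yc) / sc) ** 2
        inside = d2 < 1.0
        d = np.sqrt(d2[inside])
        img[inside] = spec.yolk.plateau * (1.0 - d ** spec.yolk.falloff_power)

    mass_mask = np.zeros((h, w), dtype=bool)
    for m in spec.masses:
        dm = (rr - m.center[0]) ** 2 + (cc - m.center[1]) ** 2 <= m.radius**2
        img[dm] = np.maximum(img[dm], m.intensity)
        mass_mask |= dm
    return img, mass_mask


def render_embryo(spec: EmbryoPhantomSpec) -> tuple[IntensityImage, PhantomGroundTruth]:
    """Render a phantom and its ground truth; deterministic given the seed."""
    clean, mass_mask = _render_noise_free(spec)
    a = spec.yolk.plateau if spec.yolk is not None else 0.0
    auto = (clean > 0) & (clean <= a) & ~mass_mask
    truth = PhantomGroundTruth(
        mass_area=int(mass_mask.sum()),
        mass_mean_intensity=float(clean[mass_mask].mean()) if mass_mask.any() else 0.0,
        autofluor_area=int(auto.sum()),
    )
    img = clean
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(clean + rng.normal(0.0, spec.noise_sigma, clean.shape), 0.0, 255.0)
    return IntensityImage(pixels=img), truth


def render_pair(
    spec0: EmbryoPhantomSpec, area_ratio: float, intensity_ratio: float
) -> tuple[tuple[IntensityImage, IntensityImage], float]:
    """Render a 0 hpi / 72 hpi phantom pair with known true proliferation index.

    The 72 hpi image scales every mass radius by sqrt(area_ratio) and every
    mass intensity by intensity_ratio.  true_PI is computed from the
    *rasterized* ground truths, so it equals area_ratio * intensity_ratio only
    up to pixelization of the disks.
    """
    if area_ratio <= 0 or intensity_ratio <= 0:
        raise ValueError("area_ratio and intensity_ratio must be positive")
    if not spec0.masses:
        raise ValueError("spec0 must contain at least one mass")
    scale = math.sqrt(area_ratio)
    scaled = tuple(
        replace(m, radius=m.radius * scale, intensity=m.intensity * intensity_ratio)
        for m in spec0.masses
    )
    # spec __post_init__ re-validates frame fit, intensity range and c > a
    spec72 = replace(spec0, masses=scaled, seed=spec0.seed + 1)
    img0, gt0 = render_embryo(spec0)
    img72, gt72 = render_embryo(spec72)
    if gt0.mass_area == 0 or gt0.mass_mean_intensity == 0:
        raise ValueError("0 hpi mass rasterized to nothing; enlarge the disk")
    true_pi = (gt72.mass_area * gt72.mass_mean_intensity) / (
        gt0.mass_area * gt0.mass_mean_intensity
    )
    return (img0, img72), true_pi


def render_cell_drop(
    n_cells: int,
    radius_range: tuple[int, int],
    min_separation: float,
    intensity: float = 200.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    max_attempts_per_cell: int = 2000,
) -> tuple[IntensityImage, PhantomGroundTruth]:
    """Scatter ``n_cells`` bright disks with pairwise center separation at
    least ``min_separation`` (rejection sampling; deterministic given seed).

    Raises ``PlacementError`` when the attempt budget (``n_cells *
    max_attempts_per_cell`` draws) runs out, i.e. the packing is infeasible.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    r_lo, r_hi = radius_range
    if not 1 <= r_lo <= r_hi:
        raise ValueError(f"need 1 <= r_lo <= r_hi, got {radius_range}")
    h, w = image_size
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w), dtype=np.float64)
    centers: list[tuple[float, float]] = []
    margin = r_hi + 1
    budget = n_cells * max_attempts_per_cell
    attempts = 0
    min_sq = min_separation * min_separation
    while len(centers) < n_cells:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(centers)}/{n_cells} cells within the "
                f"attempt budget of {budget}"
            )
        attempts += 1
        r0 = rng.uniform(margin, h - 1 - margin)
        c0 = rng.uniform(margin, w - 1 - margin)
        if any((r0 - r) ** 2 + (c0 - c) ** 2 < min_sq for r, c in centers):
            continue
        centers.append((r0, c0))

    rr, cc = _grid(h, w)
    radii = rng.integers(r_lo, r_hi + 1, size=n_cells)
    for (r0, c0), rad in zip(centers, radii):
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = intensity
    truth = PhantomGroundTruth(
        mass_area=int((img > 0).sum()),
        mass_mean_intensity=intensity if centers else 0.0,
        autofluor_area=0,
        cell_centers=tuple(centers),
    )
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 255.0)
    return IntensityImage(pixels=img), truth
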