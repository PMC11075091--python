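"""Synthetic refractive-index phantoms.

A phantom is an :class:`OpticalMap`: congruent 2D grids of the refractive
index decrement δ and absorption index β (n = 1 − δ + iβ) for one axial
slice, at a stated voxel size and effective energy. Vertical structure is
not modelled: the slit geometry makes the imaging physics independent per
axial row.

Two families are provided: a bar-pattern resolution phantom (equal-width
bars and gaps, i.e. 50% duty cycle, grouped by line width and embedded in a
cylinder — the classic chip-in-a-rod resolution target) and smooth random
soft-tissue-like blob phantoms built to satisfy the single-material
homogeneity assumption γ = δ/(2kβ) = const exactly.

Default material values are configuration inputs, not tabulated physics;
they are chosen so that a projection through a ~1 mm phantom keeps the
transmitted fraction comfortably inside (0.1, 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .units import wave_number

__all__ = [
    "OpticalMap",
    "bar_pattern_phantom",
    "soft_tissue_phantom",
    "cylinder_phantom",
    "linewidth_to_frequency",
    "DEFAULT_SUBSTRATE",
    "DEFAULT_BAR_MATERIAL",
]

#: (δ, β) of the default cylinder/substrate material. The bar material is a
#: denser version of the same material (both scaled by the same factor), so
#: the default bar phantom is exactly single-material in the γ sense.
DEFAULT_SUBSTRATE = (8.0e-7, 1.6e-9)
DEFAULT_BAR_MATERIAL = (1.6e-6, 3.2e-9)

_SUPERSAMPLE = 4  # rasterization oversampling factor per axis


@dataclass
class OpticalMap:
    """Voxelized δ and β maps of one axial slice.

    delta, beta : 2D arrays (rows = z along the beam at angle 0, cols = x)
    voxel_size : voxel edge length in metres
    energy : effective energy in keV (sets the wave number k)
    meta : free-form metadata (bar-group boxes, provenance, ...)
    """

    delta: np.ndarray
    beta: np.ndarray
    voxel_size: float
    energy: float = 18.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.delta.shape != self.beta.shape or self.delta.ndim != 2:
            raise ValueError("delta and beta must be congruent 2D grids")
        if np.any(self.delta < 0) or np.any(self.beta < 0):
            raise ValueError("delta and beta must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def k(self) -> float:
        return wave_number(self.energy)

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta.shape

    def gamma_map(self) -> np.ndarray:
        """γ = δ/(2kβ) (metres) where β > 0, NaN elsewhere."""
        with np.errstate(divide="ignore", invalid="ignore"):
            g = self.delta / (2.0 * self.k * self.beta)
        g[self.beta <= 0] = np.nan
        return g

    def field_width(self) -> float:
        """Physical width of the map along x, in metres."""
        return self.shape[1] * self.voxel_size


def linewidth_to_frequency(width: float) -> float:
    """Spatial frequency in line pairs per mm for a bar line width in metres.

    One line pair spans a bar plus a gap, i.e. twice the line width:
    f = 1/(2·width). 150 μm bars → 3.33 lp/mm, 5 μm bars → 100 lp/mm.
    """
    if width <= 0:
        raise ValueError("line width must be positive")
    return 1.0 / (2.0 * width * 1e3)


def _downsample(block: np.ndarray, f: int) -> np.ndarray:
    h, w = block.shape
    return block.reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def _disc_mask(n: int, radius_px: float) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def cylinder_phantom(
    radius: float,
    shape: int = 256,
    voxel_size: float = 4e-6,
    material: tuple[float, float] = DEFAULT_SUBSTRATE,
    energy: float = 18.0,
) -> OpticalMap:
    """Uniform cylinder (disc in-slice) of a single material.

    Edges are anti-aliased by supersampled coverage averaging; since δ and β
    scale together, the γ map stays exactly constant inside the support.
    """
    if radius <= 0 or radius > shape * voxel_size / 2:
        raise ValueError("radius must be positive and fit inside the grid")
    f = _SUPERSAMPLE
    mask = _disc_mask(shape * f, radius / voxel_size * f).astype(np.float64)
    cov = _downsample(mask, f)
    d, b = material
    return OpticalMap(
        delta=d * cov,
        beta=b * cov,
        voxel_size=voxel_size,
        energy=energy,
        meta={"kind": "cylinder", "radius_um": radius * 1e6},
    )


def bar_pattern_phantom(
    line_widths: Sequence[float],
    voxel_size: float,
    n_bars: int = 5,
    bar_length: float = 300e-6,
    material: tuple[float, float] = DEFAULT_BAR_MATERIAL,
    substrate: tuple[float, float] = DEFAULT_SUBSTRATE,
    group_gap: float = 60e-6,
    margin: float = 120e-6,
    energy: float = 18.0,
) -> OpticalMap:
    """Resolution chip: groups of vertical bars embedded in a cylinder.

    Each group holds ``n_bars`` bars of one line width, alternating with
    gaps of the same width (50% duty cycle), so a group of width W spans
    ``2·n_bars·W`` along x. Groups are laid out side by side, separated by
    ``group_gap``, inside a cylinder of substrate material sized to contain
    them. Bar-group bounding boxes (physical μm, origin at the map centre)
    are returned in ``meta["bar_groups"]`` for downstream modulation
    analysis, together with each group's pitch and bar phase.
    """
    widths = [float(w) for w in line_widths]
    if not widths:
        raise ValueError("need at least one line width")
    if voxel_size > min(widths) / 4.0:
        raise ValueError(
            f"voxel size {voxel_size*1e6:.2f} um too coarse for "
            f"{min(widths)*1e6:.2f} um bars (need <= width/4)"
        )

    group_spans = [2.0 * n_bars * w for w in widths]
    chip_w = sum(group_spans) + group_gap * (len(widths) - 1)
    radius = 0.5 * float(np.hypot(chip_w, bar_length)) + margin
    n = int(np.ceil(2.0 * radius / voxel_size)) + 2
    n += n % 2  # even grid, centre between pixels

    f = _SUPERSAMPLE
    nf = n * f
    vs_f = voxel_size / f
    centre = (nf - 1) / 2.0  # supersampled pixel index of the physical origin

    sub = _disc_mask(nf, radius / vs_f)
    d = np.where(sub, substrate[0], 0.0)
    b = np.where(sub, substrate[1], 0.0)

    # paint the bars; x=0 at the map centre, chip centred horizontally
    xs = (np.arange(nf) - centre) * vs_f
    ys = (np.arange(nf) - centre) * vs_f
    in_chip_y = np.abs(ys) <= bar_length / 2.0

    groups = []
    x_left = -chip_w / 2.0
    for w, span in zip(widths, group_spans):
        # bar occupies [x_left + 2mw, x_left + 2mw + w) for m = 0..n_bars-1
        rel = xs - x_left
        in_group = (rel >= 0) & (rel < span)
        bar_cols = in_group & ((np.floor(rel / w).astype(int) % 2) == 0)
        sel = np.outer(in_chip_y, bar_cols)
        d[sel] = material[0]
        b[sel] = material[1]
        groups.append(
            {
                "width_um": w * 1e6,
                "pitch_um": 2.0 * w * 1e6,
                "n_bars": n_bars,
                "x0_um": x_left * 1e6,
                "x1_um": (x_left + span) * 1e6,
                "y0_um": -bar_length / 2.0 * 1e6,
                "y1_um": bar_length / 2.0 * 1e6,
                # centre of the first bar: the modulation phase reference
                "first_bar_centre_um": (x_left + w / 2.0) * 1e6,
            }
        )
        x_left += span + group_gap

    return OpticalMap(
        delta=_downsample(d, f),
        beta=_downsample(b, f),
        voxel_size=voxel_size,
        energy=energy,
        meta={
            "kind": "bar_pattern",
            "bar_groups": groups,
            "radius_um": radius * 1e6,
        },
    )


def soft_tissue_phantom(
    seed: int,
    n_blobs: int = 12,
    gamma_target: float | None = None,
    background: tuple[float, float] = DEFAULT_SUBSTRATE,
    shape: int = 256,
    voxel_size: float = 4e-6,
    radius_fraction: float = 0.42,
    blob_contrast: float = 0.6,
    energy: float = 18.0,
) -> OpticalMap:
    """Smooth random blob phantom satisfying γ = const exactly.

    β is built as a uniform cylinder plus ``n_blobs`` random Gaussian blobs
    (positions, widths and signed amplitudes drawn from a seeded RNG,
    clipped to stay non-negative); δ is then defined as 2k·γ·β, so the
    homogeneity assumption behind single-image phase retrieval holds by
    construction. With ``gamma_target=None`` the background material's own
    δ/(2kβ) ratio is used.
    """
    k = wave_number(energy)
    if gamma_target is None:
        gamma_target = background[0] / (2.0 * k * background[1])
    if gamma_target < 0:
        raise ValueError("gamma_target must be >= 0")
    rng = np.random.default_rng(seed)
    n = shape
    radius = radius_fraction * n * voxel_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) * voxel_size**2
    support = r2 <= radius**2

    beta = np.where(support, background[1], 0.0)
    for _ in range(n_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * 0.75 * np.sqrt(rng.uniform())
        by, bx = c * voxel_size + rad * np.sin(ang), c * voxel_size + rad * np.cos(ang)
        sig = rng.uniform(0.04, 0.16) * radius
        amp = rng.uniform(-blob_contrast, blob_contrast) * background[1]
        g = amp * np.exp(
            -(((yy * voxel_size - by) ** 2 + (xx * voxel_size - bx) ** 2) / (2 * sig**2))
        )
        beta = beta + np.where(support, g, 0.0)
    beta = np.clip(beta, 0.0, None)
    delta = 2.0 * k * gamma_target * beta
    return OpticalMap(
        delta=delta,
        beta=beta,
        voxel_size=voxel_size,
        energy=energy,
        meta={
            "kind": "soft_tissue",
            "seed": seed,
            "n_blobs": n_blobs,
            "gamma_m": gamma_target,
            "radius_um": radius * 1e6,
        },
    )
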