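"""Single-value-threshold derivation and gross-tumor-area generation.

Three threshold families are supported, all expressed as absolute voxel
counts:

* ``cmax_pct`` — percentages (default 15-90 % in 5 % steps) of C_max, the
  maximum single voxel count inside the tumor search region.
* ``cpeak_pct`` — the same percentage grid applied to C_peak, the highest
  27-voxel mean over all fully in-bounds 3x3x3 cubes containing a C_max
  voxel.
* ``liver_multiple`` — k * C_liver_mean + 2 * C_liver_SD for a grid of
  multiples k (default 1.5, 3, 4, 5, 6, 7), with liver statistics taken
  over a 6 mm diameter sphere; k = 1.5 is the PERCIST-style background
  threshold.

A gross tumor area (GTA) is the per-slice mask of all pixels at or above a
threshold; it is deliberately computed over the whole slice, since spill
into surrounding normal tissue and air is exactly what the overestimation
ratio measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .dataio import PetVolume

__all__ = [
    "ThresholdSpec",
    "GrossTumorArea",
    "compute_cmax",
    "compute_cpeak",
    "liver_stats",
    "build_spectrum",
    "make_gta",
    "DEFAULT_PERCENTS",
    "DEFAULT_LIVER_MULTIPLES",
]

DEFAULT_PERCENTS: tuple[float, ...] = tuple(range(15, 95, 5))
DEFAULT_LIVER_MULTIPLES: tuple[float, ...] = (1.5, 3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass(frozen=True)
class ThresholdSpec:
    """An absolute count threshold and where it came from."""

    method: str  # cmax_pct | cpeak_pct | liver_multiple
    parameter: float  # percent, or multiple of liver mean
    absolute_counts: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.parameter <= 0:
            raise ValueError("parameter must be positive")
        if self.absolute_counts < 0:
            raise ValueError("absolute_counts must be >= 0")


@dataclass
class GrossTumorArea:
    mask: np.ndarray  # boolean, PET slice grid
    spec: ThresholdSpec
    section_id: str | None = None


def _check_region(volume: PetVolume, tumor_region: np.ndarray) -> np.ndarray:
    region = np.asarray(tumor_region, dtype=bool)
    if region.shape != volume.shape:
        raise ValueError("tumor_region shape must match the volume")
    if not region.any():
        raise ValueError("tumor_region is empty")
    return region


def compute_cmax(volume: PetVolume, tumor_region: np.ndarray) -> float:
    """Maximum single voxel count within the tumor search region."""
    region = _check_region(volume, tumor_region)
    return float(volume.counts[region].max())


def compute_cpeak(volume: PetVolume, tumor_region: np.ndarray) -> float:
    """Highest 27-voxel mean over 3x3x3 cubes containing a C_max voxel.

    Every voxel attaining C_max is considered; for each, all (up to 27)
    cube placements containing it that lie fully inside the volume are
    enumerated, and the overall maximum cube mean is returned.
    """
    region = _check_region(volume, tumor_region)
    counts = volume.counts
    cmax = counts[region].max()
    argmax = np.argwhere(region & (counts == cmax))
    nx, ny, nz = counts.shape
    best = None
    for vx, vy, vz in argmax:
        for ox, oy, oz in product(range(-2, 1), repeat=3):
            x0, y0, z0 = vx + ox, vy + oy, vz + oz
            if x0 < 0 or y0 < 0 or z0 < 0 or x0 + 3 > nx or y0 + 3 > ny or z0 + 3 > nz:
                continue
            m = counts[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3].mean()
            if best is None or m > best:
                best = float(m)
    if best is None:
        raise ValueError(
            "no fully in-bounds 3x3x3 cube contains a C_max voxel "
            "(volume smaller than 3 voxels along some axis, or C_max on a "
            "boundary of a degenerate grid)"
        )
    return best


def liver_stats(
    volume: PetVolume, center_mm: np.ndarray, diameter_mm: float = 6.0
) -> tuple[float, float]:
    """Mean and SD of voxel counts in a spherical liver ROI.

    Voxels whose centers lie within ``diameter_mm / 2`` of ``center_mm``
    are included; SD is the sample standard deviation (ddof=1).
    """
    cx, cy, cz = np.asarray(center_mm, dtype=float)
    vx, vy, vz = volume.voxel_size_mm
    nx, ny, nz = volume.shape
    X = (np.arange(nx) + 0.5) * vx
    Y = (np.arange(ny) + 0.5) * vy
    Z = (np.arange(nz) + 0.5) * vz
    d2 = (
        (X - cx)[:, None, None] ** 2
        + (Y - cy)[None, :, None] ** 2
        + (Z - cz)[None, None, :] ** 2
    )
    inside = d2 <= (diameter_mm / 2.0) ** 2
    n = int(inside.sum())
    if n == 0:
        raise ValueError("liver sphere contains no voxel centers")
    vals = volume.counts[inside]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    if mean == 0.0:
        warnings.warn("liver ROI contains only zero counts", stacklevel=2)
    return mean, sd


def build_spectrum(
    method: str,
    volume: PetVolume,
    tumor_region: np.ndarray | None = None,
    liver_center_mm: np.ndarray | None = None,
    percents: tuple[float, ...] = DEFAULT_PERCENTS,
    liver_multiples: tuple[float, ...] = DEFAULT_LIVER_MULTIPLES,
    liver_diameter_mm: float = 6.0,
) -> list[ThresholdSpec]:
    """Derive the full threshold spectrum for one method on one volume."""
    if method in ("cmax_pct", "cpeak_pct"):
        if tumor_region is None:
            raise ValueError(f"{method} requires a tumor_region")
        ref = (
            compute_cmax(volume, tumor_region)
            if method == "cmax_pct"
            else compute_cpeak(volume, tumor_region)
        )
        key = "C_max" if method == "cmax_pct" else "C_peak"
        return [
            ThresholdSpec(
                method=method,
                parameter=float(p),
                absolute_counts=float(p) / 100.0 * ref,
                provenance={key: ref},
            )
            for p in percents
        ]
    if method == "liver_multiple":
        if liver_center_mm is None:
            raise ValueError("liver_multiple requires liver_center_mm")
        mean, sd = liver_stats(volume, liver_center_mm, diameter_mm=liver_diameter_mm)
        return [
            ThresholdSpec(
                method=method,
                parameter=float(k),
                absolute_counts=float(k) * mean + 2.0 * sd,
                provenance={"C_liver_mean": mean, "C_liver_SD": sd},
            )
            for k in liver_multiples
        ]
    raise ValueError(f"unknown method {method!r}")


def make_gta(
    pet_slice: np.ndarray, spec: ThresholdSpec, section_id: str | None = None
) -> GrossTumorArea:
    """All pixels at or above the absolute threshold (inclusive)."""
    return GrossTumorArea(
        mask=np.asarray(pet_slice) >= spec.absolute_counts,
        spec=spec,
        section_id=section_id,
    )
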