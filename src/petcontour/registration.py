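"""Fiducial-guided rigid registration and label resampling.

Histology sections are aligned to their PET slice by a least-squares
(Procrustes) rigid fit to corresponding fiducial coordinates, then the fine
label image is resampled onto the fixed 1 mm PET pixel grid by plurality of
overlapped area, with ties broken viable > necrotic > normal > air (the
conservative choice: ambiguous tissue counts as viable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._utils import LABEL_PRIORITY, majority_from_scores
from .dataio import (
    AIR,
    NECROTIC,
    VIABLE,
    HistologySection,
    ManifestEntry,
    PetVolume,
)

__all__ = [
    "RigidTransform2D",
    "RegisteredPair",
    "fit_fiducial_transform",
    "resample_labels",
    "build_pair",
]

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform2D:
    """Planar rotation + translation (+ optional isotropic scale).

    Maps histology mm coordinates to PET mm coordinates:
    ``p' = scale * R(rotation_rad) @ p + translation_mm``.
    """

    rotation_rad: float = 0.0
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(2)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + self.translation_mm

    def inverse(self) -> "RigidTransform2D":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation_rad), np.sin(-self.rotation_rad)
        R_inv = inv_scale * np.array([[c, -s], [s, c]])
        return RigidTransform2D(
            rotation_rad=-self.rotation_rad,
            translation_mm=-R_inv @ self.translation_mm,
            scale=inv_scale,
        )

    @property
    def is_axis_aligned(self) -> bool:
        return abs(np.sin(self.rotation_rad)) < 1e-12 and np.cos(self.rotation_rad) > 0


def fit_fiducial_transform(
    points_histo: np.ndarray,
    points_pet: np.ndarray,
    allow_scale: bool = False,
) -> tuple[RigidTransform2D, float]:
    """Least-squares rigid (or similarity) fit of corresponding 2-D points.

    Returns the transform mapping histology to PET coordinates and the RMS
    residual. Requires >= 2 points per side; coincident source points are a
    degenerate configuration.
    """
    A = np.asarray(points_histo, float).reshape(-1, 2)
    B = np.asarray(points_pet, float).reshape(-1, 2)
    if A.shape != B.shape or A.shape[0] < 2:
        raise ValueError("need >= 2 corresponding points per modality")
    if np.max(np.abs(A - A[0])) < 1e-12:
        raise ValueError("degenerate fiducial configuration: source points coincide")
    muA, muB = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - muA, B - muB
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T  # proper rotation (det = +1)
    if allow_scale:
        scale = float((S @ np.diag([1.0, d]).diagonal()) / (A0**2).sum())
    else:
        scale = 1.0
    rotation = float(np.arctan2(R[1, 0], R[0, 0]))
    translation = muB - scale * R @ muA
    tf = RigidTransform2D(rotation_rad=rotation, translation_mm=translation, scale=scale)
    rms = float(np.sqrt(np.mean(np.sum((tf.apply(A) - B) ** 2, axis=1))))
    return tf, rms


def resample_labels(
    section: HistologySection,
    transform: RigidTransform2D,
    target_pixel_mm: float,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Resample a fine label image onto a coarser target grid.

    Each coarse pixel takes the plurality label by overlapped fine-pixel
    area under ``transform``; ties break viable > necrotic > normal > air.
    For axis-aligned transforms the overlap areas are exact separable
    rectangle intersections; rotated transforms accumulate each fine
    pixel's area at its transformed center (a <= half-fine-pixel
    approximation, negligible at the 8x resolution ratio used here).
    """
    h = section.pixel_size_mm
    if target_pixel_mm < h - 1e-12:
        raise ValueError("target_pixel_mm must be >= section.pixel_size_mm")
    fine = section.labels
    nfx, nfy = fine.shape
    ncx, ncy = target_shape
    V = float(target_pixel_mm)

    if transform.is_axis_aligned:
        s = transform.scale
        tx, ty = transform.translation_mm

        def overlap_matrix(nf: int, nc: int, t: float) -> np.ndarray:
            edges = t + s * h * np.arange(nf + 1)
            lo = np.clip(edges[:-1], 0.0, nc * V)
            hi = np.clip(edges[1:], 0.0, nc * V)
            M = np.zeros((nc, nf))
            for j in range(nf):
                a, b = lo[j], hi[j]
                if b <= a:
                    continue
                k0, k1 = int(a // V), int(min(b // V, nc - 1))
                if b == k1 * V:  # right edge exactly on a bin boundary
                    k1 -= 1
                for k in range(k0, k1 + 1):
                    M[k, j] = min(b, (k + 1) * V) - max(a, k * V)
            return M

        Mx = overlap_matrix(nfx, ncx, tx)
        My = overlap_matrix(nfy, ncy, ty)
        if Mx.sum() == 0 or My.sum() == 0:
            raise ValueError("transform maps the section entirely outside the target frame")
        scores = np.stack(
            [Mx @ (fine == lab).astype(float) @ My.T for lab in LABEL_PRIORITY]
        )
    else:
        centers_x = (np.arange(nfx) + 0.5) * h
        centers_y = (np.arange(nfy) + 0.5) * h
        pts = np.stack(np.meshgrid(centers_x, centers_y, indexing="ij"), axis=-1)
        mapped = transform.apply(pts.reshape(-1, 2))
        ix = np.floor(mapped[:, 0] / V).astype(np.int64)
        iy = np.floor(mapped[:, 1] / V).astype(np.int64)
        ok = (ix >= 0) & (ix < ncx) & (iy >= 0) & (iy < ncy)
        if not ok.any():
            raise ValueError("transform maps the section entirely outside the target frame")
        area = (transform.scale * h) ** 2
        flat = fine.reshape(-1)
        scores = np.zeros((len(LABEL_PRIORITY), ncx, ncy))
        for li, lab in enumerate(LABEL_PRIORITY):
            sel = ok & (flat == lab)
            np.add.at(scores[li], (ix[sel], iy[sel]), area)

    out = majority_from_scores(scores)
    out[scores.sum(axis=0) == 0] = AIR  # coarse pixels the section never covers
    return out


@dataclass
class RegisteredPair:
    """One PET slice and its co-registered coarse histology labels.

    The unit of validation: classification is restricted to the whole tumor
    area on histology (WTA_H = viable plus necrotic pixels); everything
    outside WTA_H only enters through the overestimation ratio.
    """

    pet_slice: np.ndarray
    labels_coarse: np.ndarray
    cluster_id: str
    section_id: str

    def __post_init__(self) -> None:
        if self.pet_slice.shape != self.labels_coarse.shape:
            raise ValueError("pet_slice and labels_coarse must share a grid")

    @property
    def viable_px(self) -> np.ndarray:
        return self.labels_coarse == VIABLE

    @property
    def necrotic_px(self) -> np.ndarray:
        return self.labels_coarse == NECROTIC

    @property
    def wta_px(self) -> np.ndarray:
        return self.viable_px | self.necrotic_px

    @property
    def outside_px(self) -> np.ndarray:
        return ~self.wta_px


def build_pair(
    volume: PetVolume,
    section: HistologySection,
    entry: ManifestEntry,
    allow_scale: bool = False,
) -> RegisteredPair:
    """Extract the paired PET slice, register and resample the section."""
    if not 0 <= entry.pet_slice_index < volume.shape[2]:
        raise ValueError(f"pet_slice_index {entry.pet_slice_index} outside volume")
    if entry.fiducials_histo_mm is not None and entry.fiducials_pet_mm is not None:
        transform, rms = fit_fiducial_transform(
            entry.fiducials_histo_mm, entry.fiducials_pet_mm, allow_scale=allow_scale
        )
        if rms > 1.0:
            logger.warning("pair %s: fiducial RMS residual %.2f mm", entry.section_id, rms)
    else:
        transform = RigidTransform2D()
    pet_slice = volume.slice(entry.pet_slice_index)
    labels = resample_labels(
        section,
        transform,
        target_pixel_mm=float(volume.voxel_size_mm[0]),
        target_shape=pet_slice.shape,
    )
    return RegisteredPair(
        pet_slice=pet_slice,
        labels_coarse=labels,
        cluster_id=entry.cluster_id,
        section_id=entry.section_id,
    )
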