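"""On-disk artifacts and core containers.

Conventions used throughout the package:

* PET volumes are ``(nx, ny, nz)`` arrays of voxel counts with ``z`` the
  cranial-caudal slice index, counted from the most-cranial slice, 0-based.
* The center of voxel ``(i, j, k)`` sits at ``((i + 0.5) v, (j + 0.5) v,
  (k + 0.5) v)`` mm, where ``v`` is the voxel size; histology pixels follow
  the same rule at their own pitch, so both modalities share one mm frame.
* Histology label images use the integer codes in :data:`LABEL_NAMES`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "AIR",
    "NORMAL",
    "NECROTIC",
    "VIABLE",
    "LABEL_NAMES",
    "PetVolume",
    "HistologySection",
    "ManifestEntry",
    "PairingManifest",
    "read_pet_volume",
    "write_pet_volume",
    "read_section",
    "write_section",
    "read_manifest",
    "write_manifest",
]

# Tissue label codes. Order matters for tie-breaking during label
# resampling: higher code wins (viable > necrotic > normal > air).
AIR, NORMAL, NECROTIC, VIABLE = 0, 1, 2, 3
LABEL_NAMES = {AIR: "air", NORMAL: "normal", NECROTIC: "necrotic", VIABLE: "viable"}
_NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


class FormatError(ValueError):
    """A file failed validation; the message names the offending field."""


@dataclass
class PetVolume:
    """A 3-D PET count volume with isotropic-or-not voxel spacing.

    Parameters
    ----------
    counts
        ``(nx, ny, nz)`` nonnegative, finite voxel counts.
    voxel_size_mm
        Positive spacing per axis, mm.
    """

    counts: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise FormatError("counts: expected a 3-D array")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts: non-finite voxel values")
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts: negative voxel values")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any((not np.isfinite(v)) or v <= 0 for v in vs):
            raise FormatError("voxel_size_mm: spacings must be positive and finite")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def slice(self, k: int) -> np.ndarray:
        """Transverse slice ``k`` as an ``(nx, ny)`` array (shared mm frame)."""
        return self.counts[:, :, k]


@dataclass
class HistologySection:
    """One macroscopic cut-surface label image at histology resolution."""

    labels: np.ndarray
    pixel_size_mm: float
    cluster_id: str
    side: str  # "rostral" | "caudal"
    section_id: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("labels: expected a 2-D array")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise FormatError(
                f"labels: unknown codes {sorted(bad)}; allowed {sorted(LABEL_NAMES)} "
                f"({', '.join(f'{k}={v}' for k, v in LABEL_NAMES.items())})"
            )
        if not (np.isfinite(self.pixel_size_mm) and self.pixel_size_mm > 0):
            raise FormatError("pixel_size_mm: must be positive")
        if self.side not in ("rostral", "caudal"):
            raise FormatError(f"side: {self.side!r} not in ('rostral', 'caudal')")

    @property
    def has_tumor(self) -> bool:
        return bool(np.isin(self.labels, (VIABLE, NECROTIC)).any())


@dataclass
class ManifestEntry:
    """Pairing of one histology surface with one PET slice.

    Fiducial coordinates (mm, one row per marker, same order in both
    modalities) guide the rigid registration; omitted => identity.
    """

    section_id: str
    pet_slice_index: int
    cluster_id: str
    fiducials_histo_mm: np.ndarray | None = None
    fiducials_pet_mm: np.ndarray | None = None


@dataclass
class PairingManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.section_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise FormatError("manifest: duplicate section_id")
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.cluster_id] = counts.get(e.cluster_id, 0) + 1
        bad = {c: n for c, n in counts.items() if n > 2}
        if bad:
            raise FormatError(
                f"manifest: cluster_id appears on more than 2 entries: {bad} "
                "(one sectioning position yields at most a rostral and a caudal surface)"
            )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_pet_volume(volume: PetVolume, path: str | Path) -> None:
    affine = np.diag((*volume.voxel_size_mm, 1.0))
    img = nib.Nifti1Image(volume.counts, affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def read_pet_volume(path: str | Path) -> PetVolume:
    try:
        img = nib.load(str(path))
        # nibabel silently repairs some header defects (e.g. negative
        # pixdim); validate the raw on-disk values instead.
        with nib.openers.ImageOpener(str(path), "rb") as f:
            raw = nib.Nifti1Header.from_fileobj(f, check=False)
    except Exception as exc:  # nibabel raises several types for garbled files
        raise FormatError(f"not a readable NIfTI file: {path} ({exc})") from exc
    raw_pixdim = tuple(float(z) for z in raw["pixdim"][1:4])
    if any((not np.isfinite(z)) or z <= 0 for z in raw_pixdim):
        raise FormatError(f"pixdim: non-positive voxel dimension {raw_pixdim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise FormatError(f"pixdim: non-positive voxel dimension {zooms}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return PetVolume(counts=data, voxel_size_mm=zooms)


# ---------------------------------------------------------------------------
# Histology sections: indexed PNG + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_section(section: HistologySection, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(path, section.labels.astype(np.uint8))
    meta = {
        "label_map": {str(k): v for k, v in LABEL_NAMES.items()},
        "pixel_size_mm": section.pixel_size_mm,
        "cluster_id": section.cluster_id,
        "side": section.side,
        "section_id": section.section_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_section(path: str | Path) -> HistologySection:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_mm" not in meta:
        raise FormatError(f"sidecar {sidecar}: missing field 'pixel_size_mm'")
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:  # palette PNGs may expand; collapse identical channels
        labels = labels[..., 0]
    label_map = meta.get("label_map")
    if label_map is not None:
        declared = {int(k): v for k, v in label_map.items()}
        if declared != LABEL_NAMES:
            raise FormatError(f"sidecar {sidecar}: label_map {declared} != {LABEL_NAMES}")
    return HistologySection(
        labels=labels.astype(np.int64),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        cluster_id=str(meta["cluster_id"]),
        side=str(meta["side"]),
        section_id=str(meta["section_id"]),
    )


# ---------------------------------------------------------------------------
# Pairing manifest (JSON)
# ---------------------------------------------------------------------------

def write_manifest(manifest: PairingManifest, path: str | Path) -> None:
    entries = []
    for e in manifest.entries:
        d: dict = {
            "section_id": e.section_id,
            "pet_slice_index": int(e.pet_slice_index),
            "cluster_id": e.cluster_id,
        }
        if e.fiducials_histo_mm is not None:
            d["fiducials_histo_mm"] = np.asarray(e.fiducials_histo_mm).tolist()
        if e.fiducials_pet_mm is not None:
            d["fiducials_pet_mm"] = np.asarray(e.fiducials_pet_mm).tolist()
        entries.append(d)
    payload = {
        "coordinate_convention": "0-based indices; PET slice 0 is most cranial; mm = (index + 0.5) * pitch",
        "entries": entries,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> PairingManifest:
    payload = json.loads(Path(path).read_text())
    entries = []
    for d in payload["entries"]:
        entries.append(
            ManifestEntry(
                section_id=str(d["section_id"]),
                pet_slice_index=int(d["pet_slice_index"]),
                cluster_id=str(d["cluster_id"]),
                fiducials_histo_mm=(
                    np.asarray(d["fiducials_histo_mm"], dtype=float)
                    if "fiducials_histo_mm" in d
                    else None
                ),
                fiducials_pet_mm=(
                    np.asarray(d["fiducials_pet_mm"], dtype=float)
                    if "fiducials_pet_mm" in d
                    else None
                ),
            )
        )
    return PairingManifest(entries=entries)
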