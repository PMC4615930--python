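"""Digital PET/histology phantom.

Emulates the acquisition the validation framework assumes: a rodent-scale
body with a large (>= 3 cm) FDG-avid mammary tumor containing central and
peripheral necrosis, a liver for background-referenced thresholds, skin
fiducial point sources at each transverse sectioning line, a ~2 mm FWHM
scanner point-spread function, and count noise. Each sectioning position
yields a rostral and a caudal cut surface, each paired with the PET slice
at the same cranial-caudal level; the cut surfaces are delivered as
fine-resolution histology label images together with exact coarse ground
truth, so every downstream stage (registration, contouring, classification,
aggregation) can be tested against known truth.

Intensity model, in order: class-mean uptake painted on the label volume;
multiplicative log-normal within-class variability (spatially smooth, see
``heterogeneity_corr_mm``); fiducial point sources; isotropic Gaussian PSF;
count noise. All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from ._utils import block_majority
from .dataio import (
    AIR,
    NECROTIC,
    NORMAL,
    VIABLE,
    HistologySection,
    ManifestEntry,
    PairingManifest,
    PetVolume,
)

__all__ = [
    "Ellipsoid",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "cut_histology_section",
    "tumor_search_region",
    "default_cohort",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid given by center and semi-axes, mm."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def quadric(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        rx, ry, rz = self.radii_mm
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2


@dataclass
class PhantomConfig:
    """Full description of one phantom acquisition.

    Uptake means are voxel counts. Defaults emulate a strongly FDG-avid
    tumor against cold necrosis and a moderately avid liver, with a 2 mm
    FWHM PSF and Poisson counting noise; see the methods note for how the
    ratios were chosen.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 120)
    voxel_size_mm: float = 1.0
    # anatomy (mm). The body is an elliptical cylinder along z.
    body_center_mm: tuple[float, float] = (64.0, 58.0)
    body_radii_mm: tuple[float, float] = (45.0, 35.0)
    body_z_mm: tuple[float, float] = (5.0, 115.0)
    tumor_center_mm: tuple[float, float, float] = (64.0, 86.0, 60.0)
    tumor_radii_mm: tuple[float, float, float] = (15.0, 15.0, 13.0)
    # Central necrosis plus a peripheral lobe close to the tumor surface;
    # the sub-voxel viable shell over the lobe emulates the thin viable
    # rims that fall below scanner resolution in real tumors.
    necrosis_spec: tuple[Ellipsoid, ...] = (
        Ellipsoid((64.0, 86.0, 60.0), (7.0, 7.0, 6.0)),  # central
        Ellipsoid((74.8, 86.0, 60.0), (3.3, 3.3, 2.8)),  # peripheral
    )
    # Viable cords traversing the necrosis (painted after necrosis):
    # sub-resolution viable structures whose partial-volumed PET values
    # fall well below the plateau, as in real heterogeneous tumors.
    viable_cords: tuple[Ellipsoid, ...] = (
        Ellipsoid((64.5, 86.5, 60.0), (0.5, 0.5, 5.2)),
        Ellipsoid((61.5, 83.5, 60.0), (0.75, 0.75, 4.6)),
    )
    liver: Ellipsoid = Ellipsoid((40.0, 48.0, 30.0), (13.0, 10.0, 13.0))
    # uptake (counts/voxel)
    uptake_viable_mean: float = 300.0
    uptake_necrotic_mean: float = 30.0
    uptake_normal_mean: float = 15.0
    uptake_liver_mean: float = 25.0
    uptake_sd_fraction: float = 0.2
    heterogeneity_corr_mm: float = 5.0
    # degradation
    psf_fwhm_mm: float = 2.0
    noise_model: Literal["none", "gaussian", "poisson"] = "poisson"
    # sectioning / markers
    n_sections: int = 4
    section_planes: tuple[int, ...] | None = None  # explicit cut slice indices
    fiducials_per_section: int = 2
    fiducial_intensity: float = 10000.0
    # Hand-spotted radiotracer droplets vary in activity; log-normal CV.
    fiducial_intensity_cv: float = 0.3
    fiducial_angles_deg: tuple[float, ...] = (215.0, 325.0)
    # histology digitization
    histology_pixel_mm: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if self.voxel_size_mm <= 0 or self.histology_pixel_mm <= 0:
            raise ValueError("voxel and histology pixel sizes must be positive")
        if not (self.uptake_viable_mean > self.uptake_necrotic_mean >= 0):
            raise ValueError(
                "require uptake_viable_mean > uptake_necrotic_mean >= 0 "
                "(viable tissue is FDG-avid, necrosis is cold)"
            )
        if self.section_planes is None and not 1 <= self.n_sections:
            raise ValueError("n_sections must be >= 1")
        if self.uptake_sd_fraction < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("uptake_sd_fraction and psf_fwhm_mm must be >= 0")

    @property
    def tumor(self) -> Ellipsoid:
        return Ellipsoid(self.tumor_center_mm, self.tumor_radii_mm)

    @property
    def size_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.grid_shape)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one phantom volume."""

    label_volume: np.ndarray  # (nx, ny, nz) codes {air, normal, necrotic, viable}
    fine_label_sections: list[HistologySection]
    fiducial_coords_pet: dict[str, np.ndarray]  # section_id -> (m, 2) mm
    fiducial_coords_histo: dict[str, np.ndarray]
    section_plane_indices: dict[str, int]  # section_id -> PET slice index
    cluster_ids: dict[str, str]
    config: PhantomConfig
    liver_mask: np.ndarray

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, (NECROTIC, VIABLE))

    def section(self, section_id: str) -> HistologySection:
        for s in self.fine_label_sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def manifest(self) -> PairingManifest:
        entries = [
            ManifestEntry(
                section_id=s.section_id,
                pet_slice_index=self.section_plane_indices[s.section_id],
                cluster_id=s.cluster_id,
                fiducials_histo_mm=self.fiducial_coords_histo[s.section_id],
                fiducials_pet_mm=self.fiducial_coords_pet[s.section_id],
            )
            for s in self.fine_label_sections
        ]
        return PairingManifest(entries=entries)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _axis_centers(n: int, pitch: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pitch


def _paint_plane(config: PhantomConfig, x: np.ndarray, y: np.ndarray, z_mm: float):
    """Label one transverse plane sampled at the given pixel centers.

    Returns ``(labels, liver_mask)``; painting order air -> body (normal) ->
    tumor (viable) -> necrosis, later classes overwriting earlier ones.
    """
    X, Y = x[:, None], y[None, :]
    labels = np.full((x.size, y.size), AIR, dtype=np.int64)
    bcx, bcy = config.body_center_mm
    brx, bry = config.body_radii_mm
    in_body = (((X - bcx) / brx) ** 2 + ((Y - bcy) / bry) ** 2 <= 1.0) & (
        config.body_z_mm[0] <= z_mm <= config.body_z_mm[1]
    )
    labels[in_body] = NORMAL
    liver = config.liver.quadric(X, Y, z_mm) <= 1.0
    labels[config.tumor.quadric(X, Y, z_mm) <= 1.0] = VIABLE
    for nec in config.necrosis_spec:
        labels[nec.quadric(X, Y, z_mm) <= 1.0] = NECROTIC
    for cord in config.viable_cords:
        labels[cord.quadric(X, Y, z_mm) <= 1.0] = VIABLE
    liver &= labels == NORMAL
    return labels, liver


def _label_volume(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    v = config.voxel_size_mm
    x, y = _axis_centers(nx, v), _axis_centers(ny, v)
    labels = np.empty((nx, ny, nz), dtype=np.int64)
    liver = np.empty((nx, ny, nz), dtype=bool)
    for k in range(nz):
        labels[:, :, k], liver[:, :, k] = _paint_plane(config, x, y, (k + 0.5) * v)
    return labels, liver


def _rasterize_fine(config: PhantomConfig, plane_index: int) -> np.ndarray:
    """Histology-resolution labels of the cut surface at a PET slice plane."""
    h = config.histology_pixel_mm
    nxf = int(round(config.size_mm[0] / h))
    nyf = int(round(config.size_mm[1] / h))
    z_mm = (plane_index + 0.5) * config.voxel_size_mm
    labels, _ = _paint_plane(config, _axis_centers(nxf, h), _axis_centers(nyf, h), z_mm)
    return labels


def _section_cuts(config: PhantomConfig) -> list[int]:
    if config.section_planes is not None:
        return [int(p) for p in config.section_planes]
    # Spread sectioning positions over the central portion of the tumor.
    cz, rz = config.tumor_center_mm[2], config.tumor_radii_mm[2]
    v = config.voxel_size_mm
    lo, hi = (cz - 0.55 * rz) / v, (cz + 0.55 * rz) / v
    cuts = np.unique(np.round(np.linspace(lo, hi, config.n_sections)).astype(int))
    return [int(c) for c in cuts]


def _validate_geometry(config: PhantomConfig) -> None:
    size = config.size_mm
    c, r = np.asarray(config.tumor_center_mm), np.asarray(config.tumor_radii_mm)
    if np.any(c - r < 0) or np.any(c + r > np.asarray(size)):
        raise ValueError("tumor extends outside the image grid")
    # Necrosis must lie inside the tumor: check a dense surface sampling.
    th = np.linspace(0, 2 * np.pi, 72)
    ph = np.linspace(0, np.pi, 37)
    u = np.stack(
        [
            np.outer(np.cos(th), np.sin(ph)),
            np.outer(np.sin(th), np.sin(ph)),
            np.outer(np.ones_like(th), np.cos(ph)),
        ],
        axis=-1,
    )  # (72, 37, 3) unit directions
    for nec in config.necrosis_spec:
        pts = np.asarray(nec.center_mm) + u * np.asarray(nec.radii_mm)
        q = config.tumor.quadric(pts[..., 0], pts[..., 1], pts[..., 2])
        if np.any(q > 1.0 + 1e-9):
            raise ValueError(f"necrosis region {nec} is not inside the tumor")
    for cord in config.viable_cords:
        pts = np.asarray(cord.center_mm) + u * np.asarray(cord.radii_mm)
        q = config.tumor.quadric(pts[..., 0], pts[..., 1], pts[..., 2])
        if np.any(q > 1.0 + 1e-9):
            raise ValueError(f"viable cord {cord} is not inside the tumor")


def _fiducial_voxels(config: PhantomConfig) -> list[tuple[int, int]]:
    """In-plane voxel indices of the skin fiducials (shared by all planes)."""
    v = config.voxel_size_mm
    bcx, bcy = config.body_center_mm
    brx, bry = config.body_radii_mm
    out = []
    angles = config.fiducial_angles_deg[: config.fiducials_per_section]
    for ang in angles:
        t = np.deg2rad(ang)
        px = bcx + 0.97 * brx * np.cos(t)
        py = bcy + 0.97 * bry * np.sin(t)
        out.append((int(px / v), int(py / v)))
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> tuple[PetVolume, PhantomTruth]:
    """Build one phantom volume and its exact ground truth.

    Deterministic: the same config (including ``seed``) yields bit-identical
    outputs.
    """
    _validate_geometry(config)
    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_noise, rng_fid = (np.random.default_rng(s) for s in ss.spawn(3))

    labels, liver_mask = _label_volume(config)
    v = config.voxel_size_mm
    ratio = config.voxel_size_mm / config.histology_pixel_mm
    integer_ratio = abs(ratio - round(ratio)) < 1e-9

    # --- sections ------------------------------------------------------
    sections: list[HistologySection] = []
    plane_of: dict[str, int] = {}
    cluster_of: dict[str, str] = {}
    fid_pet: dict[str, np.ndarray] = {}
    fid_histo: dict[str, np.ndarray] = {}
    fid_xy = _fiducial_voxels(config)
    cuts = _section_cuts(config)
    for i, cut in enumerate(cuts):
        cluster = f"pos{i + 1}"
        marker_mm = np.array([[(ix + 0.5) * v, (iy + 0.5) * v] for ix, iy in fid_xy])
        for side, plane in (("rostral", cut), ("caudal", cut + 1)):
            fine = _rasterize_fine(config, plane)
            sid = f"{cluster}-{side}"
            sections.append(
                HistologySection(
                    labels=fine,
                    pixel_size_mm=config.histology_pixel_mm,
                    cluster_id=cluster,
                    side=side,
                    section_id=sid,
                )
            )
            plane_of[sid] = plane
            cluster_of[sid] = cluster
            fid_pet[sid] = marker_mm.copy()
            fid_histo[sid] = marker_mm.copy()
            if integer_ratio:
                # Keep coarse truth exactly consistent with the cut surface.
                labels[:, :, plane] = block_majority(fine, int(round(ratio)))

    # --- uptake ---------------------------------------------------------
    means = np.zeros(4)
    means[AIR] = 0.0
    means[NORMAL] = config.uptake_normal_mean
    means[NECROTIC] = config.uptake_necrotic_mean
    means[VIABLE] = config.uptake_viable_mean
    values = means[labels]
    values[liver_mask] = config.uptake_liver_mean

    if config.uptake_sd_fraction > 0:
        g = rng_field.standard_normal(values.shape)
        if config.heterogeneity_corr_mm > 0:
            g = ndimage.gaussian_filter(g, sigma=config.heterogeneity_corr_mm / v)
        g /= g.std()
        s_ln = np.sqrt(np.log1p(config.uptake_sd_fraction**2))
        values *= np.exp(s_ln * g - 0.5 * s_ln**2)

    # Fiducials are physical 18F point sources: they see the same PSF and
    # noise as tissue activity, and their activities vary marker to marker.
    s_fid = np.sqrt(np.log1p(config.fiducial_intensity_cv**2))
    for i, cut in enumerate(cuts):
        for ix, iy in fid_xy:
            activity = config.fiducial_intensity * np.exp(
                s_fid * rng_fid.standard_normal() - 0.5 * s_fid**2
            )
            values[ix, iy, cut] += activity

    if config.psf_fwhm_mm > 0:
        sigma = config.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        values = ndimage.gaussian_filter(values, sigma=sigma, mode="constant")

    if config.noise_model == "poisson":
        values = rng_noise.poisson(values).astype(np.float64)
    elif config.noise_model == "gaussian":
        values = np.clip(values + rng_noise.normal(0.0, np.sqrt(values)), 0.0, None)
    elif config.noise_model != "none":
        raise ValueError(f"unknown noise_model {config.noise_model!r}")

    volume = PetVolume(counts=values, voxel_size_mm=(v, v, v))
    truth = PhantomTruth(
        label_volume=labels,
        fine_label_sections=sections,
        fiducial_coords_pet=fid_pet,
        fiducial_coords_histo=fid_histo,
        section_plane_indices=plane_of,
        cluster_ids=cluster_of,
        config=config,
        liver_mask=liver_mask,
    )
    return volume, truth


def cut_histology_section(
    truth: PhantomTruth, plane_index: int, side: str
) -> HistologySection:
    """Return the fine-resolution cut surface at a sectioning plane.

    A plane through normal tissue only yields a section with zero tumor
    pixels (``section.has_tumor`` is False); that is flagged, not an error.
    """
    for s in truth.fine_label_sections:
        if truth.section_plane_indices[s.section_id] == plane_index and s.side == side:
            return s
    raise ValueError(
        f"plane {plane_index} ({side}) is not among the phantom's sectioning "
        f"planes {sorted(set(truth.section_plane_indices.values()))}"
    )


def tumor_search_region(truth: PhantomTruth, margin_mm: float = 3.0) -> np.ndarray:
    """Tumor mask dilated by a safety margin: the C_max search region."""
    if margin_mm <= 0:
        return truth.tumor_mask
    r = margin_mm / truth.config.voxel_size_mm
    n = int(np.ceil(r))
    zz, yy, xx = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
    ball = xx**2 + yy**2 + zz**2 <= r**2
    return ndimage.binary_dilation(truth.tumor_mask, structure=ball)


def default_cohort(n_phantoms: int = 8, seed: int = 0) -> list[PhantomConfig]:
    """Configs for a study-like cohort: 8 animals, 3-5 sections each.

    Geometry is jittered deterministically per phantom; uptake ratios and
    degradation settings are the shipped defaults.
    """
    base = PhantomConfig()
    n_sections_cycle = (4, 3, 5, 4, 5, 3, 4, 5)
    configs = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_phantoms)):
        rng = np.random.default_rng(child)
        rx, ry = 13.5 + 3.0 * rng.random(2)
        rz = 11.5 + 3.0 * rng.random()
        core = 6.0 + 1.5 * rng.random()
        # Peripheral lobe near the surface: leaves a thin viable shell.
        lobe_dir = rng.random() * 2 * np.pi
        lobe_r = (0.20 + 0.03 * rng.random()) * min(rx, ry)
        lobe_off = np.array([np.cos(lobe_dir), np.sin(lobe_dir), 0.0]) * (
            0.72 * np.array([rx, ry, rz])
        )
        cx, cy, cz = base.tumor_center_mm
        # Two sub-resolution cords, thin and thick, centered on voxel
        # centers so their cross-sections dominate a single 1 mm pixel.
        cord_specs = []
        for cord_r in (0.48 + 0.06 * rng.random(), 0.72 + 0.1 * rng.random()):
            ang = rng.random() * 2 * np.pi
            off = (core - cord_r - 1.5) * (0.3 + 0.3 * rng.random())
            ox = np.floor(cx + off * np.cos(ang)) + 0.5
            oy = np.floor(cy + off * np.sin(ang)) + 0.5
            cord_specs.append(
                Ellipsoid((ox, oy, cz), (cord_r, cord_r, core * 0.75))
            )
        configs.append(
            replace(
                base,
                tumor_radii_mm=(rx, ry, rz),
                necrosis_spec=(
                    Ellipsoid((cx, cy, cz), (core, core, core * 0.85)),
                    Ellipsoid(
                        (cx + lobe_off[0], cy + lobe_off[1], cz + lobe_off[2]),
                        (lobe_r, lobe_r, lobe_r * 0.85),
                    ),
                ),
                viable_cords=tuple(cord_specs),
                n_sections=n_sections_cycle[i % len(n_sections_cycle)],
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return configs
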