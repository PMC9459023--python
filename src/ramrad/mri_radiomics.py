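"""Co-located mpMRI radiomics.

Each inspected tissue site, recorded in intraoperative TRUS coordinates,
is mapped back into the preoperative MRI frame through the inverse of the
MRI->TRUS registration transform, and 48 radiomics features are computed
on a 5-mm-radius spherical region of interest in each of the three
co-registered sequences (T2, ADC, b2000): 8 first-order intensity
statistics and 8 gray-level co-occurrence (GLCM) texture statistics per
sequence.  Feature identifiers follow a fixed grid: r1-r16 on T2,
r17-r32 on ADC, r33-r48 on b2000, first-order before GLCM within each
sequence (so e.g. r17 is ADC Energy and r46 is b2000 Difference entropy).

Geometry conventions: volumes are axis-aligned; world (mm) and voxel
(0-based index) coordinates are related by ``world = origin + index *
spacing``; ROI membership is center-in-sphere with the Euclidean
distance evaluated in physical millimetres, so grid anisotropy is
respected.

GLCM construction: distance-1 co-occurrences over the 13 unique 3-D
direction offsets, matrices symmetrized and normalized per direction,
features averaged over directions (the standard aggregation for
rotationally unprejudiced texture).  Intensities are discretized with a
fixed bin width anchored at the ROI minimum; first-order Entropy and
Uniformity share that discretization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MODALITIES = ("T2", "ADC", "b2000")

FIRST_ORDER_NAMES = (
    "Energy",
    "Total energy",
    "Entropy",
    "Mean",
    "Median",
    "Standard deviation",
    "Mean absolute deviation",
    "Uniformity",
)

GLCM_NAMES = (
    "Auto correlation",
    "Cluster shade",
    "Contrast",
    "Correlation",
    "Inverse difference",
    "Difference entropy",
    "Joint entropy",
    "Joint energy",
)

#: 13 unique direction offsets covering all distance-1 3-D neighbour pairs
#: (the other 13 are their negations, accounted for by symmetrization).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


def feature_identifiers() -> dict[str, tuple[str, str, str]]:
    """Map r1..r48 -> (modality, group, feature name), per the fixed layout."""
    mapping: dict[str, tuple[str, str, str]] = {}
    i = 1
    for modality in MODALITIES:
        for name in FIRST_ORDER_NAMES:
            mapping[f"r{i}"] = (modality, "First order", name)
            i += 1
        for name in GLCM_NAMES:
            mapping[f"r{i}"] = (modality, "GLCM", name)
            i += 1
    return mapping


@dataclass(frozen=True)
class MriVolume:
    """One modality's 3-D intensity grid with physical geometry."""

    modality: str
    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.intensities, dtype=float)
        spacing = np.asarray(self.spacing_mm, dtype=float)
        origin = np.asarray(self.origin_mm, dtype=float)
        if grid.ndim != 3 or grid.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("spacing must be three positive values")
        if origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not np.all(np.isfinite(grid)):
            raise ValueError("non-finite intensity in volume")
        object.__setattr__(self, "intensities", grid)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    def world_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(point_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def contains(self, point_mm: np.ndarray, margin_mm: float = 0.0) -> bool:
        idx = self.world_to_index(point_mm)
        lo = margin_mm / self.spacing_mm
        hi = np.array(self.intensities.shape) - 1 - lo
        return bool(np.all(idx >= lo) and np.all(idx <= hi))


@dataclass(frozen=True)
class CoRegistration:
    """Affine MRI->TRUS registration (homogeneous 4x4, mm to mm)."""

    mri_to_trus: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.mri_to_trus, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
            raise ValueError("registration transform is singular")
        object.__setattr__(self, "mri_to_trus", mat)

    def apply(self, point_mm: np.ndarray) -> np.ndarray:
        """MRI -> TRUS."""
        p = np.append(np.asarray(point_mm, dtype=float), 1.0)
        return (self.mri_to_trus @ p)[:3]


@dataclass(frozen=True)
class RoiSample:
    """Voxels of one volume whose centers fall inside a spherical ROI."""

    voxel_indices: np.ndarray  # (n, 3) int
    intensities: np.ndarray  # (n,)
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        if len(self.intensities) == 0:
            raise ValueError("empty ROI")


class EmptyRoiError(ValueError):
    """Spherical ROI contains no voxel centers."""


# ---------------------------------------------------------------------------
# Site co-location
# ---------------------------------------------------------------------------

def map_trus_to_mri(point_mm: np.ndarray, reg: CoRegistration) -> np.ndarray:
    """Invert the MRI->TRUS registration to co-locate a TRUS point on MRI."""
    inv = np.linalg.inv(reg.mri_to_trus)
    p = np.append(np.asarray(point_mm, dtype=float), 1.0)
    return (inv @ p)[:3]


# ---------------------------------------------------------------------------
# ROI extraction and discretization
# ---------------------------------------------------------------------------

def spherical_roi(vol: MriVolume, center_mm: np.ndarray, radius_mm: float = 5.0) -> RoiSample:
    """Voxels whose centers lie within ``radius_mm`` of ``center_mm``.

    Distances are Euclidean in physical mm, so the voxel footprint of the
    same radius differs per modality with anisotropic spacing.
    """
    center = np.asarray(center_mm, dtype=float)
    shape = np.array(vol.intensities.shape)
    center_idx = vol.world_to_index(center)
    half = radius_mm / vol.spacing_mm
    lo = np.maximum(np.floor(center_idx - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_idx + half).astype(int), shape - 1)
    if np.any(lo > hi):
        raise EmptyRoiError(f"ROI center {center} outside {vol.modality} volume")

    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = vol.origin_mm + idx * vol.spacing_mm
    inside = np.einsum("ij,ij->i", world - center, world - center) <= radius_mm**2
    if not inside.any():
        raise EmptyRoiError(
            f"no voxel center within {radius_mm} mm of {center} in {vol.modality}"
        )
    idx = idx[inside]
    vals = vol.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
    return RoiSample(
        voxel_indices=idx,
        intensities=vals,
        voxel_volume_mm3=float(np.prod(vol.spacing_mm)),
    )


def discretize(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretization anchored at the minimum.

    Level ``floor((x - min) / bin_width) + 1``; levels start at 1 and the
    number of levels is the maximum level reached.  Adding a constant to
    all intensities leaves the levels unchanged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    levels = np.floor((values - values.min()) / bin_width).astype(int) + 1
    return levels, int(levels.max())


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def first_order_features(roi: RoiSample, bin_width: float = 25.0) -> dict[str, float]:
    """The 8 first-order intensity statistics.

    Energy is the raw sum of squares; Total energy scales it by the voxel
    volume; Entropy and Uniformity are computed on the fixed-bin-width
    discretized histogram (base-2 entropy); the standard deviation is the
    population (divisor n) form.
    """
    x = roi.intensities
    mean = float(x.mean())
    levels, n_levels = discretize(x, bin_width)
    p = np.bincount(levels, minlength=n_levels + 1)[1:] / len(x)
    pnz = p[p > 0]
    return {
        "Energy": float(np.sum(x**2)),
        "Total energy": float(roi.voxel_volume_mm3 * np.sum(x**2)),
        "Entropy": float(-np.sum(pnz * np.log2(pnz))),
        "Mean": mean,
        "Median": float(np.median(x)),
        "Standard deviation": float(x.std(ddof=0)),
        "Mean absolute deviation": float(np.mean(np.abs(x - mean))),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(
    levels_grid: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[tuple[int, int, int], np.ndarray]:
    """Per-direction symmetric normalized co-occurrence matrices.

    ``levels_grid`` holds integer levels (1..n_levels) on a dense 3-D
    grid; ``mask`` marks the in-ROI voxels.  For each direction offset
    ``d`` the matrix counts in-mask voxel pairs ``(v, v + distance*d)``,
    is symmetrized by adding its transpose, and normalized to sum 1.
    Directions with no valid pair are dropped; if no direction has a
    valid pair, a ``ValueError`` is raised.
    """
    levels_grid = np.asarray(levels_grid)
    mask = np.asarray(mask, dtype=bool)
    if levels_grid.shape != mask.shape:
        raise ValueError("levels grid and mask shapes differ")
    out: dict[tuple[int, int, int], np.ndarray] = {}
    shape = levels_grid.shape
    for d in directions:
        off = tuple(distance * c for c in d)
        src_sl, dst_sl = [], []
        valid = True
        for k in range(3):
            o = off[k]
            if abs(o) >= shape[k]:
                valid = False
                break
            if o >= 0:
                src_sl.append(slice(0, shape[k] - o))
                dst_sl.append(slice(o, shape[k]))
            else:
                src_sl.append(slice(-o, shape[k]))
                dst_sl.append(slice(0, shape[k] + o))
        if not valid:
            continue
        src_sl, dst_sl = tuple(src_sl), tuple(dst_sl)
        pair_ok = mask[src_sl] & mask[dst_sl]
        if not pair_ok.any():
            continue
        a = levels_grid[src_sl][pair_ok]
        b = levels_grid[dst_sl][pair_ok]
        counts = np.zeros((n_levels, n_levels))
        np.add.at(counts, (a - 1, b - 1), 1.0)
        counts = counts + counts.T
        out[d] = counts / counts.sum()
    if not out:
        raise ValueError("no in-mask voxel pair in any direction")
    return out


def glcm_features(matrices: dict[tuple[int, int, int], np.ndarray]) -> dict[str, float]:
    """The 8 GLCM statistics, averaged over directions.

    For a single gray level the marginal SDs vanish and Correlation is
    defined as 1 (perfectly predictable texture); this degenerate case is
    logged once per call.
    """
    per_dir = {name: [] for name in GLCM_NAMES}
    degenerate = False
    for P in matrices.values():
        n = P.shape[0]
        i = np.arange(1, n + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi = P.sum(axis=1)
        mu_i = float(np.sum(i * pi))
        sigma_i = float(np.sqrt(np.sum((i - mu_i) ** 2 * pi)))
        # symmetric matrix: both marginals coincide
        mu_j, sigma_j = mu_i, sigma_i

        autocorr = float(np.sum(ii * jj * P))
        shade = float(np.sum((ii + jj - mu_i - mu_j) ** 3 * P))
        contrast = float(np.sum((ii - jj) ** 2 * P))
        if sigma_i * sigma_j == 0:
            degenerate = True
            correlation = 1.0
        else:
            correlation = float((np.sum(ii * jj * P) - mu_i * mu_j) / (sigma_i * sigma_j))
        inv_diff = float(np.sum(P / (1.0 + np.abs(ii - jj))))
        p_diff = np.zeros(n)
        np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
        pdnz = p_diff[p_diff > 0]
        diff_entropy = float(-np.sum(pdnz * np.log2(pdnz)))
        pnz = P[P > 0]
        joint_entropy = float(-np.sum(pnz * np.log2(pnz)))
        joint_energy = float(np.sum(P**2))

        for name, val in zip(
            GLCM_NAMES,
            (autocorr, shade, contrast, correlation, inv_diff, diff_entropy, joint_entropy, joint_energy),
        ):
            per_dir[name].append(val)
    if degenerate:
        logger.info("single-level GLCM: Correlation defined as 1")
    return {name: float(np.mean(vals)) for name, vals in per_dir.items()}


def _roi_glcm_features(vol: MriVolume, roi: RoiSample, bin_width: float) -> dict[str, float]:
    """Discretize an ROI, embed it in its bounding box, and run the GLCM."""
    levels, n_levels = discretize(roi.intensities, bin_width)
    lo = roi.voxel_indices.min(axis=0)
    hi = roi.voxel_indices.max(axis=0)
    shape = tuple(hi - lo + 1)
    grid = np.zeros(shape, dtype=int)
    mask = np.zeros(shape, dtype=bool)
    rel = roi.voxel_indices - lo
    grid[rel[:, 0], rel[:, 1], rel[:, 2]] = levels
    mask[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    return glcm_features(glcm_matrix(grid, mask, n_levels))


# ---------------------------------------------------------------------------
# Per-site feature vector
# ---------------------------------------------------------------------------

def radiomics_vector(
    trus_point_mm: np.ndarray,
    volumes: dict[str, MriVolume],
    reg: CoRegistration,
    radius_mm: float = 5.0,
    bin_width: float | dict[str, float] = 25.0,
) -> dict[str, float]:
    """48 radiomics values keyed r1..r48 for one site.

    The TRUS-frame site coordinate is mapped to MRI via the inverse
    registration; per modality a 5-mm spherical ROI is extracted and the
    8 first-order plus 8 GLCM statistics computed.  ``bin_width`` may be
    a single width or a per-modality mapping.
    """
    mri_point = map_trus_to_mri(trus_point_mm, reg)
    values: dict[str, float] = {}
    i = 1
    for modality in MODALITIES:
        if modality not in volumes:
            raise ValueError(f"missing volume for modality {modality}")
        vol = volumes[modality]
        bw = bin_width[modality] if isinstance(bin_width, dict) else bin_width
        try:
            roi = spherical_roi(vol, mri_point, radius_mm)
        except EmptyRoiError as err:
            raise EmptyRoiError(f"site ROI outside {modality} volume: {err}") from err
        fo = first_order_features(roi, bw)
        gl = _roi_glcm_features(vol, roi, bw)
        for name in FIRST_ORDER_NAMES:
            values[f"r{i}"] = fo[name]
            i += 1
        for name in GLCM_NAMES:
            values[f"r{i}"] = gl[name]
            i += 1
    return values
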