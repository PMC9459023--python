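"""Synthetic multimodal cohort generator.

No clinical data accompany the study design this pipeline implements, so
this module generates a fully labeled stand-in cohort with the same
statistical skeleton: per patient, a triplet of co-registered MRI volumes
(T2 at 1x1x1 mm, ADC at 1.8x1.8x4 mm, b2000 at 2.6x2.6x5 mm) containing a
spherical lesion; per inspected site, 50-100 replicate raw Raman spectra
in both the fingerprint and high-wavenumber regions, a TRUS-frame
coordinate with a per-patient MRI<->TRUS rigid transform, and a histology
record (Gleason pair, ISUP grade group, high-grade percentage).

Class structure is injected through two kinds of knobs:

* ``peak_bands`` — Gaussian Raman peaks with class-dependent amplitudes.
  The defaults plant benign-dominant peaks at the phenylalanine band
  (994/1007 cm^-1), the collagen/nucleic-acid band (1334 cm^-1) and the
  lipid/protein band (1766/1772 cm^-1), plus class-neutral peaks in both
  regions; the high-wavenumber region carries no class contrast by
  default.
* ``lesion_contrast`` — the fractional ADC drop inside the lesion; the
  in-lesion b2000 texture decorrelation scales with the same knob, so
  ``lesion_contrast=0`` yields a class-null imaging cohort.  T2 carries
  no planted contrast (mirroring the non-contribution of T2 features in
  the downstream selection).

Randomness is hierarchical (cohort -> patient -> site -> region) via
``numpy.random.SeedSequence`` spawning, so all outputs are a pure
function of (config, seed) and one site's draws do not perturb another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mri_radiomics import MODALITIES, CoRegistration, MriVolume
from .raman_preprocess import RamanAcquisitionSet

try:  # SciPy's Gaussian filter is used for spatially correlated noise
    from scipy.ndimage import gaussian_filter
except ImportError:  # pragma: no cover
    raise

#: ISUP grade-group mapping from (primary, secondary) Gleason patterns.
ISUP_FROM_GLEASON = {
    (0, 0): 0,
    (3, 3): 1,
    (3, 4): 2,
    (4, 3): 3,
    (4, 4): 4,
    (3, 5): 4,
    (5, 3): 4,
    (4, 5): 5,
    (5, 4): 5,
    (5, 5): 5,
}

#: Canonical Gleason pair used when generating a site of a given grade group.
GLEASON_FROM_ISUP = {0: (0, 0), 1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}

#: Fixed voxel spacings (mm) of the three sequences.
MODALITY_SPACING = {
    "T2": (1.0, 1.0, 1.0),
    "ADC": (1.8, 1.8, 4.0),
    "b2000": (2.6, 2.6, 5.0),
}


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class PeakBand:
    """One Gaussian Raman band with class-dependent amplitude.

    ``grade_response`` sets how the amplitude moves from the benign to
    the tumor value across ISUP grade groups: 0 is a step (full tumor
    amplitude for any grade), 1 is linear in grade (GG1 retains 75% of
    the benign-tumor difference, GG4 none).  Giving the planted bands a
    mix of step and graded responses reflects that different molecular
    signatures track tumor presence and tumor aggressiveness to
    different degrees, and makes nearby discriminative bands carry
    complementary rather than duplicated class information.
    """

    center_cm1: float
    width_cm1: float  # Gaussian sigma
    amplitude_benign: float
    amplitude_tumor: float
    grade_response: float = 0.0

    def amplitude_for_grade(self, isup_gg: int) -> float:
        if isup_gg == 0:
            return self.amplitude_benign
        fade = self.grade_response * max(0, 4 - isup_gg) / 4.0
        return self.amplitude_tumor + (self.amplitude_benign - self.amplitude_tumor) * fade


@dataclass(frozen=True)
class TextureParams:
    """Spatial texture of one MRI sequence.

    ``corr_length_mm`` sets the Gaussian correlation length of the
    stationary background noise; ``lesion_intensity_scale`` is the
    fractional intensity change inside the lesion per unit of the
    config-level ``lesion_contrast`` (negative = hypointense);
    ``lesion_texture_scale`` decorrelates the in-lesion noise (blend
    weight ``min(1, lesion_texture_scale * lesion_contrast)`` toward a
    white field of the same SD), a variance-preserving heterogeneity
    that moves GLCM texture statistics while leaving the first-order
    intensity marginals untouched.
    """

    base_intensity: float
    noise_sd: float
    corr_length_mm: float
    lesion_intensity_scale: float
    lesion_texture_scale: float = 0.0
    patient_gain_sd: float = 0.08


#: Class contrast is confined to the ADC intensity drop and the b2000
#: texture decorrelation; T2 carries no planted contrast.
DEFAULT_TEXTURE = {
    "T2": TextureParams(400.0, 40.0, 1.5, 0.0, patient_gain_sd=0.08),
    "ADC": TextureParams(1400.0, 120.0, 4.0, -1.0, patient_gain_sd=0.07),
    "b2000": TextureParams(120.0, 30.0, 5.0, 0.0, lesion_texture_scale=2.5, patient_gain_sd=0.04),
}

#: Default planted bands: benign-dominant discriminative fingerprint peaks
#: plus class-neutral peaks in both regions (high wavenumber carries no
#: class contrast by default).
DEFAULT_PEAK_BANDS = (
    PeakBand(994.0, 3.0, 1.70, 0.55),
    PeakBand(1007.0, 3.0, 1.90, 0.45, grade_response=1.0),
    PeakBand(1334.0, 4.0, 1.45, 0.45, grade_response=0.4),
    PeakBand(1766.0, 3.0, 1.20, 0.42, grade_response=0.25),
    PeakBand(1772.0, 3.0, 1.30, 0.25, grade_response=1.0),
    # class-neutral fingerprint bands (a realistic soft-tissue complement;
    # keeping the spectrum rich also keeps the SNV denominator nearly
    # class-independent, as in real spectra)
    PeakBand(504.0, 6.0, 0.80, 0.80),
    PeakBand(621.0, 5.0, 0.64, 0.64),
    PeakBand(643.0, 6.0, 0.72, 0.72),
    PeakBand(720.0, 6.0, 0.96, 0.96),
    PeakBand(758.0, 5.0, 1.12, 1.12),
    PeakBand(830.0, 6.0, 1.28, 1.28),
    PeakBand(853.0, 6.0, 1.44, 1.44),
    PeakBand(877.0, 6.0, 1.12, 1.12),
    PeakBand(935.0, 6.0, 0.96, 0.96),
    PeakBand(1031.0, 5.0, 1.44, 1.44),
    PeakBand(1080.0, 7.0, 1.44, 1.44),
    PeakBand(1100.0, 6.0, 0.80, 0.80),
    PeakBand(1127.0, 6.0, 0.96, 0.96),
    PeakBand(1155.0, 6.0, 0.80, 0.80),
    PeakBand(1208.0, 7.0, 0.96, 0.96),
    PeakBand(1265.0, 9.0, 1.44, 1.44),
    PeakBand(1302.0, 8.0, 1.76, 1.76),
    PeakBand(1450.0, 9.0, 1.60, 1.60),
    PeakBand(1555.0, 8.0, 0.96, 0.96),
    PeakBand(1585.0, 7.0, 1.12, 1.12),
    PeakBand(1620.0, 6.0, 0.80, 0.80),
    PeakBand(1660.0, 11.0, 1.92, 1.92),
    PeakBand(1745.0, 6.0, 0.96, 0.96),
    PeakBand(2850.0, 12.0, 0.90, 0.90),
    PeakBand(2890.0, 15.0, 1.30, 1.30),
    PeakBand(2935.0, 14.0, 1.60, 1.60),
    PeakBand(3060.0, 10.0, 0.50, 0.50),
)

#: (center, width) of the five class-discriminative planted bands above.
PLANTED_BANDS = ((994.0, 3.0), (1007.0, 3.0), (1334.0, 4.0), (1766.0, 3.0), (1772.0, 3.0))
PLANTED_BAND_CENTERS = tuple(c for c, _ in PLANTED_BANDS)

#: Smooth autofluorescence background: amplitude * polynomial(u), u in [0,1].
DEFAULT_BASELINE_COEFFS = (1.5, -1.8, 0.9, -0.2, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions: 18 patients, 47 sites total
    (2-5 per patient), class mix 23 benign / 3 GG1 / 10 GG2 / 8 GG3 /
    3 GG4, 50-100 replicates per acquisition, fingerprint and
    high-wavenumber axes of 1801 and 2801 samples.
    """

    n_patients: int = 18
    sites_per_patient_range: tuple[int, int] = (2, 5)
    n_sites_total: int | None = 47
    n_replicates_range: tuple[int, int] = (50, 100)
    fp_axis: tuple[float, float, int] = (400.0, 1800.0, 1801)
    hw_axis: tuple[float, float, int] = (2050.0, 3450.0, 2801)
    peak_bands: tuple[PeakBand, ...] = DEFAULT_PEAK_BANDS
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE_COEFFS
    baseline_amplitude: float = 25.0
    band_jitter_sd: float = 0.30
    site_gain_sd: float = 0.15
    background_wiggle_sd: float = 0.08
    background_wiggle_length_cm1: float = 150.0
    noise_sd: float = 0.05
    cosmic_ray_rate: float = 0.10
    cosmic_ray_amplitude: float = 10.0
    lesion_contrast: float = 0.35
    texture_params: dict[str, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE)
    )
    class_mix: tuple[float, ...] = (23 / 47, 3 / 47, 10 / 47, 8 / 47, 3 / 47)
    hg_low_fraction: float = 0.30
    volume_extent_mm: float = 96.0
    lesion_radius_mm: float = 10.0
    site_margin_mm: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (start, end, n) in (("fp_axis", self.fp_axis), ("hw_axis", self.hw_axis)):
            if end <= start or n < 2:
                raise ConfigurationError(f"{name} must be strictly increasing")
        if self.fp_axis[2] != 1801:
            raise ConfigurationError("fingerprint axis must have 1801 samples")
        if self.hw_axis[2] != 2801:
            raise ConfigurationError("high-wavenumber axis must have 2801 samples")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(f < 0 for f in self.class_mix):
            raise ConfigurationError("class_mix must be non-negative and sum to 1")
        for name, rate in (
            ("cosmic_ray_rate", self.cosmic_ray_rate),
            ("hg_low_fraction", self.hg_low_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.n_replicates_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("invalid replicate-count range")
        lo, hi = self.sites_per_patient_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("invalid sites-per-patient range")
        if self.n_sites_total is not None and not (
            self.n_patients * self.sites_per_patient_range[0]
            <= self.n_sites_total
            <= self.n_patients * self.sites_per_patient_range[1]
        ):
            raise ConfigurationError("n_sites_total incompatible with per-patient range")

    def region_axis(self, region: str) -> np.ndarray:
        start, end, n = self.fp_axis if region == "FP" else self.hw_axis
        return np.linspace(start, end, n)


@dataclass(frozen=True)
class Histology:
    """Per-site ground truth: Gleason pair, ISUP grade group, high-grade %."""

    gs_primary: int
    gs_secondary: int
    isup_gg: int
    hg_percent: float | None

    def __post_init__(self) -> None:
        key = (self.gs_primary, self.gs_secondary)
        if key not in ISUP_FROM_GLEASON:
            raise ValueError(f"unknown Gleason pair {key}")
        if ISUP_FROM_GLEASON[key] != self.isup_gg:
            raise ValueError(
                f"ISUP grade group {self.isup_gg} inconsistent with Gleason {key}"
            )
        if self.isup_gg == 0 and self.hg_percent is not None:
            raise ValueError("benign site must not carry a high-grade percentage")
        if self.hg_percent is not None and not 0.0 <= self.hg_percent <= 100.0:
            raise ValueError("hg_percent outside [0, 100]")

    @property
    def is_tumor(self) -> bool:
        return self.isup_gg >= 1


@dataclass(frozen=True)
class Site:
    """One inspected site: TRUS-frame coordinate plus histology."""

    patient_id: str
    site_id: str
    trus_coords_mm: np.ndarray
    histology: Histology

    def __post_init__(self) -> None:
        coords = np.asarray(self.trus_coords_mm, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("TRUS coordinates must be a finite 3-vector")
        object.__setattr__(self, "trus_coords_mm", coords)


@dataclass
class Cohort:
    """Everything the downstream pipeline consumes."""

    config: SyntheticConfig
    sites: list[Site]
    acquisitions: dict[tuple[str, str], RamanAcquisitionSet]  # (site_id, region)
    volumes: dict[str, dict[str, MriVolume]]  # patient_id -> modality -> volume
    registrations: dict[str, CoRegistration]  # patient_id
    lesion_centers_mm: dict[str, np.ndarray]  # patient_id, MRI frame

    def histology_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            h = s.histology
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "site_id": s.site_id,
                    "x_mm": s.trus_coords_mm[0],
                    "y_mm": s.trus_coords_mm[1],
                    "z_mm": s.trus_coords_mm[2],
                    "gs_primary": h.gs_primary,
                    "gs_secondary": h.gs_secondary,
                    "isup_gg": h.isup_gg,
                    "hg_percent": h.hg_percent,
                }
            )
        return pd.DataFrame(rows).set_index("site_id")


# ---------------------------------------------------------------------------
# Allocation helpers
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: tuple[float, ...], total: int) -> list[int]:
    """Integer class counts summing to ``total``, each within 1 of its quota."""
    quotas = np.array(fractions) * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    for k in order[:remainder]:
        counts[k] += 1
    return counts.tolist()


def _sites_per_patient(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    lo, hi = config.sites_per_patient_range
    weights = np.array([0.55, 0.25, 0.12, 0.08][: hi - lo + 1], dtype=float)
    weights /= weights.sum()
    counts = rng.choice(np.arange(lo, hi + 1), size=config.n_patients, p=weights)
    counts = counts.astype(int)
    if config.n_sites_total is not None:
        # nudge random patients up/down until the exact total is met
        while counts.sum() > config.n_sites_total:
            k = rng.choice(np.flatnonzero(counts > lo))
            counts[k] -= 1
        while counts.sum() < config.n_sites_total:
            k = rng.choice(np.flatnonzero(counts < hi))
            counts[k] += 1
    return counts.tolist()


def _draw_histology(isup_gg: int, config: SyntheticConfig, rng: np.random.Generator) -> Histology:
    """Histology consistent with the grade group.

    The high-grade percentage is the fraction of pattern >= 4, so it is
    structurally low for 3+3 (GG1), below 50% for 3+4 (GG2, with
    probability ``hg_low_fraction`` below the 20% reporting cutoff), at
    or above 50% for 4+3 (GG3), and near 100% for 4+4 and above.
    """
    primary, secondary = GLEASON_FROM_ISUP[isup_gg]
    if isup_gg == 0:
        hg = None
    elif isup_gg == 1:
        hg = float(rng.uniform(0.0, 15.0))
    elif isup_gg == 2:
        if rng.random() < config.hg_low_fraction:
            hg = float(rng.uniform(5.0, 19.5))
        else:
            hg = float(rng.uniform(20.0, 49.5))
    elif isup_gg == 3:
        hg = float(rng.uniform(50.0, 80.0))
    else:
        hg = float(rng.uniform(85.0, 100.0))
    return Histology(primary, secondary, isup_gg, hg)


def _random_rigid_transform(rng: np.random.Generator) -> CoRegistration:
    """Small random rigid MRI->TRUS transform (few degrees, ~cm shifts)."""
    angles = rng.uniform(-0.08, 0.08, size=3)  # radians
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    mat = np.eye(4)
    mat[:3, :3] = rz @ ry @ rx
    mat[:3, 3] = rng.uniform(-20.0, 20.0, size=3)
    return CoRegistration(mri_to_trus=mat)


# ---------------------------------------------------------------------------
# Raman simulation
# ---------------------------------------------------------------------------

def _baseline(axis_fraction: np.ndarray, coeffs: tuple[float, ...], amplitude: float) -> np.ndarray:
    return amplitude * np.polynomial.polynomial.polyval(axis_fraction, np.asarray(coeffs))


def _clean_spectrum(
    site: Site,
    region: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Baseline + class-dependent peaks for one site (no noise, no spikes)."""
    axis = config.region_axis(region)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    coeff_jitter = 1.0 + 0.10 * rng.standard_normal(len(config.baseline_coeffs))
    baseline = _baseline(u, tuple(np.array(config.baseline_coeffs) * coeff_jitter), config.baseline_amplitude)
    # smooth per-site background variability (scattering, hydration):
    # a stationary random curve too wiggly for the polynomial baseline
    # fit to absorb but much broader than any Raman band
    if config.background_wiggle_sd > 0:
        step = axis[1] - axis[0]
        white = rng.standard_normal(len(axis))
        wiggle = gaussian_filter(white, sigma=config.background_wiggle_length_cm1 / step, mode="nearest")
        sd = wiggle.std()
        if sd > 0:
            baseline = baseline + config.background_wiggle_sd / sd * wiggle
    peaks = np.zeros_like(axis)
    for band in config.peak_bands:
        if not axis[0] <= band.center_cm1 <= axis[-1]:
            continue
        amp = band.amplitude_for_grade(site.histology.isup_gg)
        amp *= max(0.2, 1.0 + config.band_jitter_sd * rng.standard_normal())
        peaks += amp * np.exp(-0.5 * ((axis - band.center_cm1) / band.width_cm1) ** 2)
    # probe-coupling gain scales the whole optical signal (baseline and
    # peaks alike), which is exactly the variation SNV is built to remove
    gain = max(0.2, 1.0 + config.site_gain_sd * rng.standard_normal())
    return gain * (baseline + peaks)


def simulate_acquisition_set(
    site: Site,
    region: str,
    config: SyntheticConfig,
    stream: np.random.SeedSequence | np.random.Generator,
) -> RamanAcquisitionSet:
    """Replicate raw spectra for one site and region.

    Each replicate is the site's clean spectrum (autofluorescence
    baseline + class-dependent Gaussian peaks, with per-site amplitude
    jitter emulating tissue heterogeneity and probe coupling) plus white
    noise; with probability ``cosmic_ray_rate`` a replicate additionally
    carries a 1-3-sample positive cosmic-ray spike.
    """
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    axis = config.region_axis(region)
    clean = _clean_spectrum(site, region, config, rng)
    lo, hi = config.n_replicates_range
    n_rep = int(rng.integers(lo, hi + 1))
    reps = clean + config.noise_sd * rng.standard_normal((n_rep, len(axis)))
    hit = rng.random(n_rep) < config.cosmic_ray_rate
    for r in np.flatnonzero(hit):
        width = int(rng.integers(1, 4))
        pos = int(rng.integers(0, len(axis) - width + 1))
        amp = config.cosmic_ray_amplitude * rng.uniform(0.8, 1.2)
        profile = amp * np.linspace(1.0, 0.6, width)
        reps[r, pos : pos + width] += profile
    return RamanAcquisitionSet(region=region, pixel_axis=axis, replicates=reps)


# ---------------------------------------------------------------------------
# MRI simulation
# ---------------------------------------------------------------------------

def _correlated_noise(shape, spacing, corr_length_mm, noise_sd, rng) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma_vox = np.maximum(np.asarray(corr_length_mm) / np.asarray(spacing), 1e-6)
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth *= noise_sd / sd
    return smooth


def simulate_mri_triplet(
    patient_id: str,
    lesion_center_mm: np.ndarray,
    config: SyntheticConfig,
    stream: np.random.SeedSequence | np.random.Generator,
) -> dict[str, MriVolume]:
    """T2/ADC/b2000 volumes sharing one world frame and one lesion.

    The lesion is a sphere of ``lesion_radius_mm`` at
    ``lesion_center_mm``; its intensity shift and extra texture noise per
    modality scale with ``lesion_contrast`` (see :class:`TextureParams`).
    """
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    extent = config.volume_extent_mm
    out: dict[str, MriVolume] = {}
    for modality in MODALITIES:
        spacing = np.array(MODALITY_SPACING[modality])
        shape = np.ceil(extent / spacing).astype(int)
        tp = config.texture_params[modality]
        gain = max(0.5, 1.0 + tp.patient_gain_sd * rng.standard_normal())
        origin = np.zeros(3)
        idx = np.indices(shape).astype(float)
        world = [origin[k] + idx[k] * spacing[k] for k in range(3)]
        dist2 = sum((world[k] - lesion_center_mm[k]) ** 2 for k in range(3))
        lesion = dist2 <= config.lesion_radius_mm**2

        grid = np.full(shape, gain * tp.base_intensity, dtype=float)
        grid *= 1.0 + tp.lesion_intensity_scale * config.lesion_contrast * lesion
        noise = _correlated_noise(shape, spacing, tp.corr_length_mm, tp.noise_sd, rng)
        w = min(1.0, tp.lesion_texture_scale * config.lesion_contrast)
        if w > 0:
            white = tp.noise_sd * rng.standard_normal(shape)
            noise = np.where(lesion, np.sqrt(1.0 - w**2) * noise + w * white, noise)
        grid += noise
        out[modality] = MriVolume(
            modality=modality,
            intensities=grid,
            spacing_mm=spacing,
            origin_mm=origin,
        )
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _site_position_mri(
    tumor: bool,
    lesion_center: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """MRI-frame site coordinate: inside the lesion core for tumor sites,
    outside the lesion plus a margin (but inside the volume) for benign."""
    extent = config.volume_extent_mm
    margin = config.site_margin_mm
    if tumor:
        offset = rng.standard_normal(3)
        offset *= rng.uniform(0.0, 0.45 * config.lesion_radius_mm) / max(np.linalg.norm(offset), 1e-9)
        return lesion_center + offset
    for _ in range(1000):
        p = rng.uniform(margin, extent - margin, size=3)
        if np.linalg.norm(p - lesion_center) >= config.lesion_radius_mm + margin:
            return p
    raise ConfigurationError("could not place a benign site outside the lesion")


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full cohort: sites, spectra, volumes, transforms, histology.

    Deterministic for a given ``config.seed``: the cohort stream allocates
    per-patient site counts and the class permutation; each patient's
    spawned stream drives its transform, lesion placement and volumes;
    each site's spawned stream drives its coordinate, histology draw and
    the two acquisition sets.
    """
    root = np.random.SeedSequence(config.seed)
    cohort_ss, patients_ss = root.spawn(2)
    cohort_rng = np.random.default_rng(cohort_ss)

    counts = _sites_per_patient(config, cohort_rng)
    total = int(sum(counts))
    class_counts = _largest_remainder_counts(config.class_mix, total)
    labels = np.repeat(np.arange(len(class_counts)), class_counts)
    cohort_rng.shuffle(labels)

    sites: list[Site] = []
    acquisitions: dict[tuple[str, str], RamanAcquisitionSet] = {}
    volumes: dict[str, dict[str, MriVolume]] = {}
    registrations: dict[str, CoRegistration] = {}
    lesion_centers: dict[str, np.ndarray] = {}

    patient_streams = patients_ss.spawn(config.n_patients)
    cursor = 0
    for p_idx, (n_sites, p_ss) in enumerate(zip(counts, patient_streams)):
        patient_id = f"P{p_idx + 1:02d}"
        p_children = p_ss.spawn(2 + n_sites)
        p_rng = np.random.default_rng(p_children[0])

        registrations[patient_id] = _random_rigid_transform(p_rng)
        extent = config.volume_extent_mm
        pad = config.lesion_radius_mm + config.site_margin_mm
        lesion_center = p_rng.uniform(pad, extent - pad, size=3)
        lesion_centers[patient_id] = lesion_center
        volumes[patient_id] = simulate_mri_triplet(
            patient_id, lesion_center, config, np.random.default_rng(p_children[1])
        )

        for s_idx in range(n_sites):
            site_ss = p_children[2 + s_idx]
            s_children = site_ss.spawn(3)
            s_rng = np.random.default_rng(s_children[0])
            isup = int(labels[cursor])
            cursor += 1
            histology = _draw_histology(isup, config, s_rng)
            mri_point = _site_position_mri(
                histology.is_tumor, lesion_center, config, s_rng
            )
            trus_point = registrations[patient_id].apply(mri_point)
            site = Site(
                patient_id=patient_id,
                site_id=f"{patient_id}S{s_idx + 1}",
                trus_coords_mm=trus_point,
                histology=histology,
            )
            sites.append(site)
            acquisitions[(site.site_id, "FP")] = simulate_acquisition_set(
                site, "FP", config, np.random.default_rng(s_children[1])
            )
            acquisitions[(site.site_id, "HW")] = simulate_acquisition_set(
                site, "HW", config, np.random.default_rng(s_children[2])
            )

    return Cohort(
        config=config,
        sites=sites,
        acquisitions=acquisitions,
        volumes=volumes,
        registrations=registrations,
        lesion_centers_mm=lesion_centers,
    )


def null_config(base: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """A class-null variant of a config: equal band amplitudes (benign value
    on both classes) and zero lesion contrast.  Used for calibration checks."""
    base = base or SyntheticConfig()
    bands = tuple(
        replace(b, amplitude_tumor=b.amplitude_benign) for b in base.peak_bands
    )
    return replace(base, peak_bands=bands, lesion_contrast=0.0, **overrides)
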