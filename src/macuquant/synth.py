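"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* layered B-scan phantoms with nine known boundary curves, per-layer mean
  intensities, Gaussian blur, and multiplicative speckle;
* en face angiogram phantoms with a zero-flow FAZ, a few wide bright
  vessels, a capillary mesh of known per-region area fraction, and
  background noise;
* three-group eye-level cohorts (control / non-DON / DON) whose group
  means and SDs default to the study's printed summary tables, with
  within-patient inter-eye correlation and a configurable cross-correlation
  between GCC thickness and superficial capillary density.

Every generator is seed-deterministic and returns machine-readable truth
next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform

from . import geometry
from .angio import Angiogram
from .segmentation import BoundarySet, BScan

GROUPS = ("control", "nonDON", "DON")

# ---------------------------------------------------------------------------
# Reference group summary statistics (mean, SD) per group, used as the
# default cohort parameters.  Thickness in μm, capillary density in %.
# ---------------------------------------------------------------------------

REFERENCE_THICKNESS: Dict[str, Dict[str, Tuple[Tuple[float, float], ...]]] = {
    # region -> ((control), (nonDON), (DON)) as (mean, sd)
    "NFL": {
        "C": ((6.9, 1.3), (6.2, 1.7), (6.9, 1.3)),
        "TAZ": ((19.9, 3.2), (17.7, 2.1), (17.4, 1.3)),
        "S": ((21.4, 3.6), (19.1, 3.3), (18.0, 1.9)),
        "T": ((17.0, 2.7), (15.5, 1.9), (15.3, 1.9)),
        "I": ((22.2, 3.6), (19.1, 3.3), (18.0, 1.9)),
        "N": ((19.3, 4.6), (16.3, 2.2), (16.5, 1.8)),
    },
    "GCL+IPL": {
        "C": ((14.6, 4.2), (12.0, 4.1), (12.0, 3.4)),
        "TAZ": ((75.4, 8.3), (69.6, 10.2), (67.1, 13.1)),
        "S": ((79.5, 9.6), (71.6, 11.0), (69.2, 14.2)),
        "T": ((72.0, 13.4), (65.1, 10.4), (62.7, 12.8)),
        "I": ((79.5, 9.6), (71.6, 11.0), (69.2, 14.2)),
        "N": ((74.9, 9.8), (66.8, 10.6), (64.9, 13.2)),
    },
    "GCC": {
        "C": ((21.5, 5.0), (18.2, 5.0), (18.9, 3.7)),
        "TAZ": ((95.2, 10.3), (87.3, 11.8), (84.5, 13.4)),
        "S": ((100.8, 12.0), (90.6, 13.1), (87.2, 15.0)),
        "T": ((88.9, 14.5), (80.6, 11.8), (78.0, 11.9)),
        "I": ((101.6, 13.1), (92.7, 12.5), (90.1, 14.0)),
        "N": ((94.2, 13.2), (83.1, 12.2), (81.4, 13.2)),
    },
    "INL+ORL": {
        "C": ((202.2, 41.2), (202.9, 9.6), (206.3, 26.4)),
        "TAZ": ((219.3, 9.4), (218.4, 7.1), (221.4, 9.4)),
        "S": ((219.6, 9.9), (219.3, 7.5), (221.6, 9.2)),
        "T": ((221.8, 10.5), (220.2, 8.2), (224.0, 10.2)),
        "I": ((216.5, 8.0), (216.6, 7.2), (219.9, 9.3)),
        "N": ((218.6, 9.6), (217.1, 6.8), (220.5, 10.0)),
    },
    "TOTAL": {
        "C": ((213.3, 51.3), (214.7, 14.9), (215.8, 36.9)),
        "TAZ": ((314.1, 17.5), (305.4, 15.8), (305.7, 12.8)),
        "S": ((320.2, 19.5), (309.7, 17.1), (308.5, 14.8)),
        "T": ((315.9, 21.8), (302.9, 17.5), (305.0, 14.9)),
        "I": ((318.1, 19.1), (309.2, 15.4), (309.6, 12.9)),
        "N": ((307.0, 21.5), (297.1, 15.0), (298.0, 11.5)),
    },
}

REFERENCE_RCD: Dict[str, Dict[str, Tuple[Tuple[float, float], ...]]] = {
    "SRCL": {
        "TAZ": ((63.7, 3.3), (60.0, 3.5), (59.8, 4.5)),
        "C1": ((57.6, 12.9), (48.5, 14.6), (51.1, 11.6)),
        "C2": ((63.0, 5.6), (60.6, 5.8), (60.8, 5.2)),
        "C3": ((64.0, 4.5), (61.0, 4.3), (61.2, 5.5)),
        "C4": ((64.4, 3.7), (61.4, 4.0), (60.3, 5.3)),
        "C5": ((64.8, 3.1), (60.8, 3.8), (60.9, 5.0)),
        "C6": ((64.2, 2.9), (61.4, 3.6), (60.0, 4.4)),
        "S": ((63.4, 3.9), (60.3, 4.3), (60.0, 5.3)),
        "T": ((64.0, 3.5), (61.2, 4.2), (60.3, 5.0)),
        "I": ((63.7, 3.6), (59.7, 4.0), (59.5, 5.6)),
        "N": ((63.6, 4.3), (59.0, 4.0), (59.5, 4.5)),
    },
    "DRCL": {
        "TAZ": ((73.9, 4.8), (70.2, 4.4), (66.4, 7.7)),
        "C1": ((40.6, 18.8), (34.0, 16.2), (29.7, 15.3)),
        "C2": ((71.6, 8.5), (66.7, 8.4), (61.3, 12.4)),
        "C3": ((78.3, 4.1), (75.2, 4.3), (71.9, 7.5)),
        "C4": ((78.4, 4.0), (75.9, 3.6), (72.3, 7.4)),
        "C5": ((77.8, 3.6), (74.4, 3.9), (71.3, 7.7)),
        "C6": ((76.5, 4.2), (72.9, 4.1), (68.9, 8.1)),
        "S": ((75.0, 4.6), (71.2, 4.1), (68.0, 8.1)),
        "T": ((73.4, 4.7), (69.4, 5.1), (65.1, 9.2)),
        "I": ((75.0, 4.9), (71.5, 4.9), (67.7, 7.0)),
        "N": ((72.4, 5.7), (68.8, 4.6), (64.8, 7.9)),
    },
}

REFERENCE_COVARIATES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "age": ((45.2, 10.8), (41.9, 11.7), (47.6, 6.5)),
    "IOP": ((14.4, 2.3), (16.1, 3.2), (19.0, 6.9)),
    "BCVA": ((0.00, 0.01), (0.00, 0.01), (0.15, 0.37)),
    "axial_length": ((23.5, 0.9), (23.3, 1.0), (23.3, 0.8)),
    "MD": ((np.nan, np.nan), (-0.29, 0.54), (-6.79, 3.91)),
    "CAS": ((np.nan, np.nan), (1.08, 1.18), (1.73, 1.12)),
}


def default_measure_params() -> Dict[str, Tuple[Tuple[float, float], ...]]:
    """Flat ``{layer}_{region} -> per-group (mean, sd)`` map of all measures."""
    params: Dict[str, Tuple[Tuple[float, float], ...]] = {}
    for layer, regions in REFERENCE_THICKNESS.items():
        key = layer.replace("+", "")
        for region, stats in regions.items():
            params[f"{key}_{region}"] = stats
    for layer, regions in REFERENCE_RCD.items():
        for region, stats in regions.items():
            params[f"{layer}_{region}"] = stats
    return params


# ---------------------------------------------------------------------------
# B-scan phantoms
# ---------------------------------------------------------------------------

#: Default mean intensity of the 8 layers between the nine boundaries,
#: with vitreous above and choroid below; chosen to alternate bright/dark
#: as in a conventionally displayed B-scan.
DEFAULT_LAYER_INTENSITIES: Tuple[float, ...] = (170, 120, 80, 150, 40, 160, 90, 200)
DEFAULT_VITREOUS_INTENSITY = 20.0
DEFAULT_CHOROID_INTENSITY = 30.0
#: Default boundary depths (px) at the scan edge; successive gaps are the
#: layer thicknesses in pixels.
DEFAULT_BOUNDARY_DEPTHS: Tuple[float, ...] = (60, 72, 97, 115, 127, 149, 159, 167, 179)


@dataclass
class BScanPhantomSpec:
    """Parametric nine-boundary B-scan phantom.

    ``boundary_shape`` is "flat", "sinusoid" (parallel sinusoidal
    boundaries, amplitude in px), or "pit" (a foveal-pit-like central
    depression of the inner boundaries).
    """

    width: int = 384
    depth: int = 320
    boundary_depths: Sequence[float] = DEFAULT_BOUNDARY_DEPTHS
    boundary_shape: str = "flat"
    amplitude: float = 0.0
    layer_intensities: Sequence[float] = DEFAULT_LAYER_INTENSITIES
    vitreous_intensity: float = DEFAULT_VITREOUS_INTENSITY
    choroid_intensity: float = DEFAULT_CHOROID_INTENSITY
    speckle_sd: float = 0.0
    blur_sigma: float = 0.0
    axial_scale: float = 3.0      # μm/px
    lateral_scale: float = 12.0   # μm/px
    meridian_angle: float = 0.0
    eye_axial_length: float = 23.95
    seed: int = 0

    def __post_init__(self) -> None:
        depths = np.asarray(self.boundary_depths, dtype=float)
        if depths.shape != (9,) or np.any(np.diff(depths) < 0):
            raise ValueError("need nine ordered boundary depths")
        if len(self.layer_intensities) != 8:
            raise ValueError("need eight layer intensities")
        if np.any(np.diff(np.r_[self.vitreous_intensity,
                                list(self.layer_intensities),
                                self.choroid_intensity]) == 0):
            raise ValueError("adjacent layer intensities must be distinct")
        if self.boundary_shape not in ("flat", "sinusoid", "pit"):
            raise ValueError("boundary_shape must be flat, sinusoid, or pit")


def _phantom_boundaries(spec: BScanPhantomSpec) -> np.ndarray:
    x = np.arange(spec.width)
    base = np.asarray(spec.boundary_depths, dtype=float)[:, None]
    curves = np.repeat(base, spec.width, axis=1)
    if spec.boundary_shape == "sinusoid" and spec.amplitude:
        wave = spec.amplitude * np.sin(2 * np.pi * x / spec.width)
        curves = curves + wave[None, :]
    elif spec.boundary_shape == "pit" and spec.amplitude:
        # inner boundaries dip toward the outer retina at the scan center,
        # scaled so ordering is preserved by construction
        bump = np.exp(-0.5 * ((x - spec.width / 2.0) / (spec.width / 10.0)) ** 2)
        gaps = np.diff(np.asarray(spec.boundary_depths))
        for k in range(4):  # boundaries 1..4 dip, progressively less
            depth_avail = gaps[k] - 1.0
            amp = min(spec.amplitude * (1.0 - k / 4.0), max(depth_avail, 0.0))
            curves[k] += amp * bump
    if np.any(np.diff(curves, axis=0) < 0):
        raise ValueError("phantom boundary curves cross")
    if curves.max() >= spec.depth:
        raise ValueError("boundaries exceed scan depth")
    return curves


def make_bscan_phantom(spec: BScanPhantomSpec) -> Tuple[BScan, BoundarySet]:
    """Render a layered B-scan phantom and return it with its true boundaries."""
    rng = np.random.default_rng(spec.seed)
    curves = _phantom_boundaries(spec)
    rows = np.arange(spec.depth)[:, None]
    levels = np.r_[spec.vitreous_intensity, list(spec.layer_intensities),
                   spec.choroid_intensity]
    # region index per pixel = number of boundaries above the pixel center
    region = (rows >= curves[:, None, :].round()).sum(axis=0)
    img = levels[region].astype(float)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.speckle_sd > 0:
        img = img * (1.0 + spec.speckle_sd * rng.standard_normal(img.shape))
        img = np.clip(img, 0.0, None)
    bscan = BScan(img, spec.axial_scale, spec.lateral_scale,
                  spec.meridian_angle, spec.eye_axial_length)
    return bscan, BoundarySet(curves)


# ---------------------------------------------------------------------------
# Angiogram phantoms
# ---------------------------------------------------------------------------


@dataclass
class AngioPhantomSpec:
    """En face angiogram phantom with known vessel geometry.

    The scene is rendered on the 1024² analysis grid; the emitted
    ``Angiogram`` is its anti-aliased downsampling to the device raster
    (default 304²).  Truth masks and per-region capillary fractions refer
    to the 1024² scene.
    """

    size: int = 304
    scene_size: int = 1024
    field_of_view_mm: float = 3.0
    faz_shape: str = "disk"                 # disk | ellipse | irregular
    faz_diameter_mm: float = 0.60
    faz_axes_mm: Tuple[float, float] = (0.5, 0.7)   # ellipse full axes
    n_large_vessels: int = 2
    vessel_width_um: Tuple[float, float] = (25.0, 30.0)
    capillary_fraction: float = 0.637
    capillary_intensity: float = 85.0
    large_vessel_intensity: float = 130.0
    noise_mean: float = 40.0
    noise_sd: float = 4.0
    noise_correlation_px: float = 2.0
    mesh_correlation_px: float = 10.0
    terminal_ring_um: float = 30.0
    layer: str = "SRCL"
    signal_strength_index: float = 65.0
    laterality: str = "OD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.capillary_fraction <= 0.95:
            raise ValueError("capillary fraction must be in (0, 0.95]")
        if self.faz_shape not in ("disk", "ellipse", "irregular"):
            raise ValueError("faz_shape must be disk, ellipse, or irregular")


@dataclass
class AngioPhantomTruth:
    """Ground truth accompanying an angiogram phantom (1024² scene grid)."""

    capillary_mask: np.ndarray = field(repr=False)
    large_vessel_mask: np.ndarray = field(repr=False)
    faz_mask: np.ndarray = field(repr=False)
    faz_area_mm2: float = 0.0
    region_capillary_fraction: Dict[str, float] = field(default_factory=dict)


def _faz_mask(spec: AngioPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.scene_size
    mm_px = spec.field_of_view_mm / n
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    dy, dx = (yy - c) * mm_px, (xx - c) * mm_px
    if spec.faz_shape == "disk":
        return np.hypot(dy, dx) <= spec.faz_diameter_mm / 2.0
    if spec.faz_shape == "ellipse":
        a, b = spec.faz_axes_mm[0] / 2.0, spec.faz_axes_mm[1] / 2.0
        return (dy / b) ** 2 + (dx / a) ** 2 <= 1.0
    # irregular: disk radius modulated by a low-order angular perturbation
    theta = np.arctan2(dx, -dy)
    coeffs = rng.uniform(-0.08, 0.08, size=3)
    radius = spec.faz_diameter_mm / 2.0 * (
        1.0 + sum(c_ * np.sin((k + 2) * theta + rng.uniform(0, 2 * np.pi))
                  for k, c_ in enumerate(coeffs))
    )
    return np.hypot(dy, dx) <= radius


def _large_vessels(spec: AngioPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.scene_size
    mm_px = spec.field_of_view_mm / n
    mask = np.zeros((n, n), dtype=bool)
    t = np.linspace(0.0, 1.0, 4 * n)
    for _ in range(spec.n_large_vessels):
        width_px = rng.uniform(*spec.vessel_width_um) / (mm_px * 1000.0)
        # smooth arc from one border to another, avoiding the center
        theta0 = rng.uniform(0, 2 * np.pi)
        theta1 = theta0 + rng.uniform(0.8, 1.6) * np.pi
        radius = rng.uniform(0.55, 0.95) * n / 2.0
        wobble = rng.uniform(0.05, 0.15) * n / 2.0
        phase = rng.uniform(0, 2 * np.pi)
        ang = theta0 + (theta1 - theta0) * t
        r = radius + wobble * np.sin(3 * ang + phase)
        rr = np.clip((n - 1) / 2.0 + r * np.sin(ang), 0, n - 1).astype(int)
        cc = np.clip((n - 1) / 2.0 + r * np.cos(ang), 0, n - 1).astype(int)
        line = np.zeros((n, n), dtype=bool)
        line[rr, cc] = True
        mask |= ndimage.distance_transform_edt(~line) <= width_px / 2.0
    return mask


def make_angiogram_phantom(
    spec: AngioPhantomSpec,
) -> Tuple[Angiogram, AngioPhantomTruth]:
    """Render an angiogram phantom and its ground truth.

    The capillary mesh is a thresholded band-limited Gaussian random field.
    The threshold is calibrated per concentric ring (and once for the area
    outside the TAZ) by the field quantile over that ring's eligible pixels,
    so every ring's realized capillary fraction — counting large-vessel
    pixels in the denominator, as the density measure does — hits the
    target to well within ±1 percentage point.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.scene_size
    grid = geometry.FoveaCenteredGrid.for_enface(
        n, spec.field_of_view_mm, spec.laterality
    )

    faz = _faz_mask(spec, rng)
    large = _large_vessels(spec, rng) & ~faz
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((n, n)), spec.mesh_correlation_px
    )

    taz = geometry.make_taz_mask(grid).pixels
    mesh = np.zeros((n, n), dtype=bool)
    zones = [m.pixels for m in geometry.make_ring_series(grid).values()]
    zones.append(~taz & ~faz)  # periphery beyond the TAZ, calibrated once
    for zone in zones:
        eligible = zone & ~large & ~faz
        needed = spec.capillary_fraction * np.count_nonzero(zone)
        n_eligible = np.count_nonzero(eligible)
        if n_eligible == 0:
            continue
        frac_eligible = needed / n_eligible
        if frac_eligible >= 1.0:
            raise ValueError(
                "target capillary fraction unreachable given large vessels")
        thresh = np.quantile(field_[eligible], 1.0 - frac_eligible)
        mesh |= (field_ > thresh) & eligible
    # terminal capillary ring delimiting the FAZ, as in real retinas —
    # without it the avascular area would extend a random gap-width past
    # the nominal boundary and the boundary would be unobservable
    ring_px = max(int(round(spec.terminal_ring_um / (grid.mm_per_pixel * 1000.0))), 1)
    ring = ndimage.binary_dilation(faz, iterations=ring_px) & ~faz
    mesh |= ring & ~large

    raw_noise = rng.standard_normal((n, n))
    if spec.noise_correlation_px > 0:
        raw_noise = ndimage.gaussian_filter(raw_noise, spec.noise_correlation_px)
        raw_noise /= raw_noise.std()
    noise = np.clip(spec.noise_mean + spec.noise_sd * raw_noise, 0.0, None)
    scene = noise.copy()
    scene[mesh] = spec.capillary_intensity + noise[mesh]
    scene[large] = spec.large_vessel_intensity + noise[large]
    scene[faz] = noise[faz]

    # The device measures one decorrelation value per raster pixel: sample
    # the scene at the raster's pixel centers rather than area-averaging,
    # which would wash out the capillary/background bimodality.
    idx = np.round(np.linspace(0, n - 1, spec.size)).astype(int)
    raster = scene[np.ix_(idx, idx)]
    angiogram = Angiogram(
        raster, spec.layer, spec.field_of_view_mm,
        spec.signal_strength_index, laterality=spec.laterality,
    )

    masks = {"TAZ": geometry.make_taz_mask(grid)}
    masks.update(geometry.make_ring_series(grid))
    masks.update(geometry.make_sector_masks(grid))
    fractions = {
        name: float(np.count_nonzero(mesh & m.pixels) / np.count_nonzero(m.pixels))
        for name, m in masks.items()
    }
    truth = AngioPhantomTruth(
        capillary_mask=mesh,
        large_vessel_mask=large,
        faz_mask=faz,
        faz_area_mm2=float(np.count_nonzero(faz)) * grid.mm_per_pixel ** 2,
        region_capillary_fraction=fractions,
    )
    return angiogram, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Three-group eye-level cohort with clustered eyes.

    Defaults reproduce the study conditions: 38/36/38 eyes in
    control / non-DON / DON, ~65% of eyes contributed bilaterally, group
    means and SDs from the printed thickness and density tables, a latent
    within-patient inter-eye correlation, and a cross-correlation between
    GCC thickness and superficial capillary density in the TAZ.
    """

    eyes_per_group: Tuple[int, int, int] = (38, 36, 38)
    bilateral_fraction: float = 0.65
    measures: Optional[Dict[str, Tuple[Tuple[float, float], ...]]] = None
    rho_eye: float = 0.6
    rho_xy: float = 0.312
    xy_pair: Tuple[str, str] = ("GCC_TAZ", "SRCL_TAZ")
    include_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_eye < 1.0 or not -1.0 < self.rho_xy < 1.0:
            raise ValueError("correlations must lie in (-1, 1)")
        if self.measures is None:
            self.measures = default_measure_params()
        for name, stats in self.measures.items():
            if any(sd <= 0 for _, sd in stats):
                raise ValueError(f"non-positive SD for measure {name}")


def _correlated_pair(rng: np.random.Generator, size: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((2, size))
    out = np.empty_like(z)
    out[0] = z[0]
    out[1] = rho * z[0] + np.sqrt(1.0 - rho ** 2) * z[1]
    return out


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample an eye-level cohort table (one row per eye).

    Each measure is drawn from its group-specific normal; a latent patient
    effect shared by both eyes of a patient induces inter-eye correlation
    ``rho_eye``; the designated measure pair shares correlated latent
    components at both patient and eye level, giving marginal
    cross-correlation ``rho_xy``.  Thickness and density values are
    truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    measures = spec.measures
    assert measures is not None
    names = list(measures)
    a_name, b_name = spec.xy_pair
    pair_active = a_name in measures and b_name in measures

    rows = []
    for g_idx, group in enumerate(GROUPS):
        n_eyes = spec.eyes_per_group[g_idx]
        n_bilateral = int(round(n_eyes * spec.bilateral_fraction / 2.0))
        n_unilateral = n_eyes - 2 * n_bilateral
        eye_counts = [2] * n_bilateral + [1] * n_unilateral
        for p_idx, n_p in enumerate(eye_counts):
            pid = f"{group}_{p_idx:03d}"
            # latent standard-normal patient effects
            z_pat = {name: rng.standard_normal() for name in names}
            if pair_active:
                pa, pb = _correlated_pair(rng, 1, spec.rho_xy)[:, 0]
                z_pat[a_name], z_pat[b_name] = pa, pb
            covs = {}
            if spec.include_covariates:
                for cov, stats in REFERENCE_COVARIATES.items():
                    mu, sd = stats[g_idx]
                    covs[cov] = (np.nan if np.isnan(mu)
                                 else float(rng.normal(mu, sd)))
                covs["sex"] = "M" if rng.random() < 0.5 else "F"
            eyes = ["OD", "OS"] if n_p == 2 else [("OD", "OS")[int(rng.integers(2))]]
            for eye in eyes:
                z_eye = {name: rng.standard_normal() for name in names}
                if pair_active:
                    ea, eb = _correlated_pair(rng, 1, spec.rho_xy)[:, 0]
                    z_eye[a_name], z_eye[b_name] = ea, eb
                row = {"patient_id": pid, "eye": eye, "group": group, **covs}
                for name in names:
                    mu, sd = measures[name][g_idx]
                    z = (np.sqrt(spec.rho_eye) * z_pat[name]
                         + np.sqrt(1.0 - spec.rho_eye) * z_eye[name])
                    row[name] = max(0.0, float(mu + sd * z))
                rows.append(row)
    return pd.DataFrame(rows)
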