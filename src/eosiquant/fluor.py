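"""Fluorescence quantification: nuclei, BODIPY lipid-body spots, morphology.

Cells are counted from Hoechst-stained nuclei (smoothed Otsu segmentation,
watershed splitting, area > 5 µm²) and lipid bodies from the BODIPY channel
(white-top-hat local-contrast detection, area > 2 µm²); both gates are
physical areas, so the pixel size must be known.  Per-image LB/cell ratios
are aggregated as mean of image means ± SEM between images.  A
multi-parametric morphology profile (area, roundness, symmetry,
compactness, intensity, background-corrected spot intensity) is computed
per object and normalized to a designated reference group, and groups are
compared with an exact-enumeration Mann–Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, h_maxima, remove_small_holes, white_tophat
from skimage.segmentation import watershed

from .image import IntensityImage
from .stats import star_code

NUCLEUS_MIN_AREA_UM2 = 5.0
SPOT_MIN_AREA_UM2 = 2.0


@dataclass
class Region:
    """One segmented object (nucleus or LB spot)."""

    label: int
    centroid: Tuple[float, float]  # (row, col) px
    area_px2: float
    area_um2: float
    perimeter_px: float
    mean_intensity: float
    coords: np.ndarray  # (n, 2) pixel coordinates


def _regions_from_labels(
    labels: np.ndarray, intensity: np.ndarray, pixel_size: float, min_area_um2: float
) -> List[Region]:
    regions = []
    kept = 0
    for rp in measure.regionprops(labels, intensity_image=intensity):
        area_um2 = rp.area * pixel_size**2
        if area_um2 <= min_area_um2:
            continue
        kept += 1
        regions.append(
            Region(
                label=kept,
                centroid=tuple(rp.centroid),
                area_px2=float(rp.area),
                area_um2=float(area_um2),
                perimeter_px=float(rp.perimeter_crofton),
                mean_intensity=float(rp.intensity_mean),
                coords=rp.coords.copy(),
            )
        )
    return regions


def find_nuclei(
    hoechst: IntensityImage,
    min_area_um2: float = NUCLEUS_MIN_AREA_UM2,
    smoothing_sigma: float = 2.0,
) -> List[Region]:
    """Segment nuclei in the Hoechst channel; regions ≤ ``min_area_um2`` are dropped.

    Gaussian smoothing, Otsu threshold, hole filling and a
    distance-transform watershed to split touching nuclei.
    """
    if hoechst.pixel_size is None:
        raise ValueError("pixel_size metadata required: the nucleus area gate is in µm²")
    pixels = np.asarray(hoechst.pixels, dtype=float)
    smoothed = ndi.gaussian_filter(pixels, smoothing_sigma)
    if smoothed.max() == smoothed.min():
        return []
    binary = smoothed > threshold_otsu(smoothed)
    if not binary.any():
        return []
    binary = remove_small_holes(binary, max_size=64)
    dist = ndi.distance_transform_edt(binary)
    markers = measure.label(h_maxima(dist, 2.0), connectivity=2)
    if markers.max() == 0:
        markers = measure.label(binary, connectivity=2)
    labels = watershed(-dist, markers=markers, mask=binary)
    return _regions_from_labels(labels, pixels, hoechst.pixel_size, min_area_um2)


def find_spots(
    bodipy: IntensityImage,
    nuclei: Optional[List[Region]] = None,
    min_area_um2: float = SPOT_MIN_AREA_UM2,
    tophat_radius: int = 5,
    noise_factor: float = 10.0,
) -> List[Region]:
    """Detect LB spots in the BODIPY channel by local contrast.

    A white top-hat removes the smooth background; pixels exceeding
    ``noise_factor`` robust noise sigmas of the top-hat residual are kept,
    and components with area ≤ ``min_area_um2`` are discarded.  The nuclei
    argument is accepted for interface symmetry (spot detection itself is
    independent of the nuclear mask).
    """
    if bodipy.pixel_size is None:
        raise ValueError("pixel_size metadata required: the spot area gate is in µm²")
    pixels = np.asarray(bodipy.pixels, dtype=float)
    tophat = white_tophat(pixels, footprint=disk(tophat_radius))
    mad = np.median(np.abs(tophat - np.median(tophat)))
    noise_sigma = 1.4826 * mad
    threshold = noise_factor * max(noise_sigma, 1e-12)
    binary = tophat > threshold
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    return _regions_from_labels(labels, pixels, bodipy.pixel_size, min_area_um2)


# --------------------------------------------------------------------------
# per-image ratios
# --------------------------------------------------------------------------


@dataclass
class RatioSummary:
    """LBs-per-cell ratios aggregated over images (mean of image means ± SEM)."""

    per_image_ratios: List[float]
    mean: float
    sem: float
    excluded_images: List[int] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.per_image_ratios)


def lbs_per_cell_ratio(per_image_counts: Sequence[Tuple[int, int]]) -> RatioSummary:
    """Per-image (spot count / nucleus count) and the across-image summary.

    Images with zero nuclei are excluded from the aggregation and recorded.
    SEM is the between-image standard error: SD of the image ratios divided
    by √(number of images).
    """
    ratios: List[float] = []
    excluded: List[int] = []
    for i, (spots, nuclei) in enumerate(per_image_counts):
        if nuclei < 1:
            excluded.append(i)
            continue
        ratios.append(spots / nuclei)
    if not ratios:
        raise ValueError("no image with at least one nucleus")
    arr = np.asarray(ratios)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return RatioSummary(per_image_ratios=ratios, mean=float(arr.mean()), sem=sem, excluded_images=excluded)


# --------------------------------------------------------------------------
# morphology profile
# --------------------------------------------------------------------------


def _symmetry_index(coords: np.ndarray) -> float:
    """Overlap fraction between an object and its 180°-rotation about the centroid."""
    center2 = np.round(2.0 * coords.mean(axis=0)).astype(int)
    original = {(int(r), int(c)) for r, c in coords}
    rotated = {(int(center2[0] - r), int(center2[1] - c)) for r, c in coords}
    return len(original & rotated) / len(original)


def _compactness(coords: np.ndarray) -> float:
    """Area over convex-hull area (1 for convex objects)."""
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    mask = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    mask[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(mask)
    return float(mask.sum() / hull.sum())


def morphology_profile(
    regions: Sequence[Region],
    intensity_image: IntensityImage,
    group: str = "custom",
) -> pd.DataFrame:
    """Per-object morphology table for one group.

    Columns: ``area_um2``, ``roundness`` (4πA/P², clamped to 1),
    ``symmetry`` (overlap with the 180°-rotated self), ``compactness``
    (area / convex-hull area), ``intensity`` (object mean) and
    ``spot_intensity`` (object mean minus the image median background).
    """
    if not regions:
        raise ValueError("empty region set")
    pixels = np.asarray(intensity_image.pixels, dtype=float)
    background = float(np.median(pixels))
    rows = []
    for reg in regions:
        roundness = (
            1.0
            if reg.perimeter_px == 0
            else min(1.0, 4.0 * math.pi * reg.area_px2 / reg.perimeter_px**2)
        )
        rows.append(
            {
                "group": group,
                "label": reg.label,
                "area_um2": reg.area_um2,
                "roundness": roundness,
                "symmetry": _symmetry_index(reg.coords),
                "compactness": _compactness(reg.coords),
                "intensity": reg.mean_intensity,
                "spot_intensity": reg.mean_intensity - background,
            }
        )
    return pd.DataFrame(rows)


MORPHOLOGY_PARAMETERS = ["area_um2", "roundness", "symmetry", "compactness", "intensity", "spot_intensity"]


def normalize_profiles(profiles: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Group mean ± SD per parameter, relative to the reference group's mean.

    The reference group's normalized mean is 1 for every parameter by
    construction.
    """
    if reference_group not in set(profiles["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")
    ref_means = profiles[profiles["group"] == reference_group][MORPHOLOGY_PARAMETERS].mean()
    rows = []
    for group, sub in profiles.groupby("group"):
        for param in MORPHOLOGY_PARAMETERS:
            denom = ref_means[param]
            rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "normalized_mean": sub[param].mean() / denom,
                    "normalized_sd": sub[param].std(ddof=1) / abs(denom) if len(sub) > 1 else 0.0,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mann–Whitney U
# --------------------------------------------------------------------------


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    stars: str
    method: str  # "exact" | "asymptotic"


def mann_whitney_compare(
    group_a: Sequence[float], group_b: Sequence[float], max_exact: int = 200_000
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test with an exact small-sample path.

    The U statistic for group A uses midranks (ties allowed).  When the
    number of label assignments C(n_a+n_b, n_a) is at most ``max_exact``,
    the permutation distribution is enumerated exhaustively and the
    two-sided p-value is P(|U − n_a·n_b/2| ≥ |u − n_a·n_b/2|), using the
    symmetry of the permutation distribution about n_a·n_b/2; otherwise the
    normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    if math.comb(na + nb, na) <= max_exact:
        n = na + nb
        obs_dev = abs(u_obs - mu)
        extreme = 0
        total = 0
        rank_arr = ranks  # midranks of the observed pooled sample
        for subset in combinations(range(n), na):
            r_sum = rank_arr[list(subset)].sum()
            u = r_sum - na * (na + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
        return MannWhitneyResult(U=u_obs, p=float(p), stars=star_code(float(p)), method="exact")

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), stars=star_code(float(res.pvalue)), method="asymptotic")
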