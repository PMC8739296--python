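"""Synthetic scenes and spectra with exact ground truth.

The generators emulate the three imaging modalities the analysis pipeline
operates on — CARS/TPEF micrographs, two-channel fluorescence images and
Raman hyperspectral cubes — with fully known ground truth, so every stage
of the pipeline can be validated by parameter recovery.  All randomness
flows from a single explicit seed through one generator stream per scene.

Conventions
-----------
* Lipid-body (LB) spots are rendered as isotropic Gaussians whose nominal
  radius is 2σ, so a thresholded spot covers approximately π·r² pixels and
  the 2–20 px equivalent-diameter particle gate is meaningful.
* Cytoplasm carries a low-amplitude smoothed-noise texture so background
  subtraction is exercised non-trivially.
* Per-cell LB-count laws are pluggable (constant, Poisson, zero-inflated
  Poisson); zero inflation mirrors real per-cell counts where the largest
  fraction of cells shows no LB in the focal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .image import IntensityImage


class PackingError(ValueError):
    """Raised when the requested cells cannot be placed in the frame."""


# --------------------------------------------------------------------------
# count laws
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantLaw:
    value: int

    @property
    def mean(self) -> float:
        return float(self.value)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value, dtype=int)


@dataclass(frozen=True)
class PoissonLaw:
    mean_: float

    @property
    def mean(self) -> float:
        return float(self.mean_)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.poisson(self.mean_, size=n)


@dataclass(frozen=True)
class ZeroInflatedPoissonLaw:
    """With probability ``zero_fraction`` a cell has no LBs; otherwise Poisson."""

    poisson_mean: float
    zero_fraction: float

    @property
    def mean(self) -> float:
        return (1.0 - self.zero_fraction) * self.poisson_mean

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        counts = rng.poisson(self.poisson_mean, size=n)
        counts[rng.random(n) < self.zero_fraction] = 0
        return counts


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------


@dataclass
class LBRecord:
    cell_label: int
    center: Tuple[float, float]  # (x, y) px
    radius: float  # px (2σ of the rendered Gaussian)
    amplitude: float


@dataclass
class CellRegion:
    label: int
    center: Tuple[float, float]  # (x, y) px
    radius: float  # px


@dataclass
class SceneGroundTruth:
    """Exact record of what a generated scene contains."""

    frame_shape: Tuple[int, int]
    cell_regions: List[CellRegion]
    lb_records: List[LBRecord]

    @property
    def per_cell_lb_count(self) -> Dict[int, int]:
        counts = {c.label: 0 for c in self.cell_regions}
        for lb in self.lb_records:
            counts[lb.cell_label] += 1
        return counts

    @property
    def n_lbs(self) -> int:
        return len(self.lb_records)

    def mean_lb_count(self) -> float:
        counts = self.per_cell_lb_count
        return float(np.mean(list(counts.values()))) if counts else 0.0

    def cell_label_image(self) -> np.ndarray:
        """Rasterize the cell regions into a label image (0 = background)."""
        labels = np.zeros(self.frame_shape, dtype=np.int32)
        yy, xx = np.mgrid[0 : self.frame_shape[0], 0 : self.frame_shape[1]]
        for cell in self.cell_regions:
            cx, cy = cell.center
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell.radius**2
            labels[inside] = cell.label
        return labels

    def validate(self) -> None:
        """Check internal consistency: every LB belongs to, and lies inside, its cell."""
        by_label = {c.label: c for c in self.cell_regions}
        for lb in self.lb_records:
            if lb.cell_label not in by_label:
                raise AssertionError(f"LB references unknown cell {lb.cell_label}")
            cell = by_label[lb.cell_label]
            d = math.hypot(lb.center[0] - cell.center[0], lb.center[1] - cell.center[1])
            if d > cell.radius:
                raise AssertionError(f"LB at {lb.center} lies outside cell {lb.cell_label}")
        tally: Dict[int, int] = {c.label: 0 for c in self.cell_regions}
        for lb in self.lb_records:
            tally[lb.cell_label] += 1
        if tally != self.per_cell_lb_count:
            raise AssertionError("per-cell count table inconsistent with LB records")

    def to_json_dict(self) -> dict:
        return {
            "frame_shape": list(self.frame_shape),
            "cell_regions": [
                {"label": c.label, "center": list(c.center), "radius": c.radius} for c in self.cell_regions
            ],
            "lb_records": [
                {
                    "cell_label": r.cell_label,
                    "center": list(r.center),
                    "radius": r.radius,
                    "amplitude": r.amplitude,
                }
                for r in self.lb_records
            ],
        }


# --------------------------------------------------------------------------
# scene rendering helpers
# --------------------------------------------------------------------------


def _grid_centers(
    n_cells: int,
    spacing: float,
    jitter: float,
    rng: np.random.Generator,
    frame: Optional[Tuple[int, int]],
) -> Tuple[Tuple[int, int], List[Tuple[float, float]]]:
    """Lay cells on a jittered square grid; guarantees non-overlap by spacing."""
    ncols = int(math.ceil(math.sqrt(n_cells)))
    nrows = int(math.ceil(n_cells / ncols))
    auto_frame = (int(math.ceil(nrows * spacing)), int(math.ceil(ncols * spacing)))
    if frame is None:
        frame = auto_frame
    else:
        if frame[0] < auto_frame[0] or frame[1] < auto_frame[1]:
            raise PackingError(
                f"cannot place {n_cells} cells with spacing {spacing:.0f}px in frame {frame}; "
                f"needs at least {auto_frame}"
            )
        nrows = int(frame[0] // spacing)
        ncols = int(frame[1] // spacing)
        if nrows * ncols < n_cells:
            raise PackingError(f"frame {frame} holds at most {nrows * ncols} cells at spacing {spacing:.0f}px")
    slots = [(i, j) for i in range(nrows) for j in range(ncols)]
    chosen = [slots[k] for k in rng.permutation(len(slots))[:n_cells]]
    centers = []
    for i, j in chosen:
        cy = (i + 0.5) * spacing + rng.uniform(-jitter, jitter)
        cx = (j + 0.5) * spacing + rng.uniform(-jitter, jitter)
        centers.append((cx, cy))
    return frame, centers


def _add_gaussian_spot(img: np.ndarray, cx: float, cy: float, sigma: float, amplitude: float) -> None:
    r = int(math.ceil(4 * sigma))
    x0, x1 = int(cx) - r, int(cx) + r + 1
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x1, img.shape[1]), min(y1, img.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    img[y0c:y1c, x0c:x1c] += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def _place_points_in_disk(
    rng: np.random.Generator,
    center: Tuple[float, float],
    radius: float,
    point_radii: Sequence[float],
    sep_factor: float = 2.4,
    max_tries: int = 200,
) -> List[Tuple[float, float]]:
    """Sample one point per entry of ``point_radii`` inside a disk.

    Pairwise separation scales with the larger of the two point radii
    (``sep_factor`` × max(rᵢ, rⱼ)) so rendered spots stay resolvable; the
    separation is relaxed gradually if the packing is tight, so the
    requested count is always honoured.
    """
    points: List[Tuple[float, float]] = []
    radii: List[float] = []
    relax = 1.0
    for r_new in point_radii:
        placed = False
        tries = 0
        while not placed:
            tries += 1
            rho = radius * math.sqrt(rng.random())
            theta = rng.uniform(0, 2 * math.pi)
            p = (center[0] + rho * math.cos(theta), center[1] + rho * math.sin(theta))
            ok = all(
                math.hypot(p[0] - q[0], p[1] - q[1]) >= relax * sep_factor * max(r_new, r_old)
                for q, r_old in zip(points, radii)
            )
            if ok:
                points.append(p)
                radii.append(r_new)
                placed = True
            elif tries % max_tries == 0:
                relax *= 0.8  # tight cell: relax separation rather than drop the LB
    return points


def _smoothed_noise(rng: np.random.Generator, shape: Tuple[int, int], sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


# --------------------------------------------------------------------------
# CARS / TPEF scene
# --------------------------------------------------------------------------


def make_cars_tpef_scene(
    n_cells: int,
    lb_count_law,
    lb_radius_range: Tuple[float, float] = (3.0, 6.0),
    noise_sd: float = 30.0,
    seed: int = 0,
    frame: Optional[Tuple[int, int]] = None,
    cell_radius_range: Tuple[float, float] = (34.0, 42.0),
    cytoplasm_level: float = 900.0,
    texture_sd: float = 120.0,
    lb_amplitude_range: Tuple[float, float] = (8000.0, 11000.0),
    background_level: float = 100.0,
) -> Tuple[Tuple[IntensityImage, IntensityImage], SceneGroundTruth]:
    """Generate a CARS/TPEF image pair with exact ground truth.

    The CARS channel contains textured cytoplasm disks with bright Gaussian
    LB spots plus additive Gaussian noise; the TPEF channel contains one
    nucleus blob per cell.  Cells are placed on a jittered grid away from
    the frame edges, so they never overlap and never touch the border.

    Parameters
    ----------
    lb_count_law : ConstantLaw | PoissonLaw | ZeroInflatedPoissonLaw
        Per-cell law for the number of LBs.
    lb_radius_range : (float, float)
        Nominal LB radii in px (radius = 2σ of the rendered Gaussian); must
        stay within [1, 10] px so detectable particles respect the
        2–20 px diameter particle gate.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not (1.0 <= lb_radius_range[0] <= lb_radius_range[1] <= 10.0):
        raise ValueError("lb_radius_range must lie within [1, 10] px radius")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        shape = frame or (64, 64)
        empty = SceneGroundTruth(frame_shape=shape, cell_regions=[], lb_records=[])
        zero = np.zeros(shape)
        return (
            (IntensityImage(_to_uint16(zero)), IntensityImage(_to_uint16(zero))),
            empty,
        )

    r_max = cell_radius_range[1]
    spacing = 2 * r_max + 16
    jitter = max(0.0, spacing / 2 - r_max - 4)
    shape, centers = _grid_centers(n_cells, spacing, jitter, rng, frame)

    cars = np.full(shape, background_level, dtype=float)
    tpef = np.full(shape, background_level * 0.5, dtype=float)
    cyto_layer = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    cells: List[CellRegion] = []
    lb_records: List[LBRecord] = []
    counts = lb_count_law.sample(rng, n_cells)
    texture = _smoothed_noise(rng, shape, sigma=4.0) * texture_sd

    for idx, (cx, cy) in enumerate(centers):
        label = idx + 1
        radius = rng.uniform(*cell_radius_range)
        cells.append(CellRegion(label=label, center=(cx, cy), radius=radius))
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        cyto_layer[inside] += cytoplasm_level + texture[inside]
        # nucleus blob in the TPEF channel
        _add_gaussian_spot(tpef, cx, cy, sigma=radius * 0.38, amplitude=3000.0)
    # cell boundaries are diffraction-blurred, not 1-px steps
    cars += ndi.gaussian_filter(cyto_layer, sigma=2.5)

    for cell, n_lb in zip(cells, counts):
        label = cell.label
        (cx, cy), radius = cell.center, cell.radius
        n_lb = int(n_lb)
        interior = max(radius - 2.5 * lb_radius_range[1], radius * 0.35)
        lb_radii = rng.uniform(*lb_radius_range, size=n_lb)
        pts = _place_points_in_disk(rng, (cx, cy), interior, lb_radii)
        for (px, py), lb_radius in zip(pts, lb_radii):
            # peak brightness grows superquadratically with droplet radius
            # (more lipid in the focal volume), so small droplets are dimmer
            size_factor = (lb_radius / 4.5) ** 2.5
            amp = rng.uniform(*lb_amplitude_range) * size_factor
            _add_gaussian_spot(cars, px, py, sigma=lb_radius / 2.0, amplitude=amp)
            lb_records.append(LBRecord(cell_label=label, center=(px, py), radius=float(lb_radius), amplitude=amp))

    cars += rng.normal(0.0, noise_sd, size=shape)
    tpef += rng.normal(0.0, noise_sd * 0.5, size=shape)

    truth = SceneGroundTruth(frame_shape=shape, cell_regions=cells, lb_records=lb_records)
    truth.validate()
    return (IntensityImage(_to_uint16(cars)), IntensityImage(_to_uint16(tpef))), truth


# --------------------------------------------------------------------------
# fluorescence scene
# --------------------------------------------------------------------------


def make_fluorescence_scene(
    n_cells: int,
    lb_count_law,
    pixel_size: float = 0.65,
    seed: int = 0,
    frame: Optional[Tuple[int, int]] = None,
    nucleus_diameter_um: Tuple[float, float] = (9.0, 12.0),
    spot_radius_um: Tuple[float, float] = (1.0, 1.6),
    noise_sd: float = 25.0,
) -> Tuple[Tuple[IntensityImage, IntensityImage], SceneGroundTruth]:
    """Generate a Hoechst/BODIPY fluorescence image pair with ground truth.

    Channel 1 emulates Hoechst-stained nuclei (smooth disks, well above the
    5 µm² area gate), channel 2 BODIPY-stained LB spots (above the 2 µm²
    gate) placed in a cytoplasmic annulus around each nucleus.  The cell
    region recorded in the ground truth is the whole cell footprint.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive (µm/px)")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        shape = frame or (64, 64)
        empty = SceneGroundTruth(frame_shape=shape, cell_regions=[], lb_records=[])
        zero = np.zeros(shape)
        return (
            (IntensityImage(_to_uint16(zero), pixel_size=pixel_size), IntensityImage(_to_uint16(zero), pixel_size=pixel_size)),
            empty,
        )

    nuc_r_px_max = nucleus_diameter_um[1] / 2.0 / pixel_size
    cell_r_px = nuc_r_px_max * 2.2  # cytoplasm footprint
    spacing = 2 * cell_r_px + 10
    jitter = max(0.0, spacing / 2 - cell_r_px - 3)
    shape, centers = _grid_centers(n_cells, spacing, jitter, rng, frame)

    hoechst = np.full(shape, 80.0, dtype=float)
    bodipy = np.full(shape, 80.0, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    cells: List[CellRegion] = []
    lb_records: List[LBRecord] = []
    counts = lb_count_law.sample(rng, n_cells)
    spot_r_px = (spot_radius_um[0] / pixel_size, spot_radius_um[1] / pixel_size)

    for idx, (cx, cy) in enumerate(centers):
        label = idx + 1
        nuc_r = rng.uniform(*nucleus_diameter_um) / 2.0 / pixel_size
        cells.append(CellRegion(label=label, center=(cx, cy), radius=cell_r_px))
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= nuc_r**2
        hoechst[disk] += 2500.0
        n_lb = int(counts[idx])
        # spots live in the cytoplasm disk around the nucleus
        spot_radii = rng.uniform(*spot_radius_um, size=n_lb) / pixel_size
        pts = _place_points_in_disk(
            rng, (cx, cy), cell_r_px - 1.5 * spot_r_px[1], spot_radii, sep_factor=4.0
        )
        for (px, py), r_px in zip(pts, spot_radii):
            amp = rng.uniform(2500.0, 5000.0)
            _add_gaussian_spot(bodipy, px, py, sigma=r_px / 2.0, amplitude=amp)
            lb_records.append(LBRecord(cell_label=label, center=(px, py), radius=r_px, amplitude=amp))

    hoechst = ndi.gaussian_filter(hoechst, sigma=1.0)
    hoechst += rng.normal(0.0, noise_sd, size=shape)
    bodipy += rng.normal(0.0, noise_sd, size=shape)

    truth = SceneGroundTruth(frame_shape=shape, cell_regions=cells, lb_records=lb_records)
    truth.validate()
    return (
        (
            IntensityImage(_to_uint16(hoechst), pixel_size=pixel_size),
            IntensityImage(_to_uint16(bodipy), pixel_size=pixel_size),
        ),
        truth,
    )


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------


def default_wavenumber_axis(start: float = 600.0, stop: float = 3100.0, step: float = 2.0) -> np.ndarray:
    return np.arange(start, stop + step / 2, step, dtype=float)


def _gaussian_band(axis: np.ndarray, center: float, width: float, area: float) -> np.ndarray:
    return area / (width * math.sqrt(2 * math.pi)) * np.exp(-((axis - center) ** 2) / (2 * width**2))


@dataclass
class SpectralComponents:
    """Named nonnegative component spectra on a shared wavenumber axis."""

    wavenumber_axis: np.ndarray
    components: Dict[str, np.ndarray]
    band_table: Dict[str, List[Tuple[float, float, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, spec in self.components.items():
            if spec.shape != self.wavenumber_axis.shape:
                raise AssertionError(f"component {name!r} not on the shared axis")
            if np.any(spec < 0):
                raise AssertionError(f"component {name!r} has negative intensity")


# band tables: (center cm⁻¹, width cm⁻¹, relative area)
_LIPID_BANDS = [
    (2850.0, 12.0, 3.0),   # ν(C–H) methylene stretch
    (1744.0, 8.0, 0.5),    # ν(C=O) triacylglycerol ester
    (1660.0, 8.0, 0.6),    # ν(C=C) olefinic stretch
    (1440.0, 10.0, 1.0),   # δ(CH₂/CH₃) scissoring
    (1304.0, 9.0, 0.5),    # τ(CH₂) twist
    (1269.0, 8.0, 0.35),   # β(=CH) deformation
]
_PROTEIN_BANDS = [
    (1003.0, 5.0, 0.5),    # phenylalanine ring breathing
    (1450.0, 12.0, 0.8),
    (1657.0, 14.0, 1.0),   # amide I
    (2935.0, 18.0, 2.0),
]
_DNA_BANDS = [
    (788.0, 8.0, 1.0),     # O–P–O backbone / pyrimidine breathing, inside 780–800
    (1094.0, 9.0, 0.5),
    (1340.0, 10.0, 0.4),
    (1578.0, 9.0, 0.5),
    (2955.0, 16.0, 0.8),
]
_EPO_BANDS = [
    (753.0, 6.0, 0.8),
    (1311.0, 7.0, 0.5),
    (1374.0, 7.0, 0.6),
    (1554.0, 7.0, 0.5),
    (1564.0, 7.0, 0.5),
    (1588.0, 7.0, 0.7),
]


def default_spectral_components(axis: Optional[np.ndarray] = None) -> SpectralComponents:
    """Reference component spectra: lipid, protein/cytoplasm, DNA, EPO.

    Each component is a sum of Gaussian bands at its marker positions
    (lipid CH₂/C=C/C=O bands; DNA backbone band inside 780–800 cm⁻¹;
    eosinophil-peroxidase resonance bands at 753–1588 cm⁻¹).
    """
    axis = default_wavenumber_axis() if axis is None else np.asarray(axis, dtype=float)
    tables = {
        "lipid": _LIPID_BANDS,
        "protein": _PROTEIN_BANDS,
        "dna": _DNA_BANDS,
        "epo": _EPO_BANDS,
    }
    comps = {}
    for name, bands in tables.items():
        spec = np.zeros_like(axis)
        for center, width, area in bands:
            spec += _gaussian_band(axis, center, width, area)
        comps[name] = spec
    sc = SpectralComponents(wavenumber_axis=axis, components=comps, band_table=dict(tables))
    sc.validate()
    return sc


_FATTY_ACID_NAMES = {1: "oleic (18:1)", 2: "linoleic (18:2)", 3: "alpha-linolenic (18:3)"}


def reference_fatty_acid_spectra(
    double_bond_counts: Sequence[int], axis: Optional[np.ndarray] = None
) -> SpectralComponents:
    """Noise-free reference spectra of fatty acids with 1–3 C=C bonds.

    By construction the integrated 1660 cm⁻¹ (C=C stretch) band area is
    proportional to the double-bond count while the 1440 cm⁻¹ (CH₂
    scissoring) area is identical across references, so the 1660/1440
    band-area ratio is exactly linear in the C=C count.
    """
    axis = default_wavenumber_axis() if axis is None else np.asarray(axis, dtype=float)
    comps: Dict[str, np.ndarray] = {}
    table: Dict[str, List[Tuple[float, float, float]]] = {}
    for count in double_bond_counts:
        if count not in _FATTY_ACID_NAMES:
            raise ValueError(f"unsupported C=C count {count}; supported: 1, 2, 3")
        name = _FATTY_ACID_NAMES[count]
        bands = [
            (center, width, area * count if center in (1660.0, 1269.0) else area)
            for center, width, area in _LIPID_BANDS
        ]
        spec = np.zeros_like(axis)
        for center, width, area in bands:
            spec += _gaussian_band(axis, center, width, area)
        comps[name] = spec
        table[name] = bands
    sc = SpectralComponents(wavenumber_axis=axis, components=comps, band_table=table)
    sc.validate()
    return sc


# --------------------------------------------------------------------------
# Raman cube
# --------------------------------------------------------------------------


def make_raman_cube(
    layout: np.ndarray,
    mixing: Dict[str, Dict[str, float]],
    baseline_coeffs: Optional[Sequence[float]] = None,
    cosmic_ray_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    components: Optional[SpectralComponents] = None,
    spike_amplitude: float = 5000.0,
):
    """Build a hyperspectral cube from a per-pixel class layout.

    Each pixel's spectrum is the nonnegative mixture of component spectra
    prescribed for its class, plus an optional polynomial baseline (degree
    ≤ 3, evaluated on the axis normalized to [0, 1]), random single-channel
    cosmic-ray spikes (per-spectrum probability ``cosmic_ray_rate``) and
    i.i.d. Gaussian noise.  Spike positions are recorded in the ground
    truth.

    Returns
    -------
    (SpectralCube, dict)
        The cube and a ground-truth dict with keys ``class_map`` (the
        layout) and ``spikes`` (list of (pixel_index, channel_index)).
    """
    from .raman import SpectralCube  # local import to avoid a cycle

    layout = np.asarray(layout)
    if layout.ndim != 2:
        raise ValueError("layout must be a 2-D class map")
    comps = components or default_spectral_components()
    axis = comps.wavenumber_axis
    if baseline_coeffs is not None and len(baseline_coeffs) > 4:
        raise ValueError("baseline polynomial degree must be <= 3")

    class_names = sorted({str(c) for c in layout.ravel()})
    for cname in class_names:
        if cname not in mixing:
            raise ValueError(f"layout references unknown class {cname!r}")
    for cname, weights in mixing.items():
        for comp_name, w in weights.items():
            if comp_name not in comps.components:
                raise ValueError(f"unknown component {comp_name!r} in class {cname!r}")
            if w < 0:
                raise ValueError("mixing weights must be nonnegative")

    class_spectrum = {
        cname: sum(
            (w * comps.components[comp_name] for comp_name, w in mixing[cname].items()),
            np.zeros_like(axis),
        )
        for cname in class_names
    }

    rng = np.random.default_rng(seed)
    n_pix = layout.size
    n_wn = axis.size
    spectra = np.zeros((n_pix, n_wn), dtype=float)
    flat = layout.ravel()
    for i in range(n_pix):
        spectra[i] = class_spectrum[str(flat[i])]

    if baseline_coeffs is not None:
        u = (axis - axis[0]) / (axis[-1] - axis[0])
        baseline = np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs, dtype=float))
        spectra += baseline[None, :]

    spikes: List[Tuple[int, int]] = []
    if cosmic_ray_rate > 0:
        hit = rng.random(n_pix) < cosmic_ray_rate
        for i in np.nonzero(hit)[0]:
            ch = int(rng.integers(0, n_wn))
            spectra[i, ch] += spike_amplitude
            spikes.append((int(i), ch))

    if noise_sd > 0:
        spectra += rng.normal(0.0, noise_sd, size=spectra.shape)

    cube = SpectralCube(spectra=spectra, wavenumber_axis=axis.copy(), spatial_shape=layout.shape)
    truth = {"class_map": layout.copy(), "spikes": spikes}
    return cube, truth
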