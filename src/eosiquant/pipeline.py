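"""End-to-end runs: synthetic-scene recovery experiments and the demo pipeline.

The recovery functions are the package's verification experiments: they
generate a synthetic scene whose ground-truth per-cell LB law (or lipid
unsaturation) is known, run the full analysis chain on the rendered data,
and return the estimate next to the truth.  ``run_pipeline`` ties the
stages into a reproducible result bundle on disk.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import cars, cells, fluor, raman, stats, synthetic
from .config import RunConfig, stage_seed


@dataclass
class RecoveryResult:
    """Outcome of one parameter-recovery experiment."""

    estimate: float
    true_mean: float  # mean of the generating law
    realized_mean: float  # ground-truth mean actually rendered
    sem: float  # standard error of the estimate
    n: int  # cells (or images/spectra) the estimate is based on

    @property
    def within_3sem(self) -> bool:
        band = 3.0 * self.sem if self.sem > 0 else 0.0
        return abs(self.estimate - self.true_mean) <= band


def _train_default_classifier(
    seed: int, lb_mean: float = 2.0, n_train_images: int = 2, n_cells: int = 9
) -> cells.PixelClassifier:
    """Train the pixel classifier on ground-truth-labelled synthetic composites.

    Training images are drawn from the same imaging condition (LB-count law)
    as the scenes to be analysed, mirroring the practice of training the
    segmentation model on manually classified images of the dataset itself:
    the per-image contrast stretch makes absolute channel levels depend on
    scene composition, so a model trained on unrepresentative images does
    not transfer.
    """
    examples = []
    for i in range(n_train_images):
        (cars_img, tpef_img), truth = synthetic.make_cars_tpef_scene(
            n_cells=n_cells,
            lb_count_law=synthetic.PoissonLaw(lb_mean),
            seed=stage_seed(seed, f"train-{i}"),
        )
        rgb = cells.compose_rgb(cars_img, tpef_img)
        examples.append((rgb, truth.cell_label_image() > 0))
    return cells.train_pixel_classifier(examples, seed=stage_seed(seed, "classifier"))


def recover_cars_group_mean(
    true_mean: float,
    n_cells: int = 150,
    seed: int = 0,
    threshold_mode: str = "relative_mean",
    classifier: Optional[cells.PixelClassifier] = None,
) -> RecoveryResult:
    """Estimate the group mean LBs/cell with the full CARS pipeline.

    Synthetic CARS/TPEF scenes are generated with per-cell LB counts drawn
    from a Poisson law of the given mean (radii 3–6 px, high SNR, isolated
    in-plane spots); the chain is LB detection on the CARS channel, cell
    segmentation (trainable classifier + mask cleaning) and centroid
    assignment of spots to cells.
    """
    (cars_img, tpef_img), truth = synthetic.make_cars_tpef_scene(
        n_cells=n_cells,
        lb_count_law=synthetic.PoissonLaw(true_mean),
        seed=stage_seed(seed, "scene"),
    )
    model = classifier or _train_default_classifier(seed, lb_mean=true_mean)
    rgb = cells.compose_rgb(cars_img, tpef_img)
    mask = cells.predict_cell_mask(rgb, model)
    cell_set = cells.clean_mask(mask)
    spot_set = cars.detect_lipid_bodies(cars_img, cars.CarsDetectionConfig(threshold_mode=threshold_mode))
    counts = cells.assign_spots_to_cells(cell_set, spot_set)
    values = np.asarray(counts.values(), dtype=float)
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return RecoveryResult(
        estimate=float(values.mean()),
        true_mean=true_mean,
        realized_mean=truth.mean_lb_count(),
        sem=sem,
        n=int(values.size),
    )


def recover_fluorescence_group_mean(
    true_mean: float,
    n_images: int = 4,
    cells_per_image: int = 75,
    pixel_size: float = 0.65,
    seed: int = 0,
) -> RecoveryResult:
    """Estimate mean LBs/cell with the fluorescence pipeline.

    ``n_images`` synthetic Hoechst/BODIPY image pairs are generated with
    per-cell LB counts from a Poisson law of the given mean; nuclei and
    spots are counted per image and the group value is the mean of image
    means with the between-image SEM.
    """
    per_image = []
    for i in range(n_images):
        (hoechst, bodipy), _ = synthetic.make_fluorescence_scene(
            n_cells=cells_per_image,
            lb_count_law=synthetic.PoissonLaw(true_mean),
            pixel_size=pixel_size,
            seed=stage_seed(seed, f"fluor-{i}"),
        )
        nuclei = fluor.find_nuclei(hoechst)
        spots = fluor.find_spots(bodipy, nuclei)
        per_image.append((len(spots), len(nuclei)))
    summary = fluor.lbs_per_cell_ratio(per_image)
    return RecoveryResult(
        estimate=summary.mean,
        true_mean=true_mean,
        realized_mean=float("nan"),
        sem=summary.sem,
        n=summary.n_images,
    )


def recover_unsaturation(
    true_mean_cc: float = 1.5,
    n_spectra: int = 50,
    noise_sd: float = 0.0004,
    seed: int = 0,
) -> RecoveryResult:
    """Recover the mean C=C bond count from synthetic LB spectra.

    Noise-free oleic (18:1), linoleic (18:2) and α-linolenic (18:3)
    references calibrate the 1660/1440 band-ratio-vs-C=C line; LB spectra
    are oleic/linoleic mixtures whose per-spectrum mixing fraction averages
    to the requested mean count, rendered with a cubic baseline and small
    additive noise, then pushed through baseline correction, the
    unsaturation ratio and the calibration inversion.
    """
    if not 1.0 <= true_mean_cc <= 2.0:
        raise ValueError("oleic/linoleic mixtures cover mean C=C counts in [1, 2]")
    refs = synthetic.reference_fatty_acid_spectra([1, 2, 3])
    axis = refs.wavenumber_axis
    by_count = {
        1: refs.components["oleic (18:1)"],
        2: refs.components["linoleic (18:2)"],
        3: refs.components["alpha-linolenic (18:3)"],
    }
    calibration = raman.fit_unsaturation_calibration({k: by_count[k] for k in (1, 2, 3)}, axis)

    rng = np.random.default_rng(stage_seed(seed, "lb-spectra"))
    # per-spectrum linoleic weight; mean weight = true_mean - 1 so the mean
    # C=C count over spectra equals the requested truth
    w_mean = true_mean_cc - 1.0
    half_spread = min(w_mean, 1.0 - w_mean, 0.25)
    weights = rng.uniform(w_mean - half_spread, w_mean + half_spread, size=n_spectra)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = 0.002 + 0.004 * u - 0.003 * u**2 + 0.002 * u**3
    estimates = []
    for w in weights:
        spec = (1.0 - w) * by_count[1] + w * by_count[2] + baseline
        spec = spec + rng.normal(0.0, noise_sd, size=axis.size)
        corrected = raman.baseline_correct(spec, axis)
        ratio = raman.unsaturation_ratio(corrected, axis)
        estimates.append(calibration.estimate_double_bonds(ratio))
    est = np.asarray(estimates)
    sem = float(est.std(ddof=1) / math.sqrt(est.size)) if est.size > 1 else 0.0
    return RecoveryResult(
        estimate=float(est.mean()),
        true_mean=true_mean_cc,
        realized_mean=float(1.0 + weights.mean()),
        sem=sem,
        n=int(est.size),
    )


# --------------------------------------------------------------------------
# demo pipeline
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Run the synthetic CARS demo end-to-end and write a result bundle.

    Generates a scene per the config, runs detection, cell segmentation
    and per-cell counting, writes ``percell.csv``, ``spots.csv``,
    ``labels.tif`` and ``summary.json`` (parameters + seed + output
    hashes), and returns the summary dict.  Identical config + seed give
    identical bundle hashes.
    """
    from . import io as eio
    from .image import IntensityImage

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (cars_img, tpef_img), truth = synthetic.make_cars_tpef_scene(
        n_cells=config.n_cells,
        lb_count_law=synthetic.PoissonLaw(config.lb_mean),
        seed=stage_seed(config.seed, "scene"),
    )
    model = _train_default_classifier(config.seed, lb_mean=config.lb_mean)
    rgb = cells.compose_rgb(cars_img, tpef_img, config.saturation_fraction)
    mask = cells.predict_cell_mask(rgb, model)
    cell_set = cells.clean_mask(mask, hole_max=config.hole_max, min_cell_area=config.min_cell_area)
    det_config = cars.CarsDetectionConfig(
        ball_radius=config.ball_radius,
        log_scale=config.log_scale,
        bandpass_small=config.bandpass_small,
        bandpass_large=config.bandpass_large,
        threshold_mode=config.threshold_mode,
        relative_mean_factor=config.relative_mean_factor,
        min_area=config.min_spot_area,
        max_area=config.max_spot_area,
        min_circularity=config.min_circularity,
    )
    spot_set = cars.detect_lipid_bodies(cars_img, det_config)
    counts = cells.assign_spots_to_cells(cell_set, spot_set)
    summary_stats = stats.percent_rank(counts.values()) if counts.counts else None

    counts.to_dataframe().to_csv(out / "percell.csv", index=False)
    spot_set.to_dataframe().to_csv(out / "spots.csv", index=False)
    eio.write_image(IntensityImage(cell_set.label_image.astype(np.uint16)), out / "labels.tif")

    # conservation audit across the whole run
    audit = {
        "spots_total": spot_set.count,
        "spots_assigned": counts.total_assigned,
        "spots_orphaned": counts.orphan_count,
        "cells_candidates": len(cell_set.records),
        "cells_retained": cell_set.n_retained,
        "cells_excluded": len(cell_set.records) - cell_set.n_retained,
        "true_lb_total": truth.n_lbs,
    }
    assert audit["spots_assigned"] + audit["spots_orphaned"] == audit["spots_total"]

    summary = {
        "config": config.to_dict(),
        "stage_order": [
            "simulate", "compose_rgb", "pixel_classifier", "clean_mask",
            "detect_lipid_bodies", "assign_spots_to_cells", "percent_rank",
        ],
        "audit": audit,
        "estimated_mean_lbs_per_cell": counts.mean() if counts.counts else None,
        "true_mean_lbs_per_cell": truth.mean_lb_count(),
        "median": summary_stats.median if summary_stats else None,
        "zero_fraction": stats.zero_fraction(counts.values()) if counts.counts else None,
        "hashes": {},
    }
    for name in ("percell.csv", "spots.csv", "labels.tif"):
        summary["hashes"][name] = _sha256(out / name)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
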