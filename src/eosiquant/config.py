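"""Run configuration: every stage parameter with its reference default.

The defaults are the protocol values of the analysis this package
implements (rolling-ball radius 3 px, Laplacian smoothing scale 1, FFT
bandpass 2–20 px, relative-mean threshold factor 1.4, circularity gate 0.5,
particle area window π·2²/4–π·20²/4 px², hole-fill limit 500 px, minimum
cell area 2500 px, 3.5 % contrast saturation, 2 µm² spot and 5 µm² nucleus
gates, cosmic-ray filter 3/8, baseline degree 3, PCA region
600–1800 cm⁻¹).  The config round-trips losslessly through JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    # synthetic scene
    n_cells: int = 50
    lb_mean: float = 2.0
    # CARS detection chain
    ball_radius: float = 3.0
    log_scale: float = 1.0
    bandpass_small: float = 2.0
    bandpass_large: float = 20.0
    threshold_mode: str = "renyi"
    relative_mean_factor: float = 1.4
    min_circularity: float = 0.5
    min_spot_area: float = math.pi * 2**2 / 4.0
    max_spot_area: float = math.pi * 20**2 / 4.0
    # cell segmentation
    saturation_fraction: float = 0.035
    hole_max: int = 500
    min_cell_area: int = 2500
    # fluorescence
    pixel_size: float = 0.65
    nucleus_min_area_um2: float = 5.0
    spot_min_area_um2: float = 2.0
    # Raman
    cosmic_filter_size: int = 3
    cosmic_dynamic_factor: float = 8.0
    baseline_degree: int = 3
    kmeans_k: int = 4
    kmeans_restarts: int = 10
    pca_region: tuple = (600.0, 1800.0)
    # I/O
    out_dir: str = "results"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pca_region"] = list(d["pca_region"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pca_region" in d:
            d["pca_region"] = tuple(d["pca_region"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed.

    One global seed fans out to named stages so each stage is reproducible
    in isolation without coupling the random streams of different stages.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)
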