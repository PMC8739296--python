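import numpy as np
import pytest

from eosiquant import cells, synthetic
from eosiquant.synthetic import PoissonLaw


@pytest.fixture(scope="session")
def cars_scene():
    """Small CARS/TPEF scene with ground truth (16 cells, ~56 LBs)."""
    return synthetic.make_cars_tpef_scene(16, PoissonLaw(3.5), seed=101)


@pytest.fixture(scope="session")
def fluor_scene():
    """Small fluorescence scene with ground truth."""
    return synthetic.make_fluorescence_scene(25, PoissonLaw(2.35), pixel_size=0.65, seed=202)


@pytest.fixture(scope="session")
def raman_cube_with_truth():
    """20x20 four-class Raman cube with spikes, baseline and noise."""
    layout = np.empty((20, 20), dtype=object)
    layout[:] = "background"
    layout[2:10, 2:10] = "cytoplasm"
    layout[12:18, 2:8] = "lb"
    layout[4:9, 12:18] = "nucleus"
    mixing = {
        "background": {},
        "cytoplasm": {"protein": 1.0},
        "lb": {"lipid": 1.0},
        "nucleus": {"dna": 0.8, "protein": 0.4},
    }
    cube, truth = synthetic.make_raman_cube(
        layout,
        mixing,
        baseline_coeffs=[0.001, 0.002, 0.0, 0.0],
        cosmic_ray_rate=0.05,
        noise_sd=0.0005,
        seed=7,
        spike_amplitude=0.025,
    )
    return cube, truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Pixel classifier trained once on two labelled synthetic composites."""
    examples = []
    for i in range(2):
        (cars_img, tpef_img), truth = synthetic.make_cars_tpef_scene(
            9, PoissonLaw(2.0), seed=50 + i
        )
        rgb = cells.compose_rgb(cars_img, tpef_img)
        examples.append((rgb, truth.cell_label_image() > 0))
    return cells.train_pixel_classifier(examples, seed=5)
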