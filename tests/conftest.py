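"""Shared fixtures: synthetic corpora and session-trained models.

Training the two segmenters and the counter once per session keeps the
suite inside a desk-scale CPU budget; every test that needs a trained
model reuses these.  All randomness is seeded, so the fixtures are
reproducible across runs.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from colonycount import counter, preprocess, segmenter, synthetic

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# Published benchmark confusion matrix (rows = predicted class, columns =
# ground-truth class) used as input data for the evaluation-report tests.
BENCHMARK_MATRIX = np.array(
    [
        [485, 36, 0, 0, 3, 0, 0, 0, 0, 0],
        [19, 3002, 10, 3, 1, 0, 1, 0, 0, 0],
        [0, 37, 458, 15, 0, 0, 0, 0, 0, 0],
        [0, 1, 4, 97, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 58, 6, 0, 0, 0, 0],
        [0, 0, 0, 1, 3, 56, 5, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 71, 2, 1, 0],
        [0, 0, 0, 0, 0, 0, 4, 103, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 61, 3],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 75],
    ],
    dtype=int,
)

# Published per-class rows for the matrix above, in percent.
BENCHMARK_RECALL = [96.23, 97.59, 97.03, 83.62, 89.23, 90.32, 87.65, 98.10, 96.83, 96.15]
BENCHMARK_PRECISION = [92.56, 98.88, 89.80, 95.10, 90.63, 86.15, 95.95, 95.37, 95.31, 99.99]
BENCHMARK_RECOVERY = [96.23, 99.90, 99.36, 94.54, 95.38, 98.06, 98.77, 99.73, 99.40, 99.57]

N_PLATES = 44
N_TRAIN_PLATES = 36


@pytest.fixture(scope="session")
def plate_cfg():
    """Desk-scale plate geometry: 64 px plates, 5 components, 2-4 px colonies."""
    return synthetic.SynthConfig(
        image_size=(64, 64),
        n_components=5,
        colony_radius_range=(2.0, 4.0),
        seed=100,
    )


@pytest.fixture(scope="session")
def plate_corpus(plate_cfg):
    """Rendered plates with preprocessed unit images and ROI-limited views."""
    samples = synthetic.generate_plate_set(N_PLATES, plate_cfg)
    corpus = []
    for s in samples:
        unit = preprocess.preprocess_image(s.image)[0]
        dish_full = ndimage.binary_fill_holes(s.edge_mask)
        corpus.append(
            {
                "sample": s,
                "unit": unit,
                "roi_image": unit * dish_full[:, :, None],
                "interior": dish_full & ~s.edge_mask,
            }
        )
    return corpus


@pytest.fixture(scope="session")
def edge_training(plate_corpus):
    """Dish-edge segmenter trained at small scale, with its history."""
    ds = [(c["unit"], c["sample"].edge_mask) for c in plate_corpus]
    model = segmenter.build_segmenter(segmenter.SegmenterConfig(scale="small", seed=0))
    model, history = segmenter.train_segmenter(
        model,
        ds[:N_TRAIN_PLATES],
        segmenter.TrainConfig(epochs=10, fg_weight=8.0, flip_rate=0.0, seed=1),
        val_dataset=ds[N_TRAIN_PLATES:],
    )
    return model, history


@pytest.fixture(scope="session")
def edge_model(edge_training):
    return edge_training[0]


@pytest.fixture(scope="session")
def colony_training(plate_corpus):
    """Colony-region segmenter trained on ROI images, with its history."""
    ds = [(c["roi_image"], c["sample"].colony_mask) for c in plate_corpus]
    model = segmenter.build_segmenter(segmenter.SegmenterConfig(scale="small", seed=1))
    model, history = segmenter.train_segmenter(
        model,
        ds[:N_TRAIN_PLATES],
        segmenter.TrainConfig(epochs=14, fg_weight=1.0, flip_rate=0.5, seed=2),
        val_dataset=ds[N_TRAIN_PLATES:],
    )
    return model, history


@pytest.fixture(scope="session")
def colony_model(colony_training):
    return colony_training[0]


@pytest.fixture(scope="session")
def crop_cfg():
    """Crop generator matched to the plate corpus colony sizes."""
    return synthetic.SynthConfig(colony_radius_range=(2.0, 4.0), seed=200)


@pytest.fixture(scope="session")
def counter_model(crop_cfg):
    crops = synthetic.generate_crop_dataset(1200, crop_cfg)
    model, history = counter.train_counter(
        crops, counter.CounterConfig(epochs=14, seed=0)
    )
    model.history = history
    return model


@pytest.fixture(scope="session")
def easy_plate_cfg():
    """Well-separated single colonies: the easiest counting regime."""
    return synthetic.SynthConfig(
        image_size=(64, 64),
        n_components=6,
        colony_radius_range=(2.0, 4.0),
        count_distribution=[1.0] + [0.0] * 8,
        seed=300,
    )
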