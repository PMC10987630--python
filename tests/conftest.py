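import numpy as np
import pytest

from cspws.classifier import (
    ClassificationDataset,
    ClassifierConfig,
    RandomConvBackbone,
    repeated_stratified_cv,
)
from cspws.models import InstrumentModel
from cspws.processing import build_calibration
from cspws.synthetic import generate_dmap_dataset


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def calibration(instrument):
    return build_calibration(instrument, phi=0.35)


@pytest.fixture(scope="session")
def small_backbone():
    """Narrow fixed-seed CNN used throughout the classifier tests."""
    return RandomConvBackbone(out_dim=128, seed=0, channels=(8, 16, 32, 32))


@pytest.fixture(scope="session")
def strong_signal_dataset(small_backbone):
    """12 patients/arm, 8 cells each, well-separated D texture classes."""
    dmaps, pids, labels = generate_dmap_dataset(
        n_per_class=12, cells_per_patient=8, seed=0
    )
    return ClassificationDataset.from_dmaps(
        dmaps, pids, labels, small_backbone, out_size=(64, 64)
    )


@pytest.fixture(scope="session")
def strong_signal_report(strong_signal_dataset):
    """CV report on the strong-signal cohort (shared across tests)."""
    return repeated_stratified_cv(
        strong_signal_dataset, k=4, repeats=5, config=ClassifierConfig(), seed=0
    )
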