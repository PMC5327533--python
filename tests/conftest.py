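"""Shared fixtures: small simulated multi-study datasets and helpers."""

import numpy as np
import pandas as pd
import pytest

from mintpls import MultiStudyDataset, SimulationDesign, simulate_multistudy


def make_dataset(
    n_studies=2,
    n_classes=2,
    samples_per_class=6,
    n_variables=15,
    n_informative=5,
    effect_size=2.0,
    study_sd=1.5,
    study_scale_sd=0.2,
    seed=11,
):
    design = SimulationDesign(
        n_studies=n_studies,
        n_classes=n_classes,
        samples_per_class=samples_per_class,
        n_variables=n_variables,
        n_informative=n_informative,
        effect_size=effect_size,
        study_sd=study_sd,
        study_scale_sd=study_scale_sd,
        seed=seed,
    )
    return simulate_multistudy(design)


def random_dataset(rng, n_studies=2, n_classes=2, n_per=5, p=8):
    """Pure-noise multi-study dataset with balanced classes (no signal)."""
    rows, studies, classes, ids = [], [], [], []
    for m in range(n_studies):
        for k in range(n_classes):
            rows.append(rng.normal(size=(n_per, p)))
            studies += [f"s{m}"] * n_per
            classes += [f"c{k}"] * n_per
            ids += [f"s{m}_c{k}_{i}" for i in range(n_per)]
    x = pd.DataFrame(np.vstack(rows), index=ids, columns=[f"v{j}" for j in range(p)])
    return MultiStudyDataset(x, pd.Series(studies, index=ids), pd.Series(classes, index=ids))


@pytest.fixture
def small_dataset():
    """3 studies, 3 classes, 8/class/study, 30 variables, clear signal."""
    ds, _ = make_dataset(
        n_studies=3, n_classes=3, samples_per_class=8, n_variables=30,
        n_informative=6, effect_size=2.0, seed=7,
    )
    return ds


@pytest.fixture
def small_dataset_truth():
    ds, truth = make_dataset(
        n_studies=3, n_classes=3, samples_per_class=8, n_variables=30,
        n_informative=6, effect_size=2.0, seed=7,
    )
    return ds, truth


@pytest.fixture
def two_class_dataset():
    """2 studies, 2 classes: the smallest configuration exercising LOGOCV."""
    ds, _ = make_dataset(n_studies=2, n_classes=2, samples_per_class=8, seed=3)
    return ds
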