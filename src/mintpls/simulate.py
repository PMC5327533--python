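"""Synthetic multi-study expression data with known discriminant variables.

The generator emulates the confounding regime typical of cross-platform
transcriptomic compilations, where systematic study-to-study variation
dominates the biological class signal: every variable receives a per-study
additive offset (Normal, sd ``study_sd``) and a per-study multiplicative
sensitivity factor (LogNormal, sigma ``study_scale_sd``), on top of Gaussian
residual noise (sd 1) and class mean shifts of ``effect_size`` residual-sd
units on a known set of informative variables.  Draws are stream-per-study
(counter-based seeding), so adding a study never perturbs the data of
existing studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultiStudyDataset

__all__ = ["SimulationDesign", "simulate_multistudy", "confounded_preset"]


@dataclass
class SimulationDesign:
    """Design of a multi-study simulation.

    Parameters
    ----------
    n_studies, n_classes
        M studies and K classes; every class appears in every study.
    samples_per_class
        Samples per class within each study (same for all studies/classes).
    n_variables, n_informative
        Total variables P and size of the informative set S.  Informative
        variables are assigned round-robin to classes: variable s in S carries
        a mean shift of ``effect_size`` for its class and 0 for the others.
    effect_size
        Class mean shift delta, in residual-sd units.
    study_sd
        Standard deviation of the per-study, per-variable additive offset.
    study_scale_sd
        Log-sd tau of the per-study, per-variable multiplicative factor
        (LogNormal(0, tau^2)).
    seed
        Base seed; identical (seed, design) pairs give identical datasets.
    """

    n_studies: int = 3
    n_classes: int = 2
    samples_per_class: int = 10
    n_variables: int = 200
    n_informative: int = 10
    effect_size: float = 1.0
    study_sd: float = 2.0
    study_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_classes < 2:
            raise ValueError("need >=1 study and >=2 classes")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >=1")
        if not 0 <= self.n_informative <= self.n_variables:
            raise ValueError("n_informative must lie in [0, n_variables]")
        if self.effect_size < 0 or self.study_sd < 0 or self.study_scale_sd < 0:
            raise ValueError("effect sizes and dispersions must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    informative: list                      # informative variable ids
    informative_index: np.ndarray          # column indices of S
    class_means: pd.DataFrame              # K x P mean-shift matrix
    study_offset: pd.DataFrame             # M x P additive offsets
    study_scale: pd.DataFrame              # M x P multiplicative factors


def simulate_multistudy(design: SimulationDesign) -> tuple[MultiStudyDataset, SimulationTruth]:
    """Draw one multi-study dataset from the design.

    X[i, j] = offset[m, j] + scale[m, j] * (classMean[k, j] + eps),
    eps ~ N(0, 1), for sample i of class k in study m.
    """
    m_stud, k_cls, p = design.n_studies, design.n_classes, design.n_variables
    n_per = design.samples_per_class

    # design-level stream: informative set and class mean pattern
    rng_design = np.random.default_rng([int(design.seed), 0])
    s_idx = np.sort(rng_design.choice(p, size=design.n_informative, replace=False))
    class_means = np.zeros((k_cls, p))
    for rank, j in enumerate(s_idx):
        class_means[rank % k_cls, j] = design.effect_size

    var_ids = [f"g{j + 1}" for j in range(p)]
    study_ids = [f"study{m + 1}" for m in range(m_stud)]
    class_ids = [f"class{chr(ord('A') + k)}" for k in range(k_cls)]

    blocks, studies, classes, sample_ids = [], [], [], []
    offsets = np.zeros((m_stud, p))
    scales = np.ones((m_stud, p))
    for m in range(m_stud):
        # counter-based stream: study m's draws never depend on other studies
        rng = np.random.default_rng([int(design.seed), m + 1])
        offsets[m] = rng.normal(0.0, design.study_sd, size=p)
        scales[m] = np.exp(rng.normal(0.0, design.study_scale_sd, size=p)) \
            if design.study_scale_sd > 0 else np.ones(p)
        for k in range(k_cls):
            eps = rng.normal(0.0, 1.0, size=(n_per, p))
            block = offsets[m] + scales[m] * (class_means[k] + eps)
            blocks.append(block)
            studies.extend([study_ids[m]] * n_per)
            classes.extend([class_ids[k]] * n_per)
            sample_ids.extend(
                f"{study_ids[m]}_{class_ids[k]}_{i + 1}" for i in range(n_per)
            )

    expression = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=var_ids)
    dataset = MultiStudyDataset(
        expression=expression,
        study_labels=pd.Series(studies, index=sample_ids),
        class_labels=pd.Series(classes, index=sample_ids),
    )
    truth = SimulationTruth(
        informative=[var_ids[j] for j in s_idx],
        informative_index=s_idx,
        class_means=pd.DataFrame(class_means, index=class_ids, columns=var_ids),
        study_offset=pd.DataFrame(offsets, index=study_ids, columns=var_ids),
        study_scale=pd.DataFrame(scales, index=study_ids, columns=var_ids),
    )
    return dataset, truth


#: Documented confounding presets.  "maqc-like" mimics a small number of
#: platforms profiling the same two reference classes, with study variation
#: several times the class effect; "mild" has comparable study and class
#: effects; "null" has no informative variable at all.
_PRESETS = {
    "maqc-like": SimulationDesign(
        n_studies=3,
        n_classes=2,
        samples_per_class=10,
        n_variables=500,
        n_informative=10,
        effect_size=1.0,
        study_sd=3.0,
        study_scale_sd=0.3,
    ),
    "mild": SimulationDesign(
        n_studies=2,
        n_classes=2,
        samples_per_class=10,
        n_variables=200,
        n_informative=10,
        effect_size=1.0,
        study_sd=1.0,
        study_scale_sd=0.1,
    ),
    "null": SimulationDesign(
        n_studies=3,
        n_classes=2,
        samples_per_class=10,
        n_variables=200,
        n_informative=0,
        effect_size=0.0,
        study_sd=2.0,
        study_scale_sd=0.3,
    ),
}


def confounded_preset(level: str, seed: int = 0) -> SimulationDesign:
    """Return a documented simulation design ("maqc-like", "mild" or "null")."""
    if level not in _PRESETS:
        raise ValueError(f"unknown preset {level!r}; choose from {sorted(_PRESETS)}")
    base = _PRESETS[level]
    return SimulationDesign(**{**base.__dict__, "seed": int(seed)})
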