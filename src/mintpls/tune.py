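"""keepX selection by Leave-One-Group-Out Cross-Validation (LOGOCV).

Each study is held out exactly once and predicted from a model fitted on the
remaining studies, mimicking the real use case of predicting an external
study.  Tuning is component-wise and forward: keepX values already selected
for earlier components are frozen while the grid is scanned for the current
one, and the candidate with the smallest mean balanced error rate across
folds wins (ties go to the sparsest model).  Folds are the sorted studies, so
tuning is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import fit_mint
from .data import MultiStudyDataset
from .predict import balanced_error_rate, predict

__all__ = ["CvResult", "logocv_folds", "tune_keepx", "default_keepx_grid"]


@dataclass
class CvResult:
    """Per-component LOGOCV error grids and the selected keepX values."""

    grids: list                    # one DataFrame per component: keepx, per-fold BER, mean
    selected_keepx: list
    n_components: int
    fold_test_studies: list
    warnings: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Long table: component, keepx, mean BER, selected flag."""
        frames = []
        for h, grid in enumerate(self.grids, start=1):
            g = grid.copy()
            g.insert(0, "component", h)
            g["selected"] = g["keepx"] == self.selected_keepx[h - 1]
            frames.append(g)
        return pd.concat(frames, ignore_index=True)


def logocv_folds(dataset: MultiStudyDataset) -> list[tuple[list, object]]:
    """Leave-one-group-out folds: (training studies, left-out study) per study.

    Exactly M folds in sorted study order; requires at least 2 studies.
    """
    studies = dataset.studies
    if len(studies) < 2:
        raise ValueError("LOGOCV requires >=2 studies")
    return [([s for s in studies if s != test], test) for test in studies]


def default_keepx_grid(n_variables: int) -> list[int]:
    grid = list(range(1, 11)) + [20, 50, 100, 200, 500]
    return sorted(k for k in set(grid) if 1 <= k <= n_variables)


def tune_keepx(
    dataset: MultiStudyDataset,
    grid=None,
    n_components: int | None = None,
    scale_y: bool = True,
    zero_variance: str = "error",
) -> CvResult:
    """Select keepX per component by LOGOCV minimizing the balanced error rate.

    For each fold the held-out study is standardized independently of the
    training studies (it plays the role of an external study), so no scaling
    information leaks across the split.  Folds whose training part misses a
    class are skipped with a recorded warning; fit failures on a fold are
    recorded and that fold is excluded from the candidate's mean.
    """
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("tuning requires >=2 classes")
    p = dataset.n_variables
    if grid is None:
        grid = default_keepx_grid(p)
    grid = sorted({int(g) for g in grid})
    for g in grid:
        if not 1 <= g <= p:
            raise ValueError(f"grid values must be in [1, {p}], got {g}")
    h_total = (len(classes) - 1) if n_components is None else int(n_components)

    folds = logocv_folds(dataset)
    notes: list[str] = []
    usable = []
    for train_studies, test_study in folds:
        train = dataset.subset_studies(train_studies)
        if set(train.classes) != set(classes):
            msg = (
                f"fold leaving out {test_study!r} skipped: training studies "
                f"miss class(es) {sorted(set(classes) - set(train.classes), key=str)}"
            )
            warnings.warn(msg, UserWarning, stacklevel=2)
            notes.append(msg)
            continue
        test = dataset.subset_studies([test_study])
        usable.append((train, test, test_study))
    if not usable:
        raise ValueError("no usable LOGOCV fold (every fold misses a class)")

    selected: list[int] = []
    grids: list[pd.DataFrame] = []
    for h in range(1, h_total + 1):
        fold_ber = np.full((len(grid), len(usable)), np.nan)
        for gi, cand in enumerate(grid):
            keep = selected + [cand]
            for fi, (train, test, test_study) in enumerate(usable):
                try:
                    model = fit_mint(
                        train,
                        keep_x=keep,
                        n_components=h,
                        scale_y=scale_y,
                        zero_variance=zero_variance,
                    )
                    res = predict(model, test.expression, test.study_labels)
                    fold_ber[gi, fi] = balanced_error_rate(
                        test.class_labels, res.labels
                    )
                except Exception as exc:  # noqa: BLE001 - fold-level fault isolation
                    msg = (
                        f"component {h}, keepx={cand}, fold {test_study!r} "
                        f"failed: {exc}"
                    )
                    warnings.warn(msg, UserWarning, stacklevel=2)
                    notes.append(msg)
        with warnings.catch_warnings():
            # a fully-failed candidate yields an all-NaN row (mean of empty slice)
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_ber = np.nanmean(fold_ber, axis=1)
        if np.isnan(mean_ber).all():
            raise ValueError(
                f"component {h}: no fold could be evaluated for any candidate "
                f"(see recorded warnings)"
            )
        gdf = pd.DataFrame({"keepx": grid})
        for fi, (_, _, test_study) in enumerate(usable):
            gdf[f"ber_fold_{test_study}"] = fold_ber[:, fi]
        gdf["mean_ber"] = mean_ber
        grids.append(gdf)
        # smallest mean BER; ties resolve to the smallest keepX (grid is sorted)
        best = int(np.nanargmin(mean_ber))
        selected.append(grid[best])

    return CvResult(
        grids=grids,
        selected_keepx=selected,
        n_components=h_total,
        fold_test_studies=[s for _, _, s in usable],
        warnings=notes,
    )
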