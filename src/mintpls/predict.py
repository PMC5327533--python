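"""Class prediction for external samples and classification error metrics.

Test samples are standardized under the train/test contract: samples from a
study seen at training reuse that study's stored coefficients (so a single
training study reproduces classical PLS exactly); samples from an unseen study
are centered and scaled within their own study.  Scores are obtained by
projecting through the fitted deflation sequence, the class-indicator matrix
is estimated by the PLS regression formula and back-transformed with the
pooled training statistics, and each sample is assigned the class with
maximal value (maximal-distance rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MintModel
from .data import MIN_STUDY_SIZE, DataValidationError

__all__ = [
    "PredictionResult",
    "standardize_test",
    "project_test",
    "predict_classes",
    "predict",
    "balanced_error_rate",
    "accuracy_by_study_and_class",
]


@dataclass
class PredictionResult:
    """Scores, estimated class-indicator matrix and assigned labels."""

    scores: pd.DataFrame          # n_test x H component scores
    y_hat: pd.DataFrame           # n_test x K, back-transformed scale
    labels: pd.Series             # predicted class per sample
    class_order: list


def _align_variables(x_test: pd.DataFrame, variable_ids: pd.Index) -> pd.DataFrame:
    missing = variable_ids.difference(x_test.columns)
    extra = x_test.columns.difference(variable_ids)
    if len(missing) or len(extra):
        raise DataValidationError(
            f"test variables do not match the training variables; "
            f"missing from test: {missing.tolist()[:10]}{'...' if len(missing) > 10 else ''}; "
            f"absent from training: {extra.tolist()[:10]}{'...' if len(extra) > 10 else ''}"
        )
    return x_test.loc[:, variable_ids]


def standardize_test(
    x_test: pd.DataFrame,
    test_study_labels,
    params,
) -> np.ndarray:
    """Standardize test samples with the train/test scaling contract.

    Studies present in the training set reuse the stored coefficients;
    completely independent studies are centered and scaled on their own
    (requiring more than 3 samples).  Columns are aligned to the training
    variable ids by name.
    """
    study_labels = pd.Series(np.asarray(test_study_labels), index=x_test.index)
    if params.dropped_variables:
        # variables dropped at training (zero within-study variance) may still
        # be present in the test table; they carry no model information
        present = [c for c in params.dropped_variables if c in x_test.columns]
        x_test = x_test.drop(columns=present)
    x_test = _align_variables(x_test, params.variable_ids)
    xv = x_test.to_numpy(dtype=float)
    out = np.empty(xv.shape, dtype=float)
    known = set(params.studies)
    for study in pd.unique(study_labels):
        mask = (study_labels == study).to_numpy()
        block = xv[mask]
        if study in known:
            mu = params.x_mean.loc[study].to_numpy()
            sd = params.x_sd.loc[study].to_numpy()
        else:
            if block.shape[0] <= MIN_STUDY_SIZE - 1:
                raise DataValidationError(
                    f"independent test study {study!r} has {block.shape[0]} "
                    f"samples; only studies with a sample size >3 can be included"
                )
            mu = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            if np.any(sd == 0.0):
                j = int(np.flatnonzero(sd == 0.0)[0])
                raise DataValidationError(
                    f"variable {params.variable_ids[j]!r} is constant within "
                    f"independent test study {study!r}"
                )
        out[mask] = (block - mu) / sd
    return out


def project_test(x_test_std: np.ndarray, model: MintModel, n_components: int | None = None) -> np.ndarray:
    """Component scores of standardized test samples.

    Applies the fitted deflation sequence with the *training* projection
    vectors: t_h = X_h a_h, then X_{h+1} = X_h - t_h p_h'.
    """
    h_total = model.n_components if n_components is None else int(n_components)
    if not 1 <= h_total <= model.n_components:
        raise ValueError(
            f"n_components must be in [1, {model.n_components}], got {h_total}"
        )
    x = np.array(x_test_std, dtype=float, copy=True)
    if x.shape[1] != model.a.shape[0]:
        raise ValueError("test matrix has a different number of variables than the model")
    scores = np.empty((x.shape[0], h_total))
    a = model.a.to_numpy()
    p = model.x_projection.to_numpy()
    for h in range(h_total):
        t = x @ a[:, h]
        scores[:, h] = t
        x -= np.outer(t, p[:, h])
    return scores


def predict_classes(
    scores: np.ndarray,
    model: MintModel,
    sample_ids=None,
) -> PredictionResult:
    """Estimate the class-indicator matrix from scores and assign classes.

    Y_hat (standardized scale) = sum_h t_h c_h'; the back-transform multiplies
    by the pooled training class standard deviations when Y was scaled, then
    adds the pooled class proportions.  The label is the per-row argmax
    (maximal distance); rows with no positive entry or with ties are flagged
    with a warning, ties resolving to the first class in class order.
    """
    scores = np.asarray(scores, dtype=float)
    h = scores.shape[1]
    c = model.y_regression.to_numpy()[:, :h]
    y_std = scores @ c.T
    sd = model.standardization.pooled_y_sd.to_numpy()
    mu = model.standardization.pooled_y_mean.to_numpy()
    y_hat = y_std * sd + mu if model.standardization.scale_y else y_std + mu

    if np.any((y_hat <= 0.0).all(axis=1)):
        n_bad = int((y_hat <= 0.0).all(axis=1).sum())
        warnings.warn(
            f"{n_bad} test sample(s) have no positive class score; assigning "
            f"the maximal (non-positive) value",
            UserWarning,
            stacklevel=2,
        )
    idx = np.argmax(y_hat, axis=1)  # ties -> first class in class order
    row_max = y_hat[np.arange(len(idx)), idx]
    ties = (y_hat == row_max[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} sample(s) tie on the maximal class score; "
            f"assigned the first class in class order",
            UserWarning,
            stacklevel=2,
        )
    classes = model.class_order
    labels = pd.Series([classes[i] for i in idx], index=sample_ids, name="predicted_class")
    comp_names = model.t_global.columns[:h]
    return PredictionResult(
        scores=pd.DataFrame(scores, index=sample_ids, columns=comp_names),
        y_hat=pd.DataFrame(y_hat, index=sample_ids, columns=classes),
        labels=labels,
        class_order=classes,
    )


def predict(
    model: MintModel,
    x_test: pd.DataFrame,
    test_study_labels,
    n_components: int | None = None,
) -> PredictionResult:
    """Standardize, project and classify test samples in one call."""
    xs = standardize_test(x_test, test_study_labels, model.standardization)
    scores = project_test(xs, model, n_components=n_components)
    return predict_classes(scores, model, sample_ids=x_test.index)


def balanced_error_rate(true_labels, predicted_labels) -> float:
    """Average over classes of the within-class misclassification proportion.

    Weights small classes up relative to the overall error rate; equals the
    overall error rate when classes are balanced.
    """
    truth = pd.Series(np.asarray(true_labels))
    pred = pd.Series(np.asarray(predicted_labels))
    if len(truth) != len(pred):
        raise ValueError("true and predicted label vectors differ in length")
    if len(truth) == 0:
        raise ValueError("empty truth vector: every class must have samples")
    rates = []
    for cls in sorted(pd.unique(truth).tolist()):
        mask = (truth == cls).to_numpy()
        n_k = int(mask.sum())
        if n_k == 0:
            raise ValueError(f"class {cls!r} is empty in the truth vector")
        rates.append(float((pred.to_numpy()[mask] != cls).sum()) / n_k)
    return float(np.mean(rates))


def accuracy_by_study_and_class(true_labels, predicted_labels, study_labels) -> pd.DataFrame:
    """Per (study, class) accuracy with a per-study balanced error rate.

    Returns a long-format table with one row per (study, class) plus the
    per-study BER repeated on each row of that study.
    """
    truth = pd.Series(np.asarray(true_labels))
    pred = pd.Series(np.asarray(predicted_labels))
    study = pd.Series(np.asarray(study_labels))
    rows = []
    for st in sorted(pd.unique(study).tolist()):
        smask = (study == st).to_numpy()
        ber = balanced_error_rate(truth[smask], pred[smask])
        for cls in sorted(pd.unique(truth[smask]).tolist()):
            cmask = smask & (truth == cls).to_numpy()
            acc = float((pred.to_numpy()[cmask] == cls).mean())
            rows.append(
                {"study": st, "class": cls, "n": int(cmask.sum()),
                 "accuracy": acc, "study_ber": ber}
            )
    return pd.DataFrame(rows, columns=["study", "class", "n", "accuracy", "study_ber"])
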