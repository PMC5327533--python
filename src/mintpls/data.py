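"""Multi-study expression containers, class encoding and per-study standardization.

A multi-study dataset is a samples x variables expression matrix (log-scale,
continuous) whose rows are partitioned into M independent studies, each sample
carrying one study label and one class label.  Standardization is performed
*within* each study (mean 0, variance 1 per variable per study), which removes
additive study offsets and equalizes platform scale before any model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MultiStudyDataset",
    "DummyOutcome",
    "StandardizationParams",
    "ValidationReport",
    "encode_dummy",
    "standardize_by_study",
    "validate_dataset",
]

#: Smallest study size admissible for per-study centering/scaling.  Studies of
#: 3 or fewer samples cannot be standardized reliably and are rejected.
MIN_STUDY_SIZE = 4


class DataValidationError(ValueError):
    """Raised when a dataset violates the multi-study contract."""


@dataclass
class MultiStudyDataset:
    """Expression matrix with aligned study and class labels.

    Parameters
    ----------
    expression
        DataFrame of shape (N samples, P variables); index = sample ids,
        columns = variable ids.  Must be complete (no missing values).
    study_labels
        Length-N sequence assigning each sample to one study.
    class_labels
        Length-N sequence of class labels, or None for unlabelled test data.
    """

    expression: pd.DataFrame
    study_labels: pd.Series
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        x = self.expression
        if not isinstance(x, pd.DataFrame):
            x = pd.DataFrame(x)
            self.expression = x
        n = x.shape[0]
        self.study_labels = pd.Series(
            np.asarray(self.study_labels), index=x.index, name="study"
        )
        if self.class_labels is not None:
            self.class_labels = pd.Series(
                np.asarray(self.class_labels), index=x.index, name="class"
            )
            if len(self.class_labels) != n:
                raise DataValidationError("class_labels length != number of samples")
        if len(self.study_labels) != n:
            raise DataValidationError("study_labels length != number of samples")
        if x.index.has_duplicates:
            dup = x.index[x.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicated sample ids: {dup}")
        if x.columns.has_duplicates:
            dup = x.columns[x.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicated variable ids: {dup}")
        if x.isna().to_numpy().any():
            raise DataValidationError("expression matrix contains missing values")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_variables(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def variable_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def studies(self) -> list:
        """Sorted unique study labels."""
        return sorted(pd.unique(self.study_labels).tolist())

    @property
    def classes(self) -> list:
        """Sorted unique class labels (empty if unlabelled)."""
        if self.class_labels is None:
            return []
        return sorted(pd.unique(self.class_labels).tolist())

    def study_mask(self, study) -> np.ndarray:
        return (self.study_labels == study).to_numpy()

    def subset(self, mask: np.ndarray) -> "MultiStudyDataset":
        """Row subset keeping labels aligned."""
        return MultiStudyDataset(
            expression=self.expression.loc[mask],
            study_labels=self.study_labels.loc[mask],
            class_labels=None if self.class_labels is None else self.class_labels.loc[mask],
        )

    def subset_studies(self, studies) -> "MultiStudyDataset":
        mask = self.study_labels.isin(list(studies)).to_numpy()
        return self.subset(mask)


@dataclass
class DummyOutcome:
    """N x K 0/1 indicator of class membership used as the PLS response.

    Columns follow ``classes`` (lexicographically sorted labels) so the
    encoding is reproducible across runs and serializations.
    """

    matrix: np.ndarray
    classes: list

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def column_of(self, label) -> int:
        return self.classes.index(label)


def encode_dummy(class_labels) -> DummyOutcome:
    """Encode class labels as an N x K indicator matrix.

    Column order is the lexicographic sort of the unique labels; every row
    sums to exactly 1.

    Raises
    ------
    ValueError
        If fewer than 2 distinct classes are present.
    """
    labels = np.asarray(pd.Series(class_labels))
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need >=2 classes to encode a dummy outcome")
    col = {c: k for k, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)), dtype=float)
    for i, lab in enumerate(labels):
        y[i, col[lab]] = 1.0
    return DummyOutcome(matrix=y, classes=classes)


@dataclass
class StandardizationParams:
    """Per-study centering/scaling coefficients fitted on training data.

    ``x_mean``/``x_sd`` are (study x variable) DataFrames; ``y_mean``/``y_sd``
    are (study x class).  ``pooled_y_mean``/``pooled_y_sd`` are computed on the
    concatenated raw indicator matrix and used to back-transform predicted
    class scores (defined for any test study, including unseen ones).
    Standard deviations use the unbiased n-1 denominator throughout.
    """

    x_mean: pd.DataFrame
    x_sd: pd.DataFrame
    y_mean: pd.DataFrame
    y_sd: pd.DataFrame | None
    pooled_y_mean: pd.Series
    pooled_y_sd: pd.Series
    scale_y: bool
    dropped_variables: list = field(default_factory=list)

    @property
    def studies(self) -> list:
        return self.x_mean.index.tolist()

    @property
    def variable_ids(self) -> pd.Index:
        return self.x_mean.columns

    def transform_x(self, x: pd.DataFrame, study_labels: pd.Series) -> np.ndarray:
        """Apply the stored per-study transform to known-study samples."""
        out = np.empty(x.shape, dtype=float)
        xv = x.to_numpy(dtype=float)
        for study in pd.unique(study_labels):
            if study not in self.x_mean.index:
                raise KeyError(f"study {study!r} has no stored coefficients")
            mask = (study_labels == study).to_numpy()
            mu = self.x_mean.loc[study].to_numpy()
            sd = self.x_sd.loc[study].to_numpy()
            out[mask] = (xv[mask] - mu) / sd
        return out

    def inverse_transform_x(self, xs: np.ndarray, study_labels: pd.Series) -> np.ndarray:
        out = np.empty(xs.shape, dtype=float)
        for study in pd.unique(study_labels):
            mask = (study_labels == study).to_numpy()
            mu = self.x_mean.loc[study].to_numpy()
            sd = self.x_sd.loc[study].to_numpy()
            out[mask] = xs[mask] * sd + mu
        return out


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`: passes iff no violations."""

    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise DataValidationError(
                "dataset failed validation:\n- " + "\n- ".join(self.violations)
            )


def validate_dataset(dataset: MultiStudyDataset, for_training: bool = True) -> ValidationReport:
    """Check the multi-study contract; returns a report, never raises.

    Violations collected: studies with 3 or fewer samples (per-study scaling
    needs a sample size greater than 3); for training data, studies missing
    one or more outcome classes (study and class effects are confounded
    otherwise); missing values; duplicated sample ids.
    """
    violations: list[str] = []
    counts = dataset.study_labels.value_counts()
    for study, n_m in counts.items():
        if n_m <= MIN_STUDY_SIZE - 1:
            violations.append(
                f"study {study!r} has {n_m} samples; only studies with a sample "
                f"size >3 can be included"
            )
    if for_training:
        if dataset.class_labels is None:
            violations.append("training data must carry class labels")
        else:
            classes = set(dataset.classes)
            for study in dataset.studies:
                present = set(dataset.class_labels[dataset.study_mask(study)])
                missing = sorted(classes - present, key=str)
                if missing:
                    violations.append(
                        f"study {study!r} is missing class(es) {missing}; every "
                        f"outcome category must be represented in each study"
                    )
    # NaN / duplicate checks are enforced at construction; re-check defensively
    if dataset.expression.isna().to_numpy().any():
        violations.append("expression matrix contains missing values")
    if dataset.sample_ids.has_duplicates:
        violations.append("duplicated sample ids")
    return ValidationReport(violations=violations)


def _study_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return mu, sd


def standardize_by_study(
    dataset: MultiStudyDataset,
    dummy: DummyOutcome,
    scale_y: bool = True,
    zero_variance: str = "error",
) -> tuple[np.ndarray, np.ndarray, StandardizationParams]:
    """Center and scale every variable to mean 0 / variance 1 within each study.

    The indicator matrix Y is centered per study and scaled iff ``scale_y``.
    The fitted coefficients are returned for reuse on test samples.

    Parameters
    ----------
    zero_variance
        ``"error"`` (default): a variable constant within some study aborts;
        ``"drop"``: such variables are removed with a warning listing them.
    """
    if zero_variance not in ("error", "drop"):
        raise ValueError("zero_variance must be 'error' or 'drop'")
    studies = dataset.studies
    x = dataset.expression
    y = dummy.matrix

    counts = dataset.study_labels.value_counts()
    small = counts[counts <= MIN_STUDY_SIZE - 1]
    if len(small):
        raise DataValidationError(
            f"studies {small.index.tolist()} have <=3 samples; only studies with "
            f"a sample size >3 can be included"
        )

    # locate zero-variance-within-study variables first
    xv0 = x.to_numpy(dtype=float)
    sds = {}
    means = {}
    bad: dict = {}
    for study in studies:
        mask = dataset.study_mask(study)
        mu, sd = _study_moments(xv0[mask])
        means[study] = mu
        sds[study] = sd
        zero = np.flatnonzero(sd == 0.0)
        for j in zero:
            bad.setdefault(x.columns[j], []).append(study)
    dropped: list = []
    if bad:
        if zero_variance == "error":
            msgs = [f"{var!r} in study {studs!r}" for var, studs in bad.items()]
            raise DataValidationError(
                "zero within-study variance for variable(s): " + "; ".join(msgs)
            )
        dropped = list(bad)
        warnings.warn(
            f"dropping {len(dropped)} variable(s) with zero within-study "
            f"variance: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        keep = ~x.columns.isin(dropped)
        x = x.loc[:, keep]
        for study in studies:
            means[study] = means[study][keep]
            sds[study] = sds[study][keep]

    xs = np.empty(x.shape, dtype=float)
    ys = np.empty(y.shape, dtype=float)
    y_mu = {}
    y_sd = {}
    xv = x.to_numpy(dtype=float)
    for study in studies:
        mask = dataset.study_mask(study)
        xs[mask] = (xv[mask] - means[study]) / sds[study]
        mu_y, sd_y = _study_moments(y[mask])
        y_mu[study] = mu_y
        y_sd[study] = sd_y
        ys[mask] = y[mask] - mu_y
        if scale_y:
            if np.any(sd_y == 0.0):
                k = int(np.flatnonzero(sd_y == 0.0)[0])
                raise DataValidationError(
                    f"class {dummy.classes[k]!r} indicator is constant within "
                    f"study {study!r}; cannot scale Y (is the class missing?)"
                )
            ys[mask] /= sd_y

    params = StandardizationParams(
        x_mean=pd.DataFrame(means, index=x.columns).T.loc[studies],
        x_sd=pd.DataFrame(sds, index=x.columns).T.loc[studies],
        y_mean=pd.DataFrame(y_mu, index=dummy.classes).T.loc[studies],
        y_sd=None if not scale_y else pd.DataFrame(y_sd, index=dummy.classes).T.loc[studies],
        pooled_y_mean=pd.Series(y.mean(axis=0), index=dummy.classes),
        pooled_y_sd=pd.Series(y.std(axis=0, ddof=1), index=dummy.classes),
        scale_y=scale_y,
        dropped_variables=dropped,
    )
    return xs, ys, params
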