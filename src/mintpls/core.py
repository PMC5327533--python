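"""Sparse multi-group PLS-DA fitting.

For each dimension h the model maximizes the summed per-study covariance
between the X component and the class-indicator component,

    max_{||a||=||b||=1}  sum_m n_m cov(X_h^(m) a, Y_h^(m) b)  -  lambda_h ||a||_1,

over global loading vectors a (genes) and b (classes) shared by all studies.
Because every study is centered and scaled beforehand, the multi-group
objective reduces, up to the variance-denominator constant, to the penalized
cross-product a' X_h' Y_h b on the per-study standardized concatenation, and
each component is a soft-thresholded power iteration on M_h = X_h' Y_h.  The
l1 penalty is parameterized by keepX, the number of genes retained per
component.  With keepX = P the model is multi-group PLS-DA; with a single
study it collapses to classical PLS-DA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    DummyOutcome,
    MultiStudyDataset,
    StandardizationParams,
    encode_dummy,
    standardize_by_study,
    validate_dataset,
)

__all__ = [
    "MintModel",
    "fit_mint",
    "fit_component",
    "deflate",
    "soft_threshold",
    "threshold_for_keepx",
]


class FitError(RuntimeError):
    """Raised when a component cannot be fitted (e.g. no X/Y covariance)."""


def soft_threshold(w: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(w) * max(0, |w| - lam); zero exactly where |w| <= lam."""
    if lam < 0:
        raise ValueError("soft-threshold parameter must be nonnegative")
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def threshold_for_keepx(w: np.ndarray, keep: int) -> float:
    """Penalty value at which soft-thresholding ``w`` retains ``keep`` entries.

    Returns the largest |w| value strictly smaller than the keep-th largest,
    i.e. the (keep+1)-th largest when all |w| are distinct, and 0 when
    keep = len(w).  If several entries tie with the keep-th largest |w| they
    are all retained (the count then exceeds ``keep``) and a warning is
    emitted, avoiding an arbitrary index-order choice among tied variables.
    """
    w = np.asarray(w)
    p = w.size
    if not 1 <= keep <= p:
        raise ValueError(f"keep must be in [1, {p}], got {keep}")
    if keep == p:
        return 0.0
    aw = np.sort(np.abs(w))[::-1]
    kth = aw[keep - 1]
    below = aw[aw < kth]
    lam = float(below[0]) if below.size else 0.0
    n_kept = int(np.count_nonzero(np.abs(w) > lam))
    if n_kept > keep:
        warnings.warn(
            f"{n_kept - keep + 1} entries tie at the keepX boundary "
            f"(|w| = {kth:.6g}); keeping {n_kept} variables instead of {keep}",
            UserWarning,
            stacklevel=2,
        )
    return lam


def _normalize(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise FitError("zero vector cannot be normalized")
    return v / nrm


def fit_component(
    x: np.ndarray,
    y: np.ndarray,
    keep: int,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """One soft-thresholded power iteration on the cross-product M = X'Y.

    Alternates  w <- M b;  a <- normalize(soft_threshold(w, lam(keep)));
    b <- normalize(M'a)  until the l2 change in ``a`` falls below ``tol``.
    The class loading b is never thresholded.  Initialization is the leading
    right singular vector of M (deterministic, near-optimal start).  Returns
    (a, b, t, u, diagnostics) with t = Xa, u = Yb, and the sign fixed so the
    largest-|.| entry of a is positive.
    """
    m = x.T @ y
    if not np.any(m):
        raise FitError("no covariance between X and Y (X'Y is the zero matrix)")
    # deterministic init: leading right singular vector of M
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    b = vt[0]
    a = np.zeros(x.shape[1])
    converged = False
    change = np.inf
    it = 0
    with warnings.catch_warnings():
        # the keepX tie warning is meaningful once, not once per iteration
        warnings.simplefilter("once", UserWarning)
        for it in range(1, max_iter + 1):
            w = m @ b
            lam = threshold_for_keepx(w, keep)
            a_new = _normalize(soft_threshold(w, lam))
            b = _normalize(m.T @ a_new)
            change = float(np.linalg.norm(a_new - a))
            a = a_new
            if change < tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"component did not converge in {max_iter} iterations "
            f"(last change {change:.3g}); returning best iterate",
            UserWarning,
            stacklevel=2,
        )
    # reproducible sign: largest-|.| entry of a positive; flip jointly
    j = int(np.argmax(np.abs(a)))
    if a[j] < 0:
        a = -a
        b = -b
    t = x @ a
    u = y @ b
    return a, b, t, u, {"iterations": it, "final_change": change, "converged": converged}


def deflate(
    x: np.ndarray, y: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Regression-mode deflation of both blocks on the global component t.

    p = X't/(t't), c = Y't/(t't); residuals X - t p', Y - t c'.  Deflating on
    the global component (not per-study) guarantees mutually orthogonal global
    components and a well-defined prediction operator.
    """
    tt = float(t @ t)
    if tt <= 0.0 or not np.isfinite(tt):
        raise FitError("cannot deflate on a zero-norm component")
    p = x.T @ t / tt
    c = y.T @ t / tt
    return x - np.outer(t, p), y - np.outer(t, c), p, c


@dataclass
class MintModel:
    """Fitted sparse multi-group PLS-DA model.

    Loadings ``a`` (P x H, unit l2 columns, keepX-sparse) and ``b`` (K x H)
    are global, shared by all studies; ``t_global`` (= X a, per component,
    on deflated data) are the global sample scores whose per-study row blocks
    are the study-specific (partial) components.  ``x_projection`` (p_h) and
    ``y_regression`` (c_h) are the deflation regression vectors reused at
    prediction time.
    """

    a: pd.DataFrame                 # P x H, index = variable ids
    b: pd.DataFrame                 # K x H, index = class order
    t_global: pd.DataFrame          # N x H, index = sample ids
    u_global: pd.DataFrame          # N x H
    x_projection: pd.DataFrame      # P x H
    y_regression: pd.DataFrame      # K x H
    keep_x: list
    standardization: StandardizationParams
    class_order: list
    study_labels: pd.Series
    class_labels: pd.Series
    diagnostics: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.a.shape[1]

    @property
    def variable_ids(self) -> pd.Index:
        return self.a.index

    @property
    def studies(self) -> list:
        return sorted(pd.unique(self.study_labels).tolist())

    def partial_scores(self, study) -> pd.DataFrame:
        """Study-specific components: the rows of t_global for one study."""
        if study not in set(self.study_labels):
            raise KeyError(f"unknown study {study!r}")
        return self.t_global.loc[(self.study_labels == study).to_numpy()]

    def selected_variables(self, component: int) -> pd.Series:
        """Nonzero loadings of one component (1-based), largest |weight| first."""
        col = self.a.iloc[:, component - 1]
        sel = col[col != 0.0]
        return sel.iloc[np.argsort(-np.abs(sel.to_numpy()), kind="stable")]

    def signature_table(self) -> pd.DataFrame:
        """Long table of (component, variable, loading) for all selected genes."""
        rows = []
        for h in range(1, self.n_components + 1):
            sel = self.selected_variables(h)
            for var, wgt in sel.items():
                rows.append({"component": h, "variable": var, "loading": wgt})
        return pd.DataFrame(rows, columns=["component", "variable", "loading"])


def _resolve_keepx(keep_x, h: int, p: int) -> list[int]:
    if keep_x is None or (isinstance(keep_x, str) and keep_x == "all"):
        return [p] * h
    if isinstance(keep_x, (int, np.integer)):
        keep_x = [int(keep_x)] * h
    keep_x = [int(k) for k in keep_x]
    if len(keep_x) != h:
        raise ValueError(f"keep_x must have one entry per component ({h}), got {len(keep_x)}")
    for k in keep_x:
        if not 1 <= k <= p:
            raise ValueError(f"keep_x entries must be in [1, {p}], got {k}")
    return keep_x


def fit_mint(
    dataset: MultiStudyDataset,
    keep_x="all",
    n_components: int | None = None,
    scale_y: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
    zero_variance: str = "error",
) -> MintModel:
    """Fit the sparse multi-group PLS-DA model.

    Parameters
    ----------
    dataset
        Training data; must pass :func:`validate_dataset` (every study has
        more than 3 samples and contains every class).
    keep_x
        ``"all"`` (no penalty; multi-group PLS-DA), a single int, or one int
        per component: the number of genes with nonzero loading per component.
    n_components
        Number of latent components H; defaults to K - 1 for K classes.
    scale_y
        Scale the per-study centered indicator matrix to unit variance
        (default True).
    zero_variance
        Policy for variables constant within a study: ``"error"`` or ``"drop"``.

    Returns
    -------
    MintModel
    """
    report = validate_dataset(dataset, for_training=True)
    report.raise_if_invalid()
    dummy = encode_dummy(dataset.class_labels)
    k = dummy.n_classes
    h_total = (k - 1) if n_components is None else int(n_components)
    if h_total < 1:
        raise ValueError("number of components must be >= 1")

    xs, ys, params = standardize_by_study(
        dataset, dummy, scale_y=scale_y, zero_variance=zero_variance
    )
    var_ids = params.variable_ids
    p = len(var_ids)
    keep = _resolve_keepx(keep_x, h_total, p)

    a_cols, b_cols, t_cols, u_cols, p_cols, c_cols, diags = [], [], [], [], [], [], []
    x_h, y_h = xs, ys
    for h in range(h_total):
        m = x_h.T @ y_h
        if not np.any(np.abs(m) > 1e-14):
            warnings.warn(
                f"residual cross-product vanished after {h} component(s); "
                f"stopping early",
                UserWarning,
                stacklevel=2,
            )
            break
        a_h, b_h, t_h, u_h, diag = fit_component(x_h, y_h, keep[h], tol=tol, max_iter=max_iter)
        if float(t_h @ t_h) <= 1e-24:
            warnings.warn(
                f"component {h + 1} has a zero-norm score; stopping early",
                UserWarning,
                stacklevel=2,
            )
            break
        x_h, y_h, p_h, c_h = deflate(x_h, y_h, t_h)
        a_cols.append(a_h)
        b_cols.append(b_h)
        t_cols.append(t_h)
        u_cols.append(u_h)
        p_cols.append(p_h)
        c_cols.append(c_h)
        diags.append(diag)
    if not a_cols:
        raise FitError("no component could be fitted")

    comp_names = [f"comp{h + 1}" for h in range(len(a_cols))]
    return MintModel(
        a=pd.DataFrame(np.column_stack(a_cols), index=var_ids, columns=comp_names),
        b=pd.DataFrame(np.column_stack(b_cols), index=dummy.classes, columns=comp_names),
        t_global=pd.DataFrame(
            np.column_stack(t_cols), index=dataset.sample_ids, columns=comp_names
        ),
        u_global=pd.DataFrame(
            np.column_stack(u_cols), index=dataset.sample_ids, columns=comp_names
        ),
        x_projection=pd.DataFrame(
            np.column_stack(p_cols), index=var_ids, columns=comp_names
        ),
        y_regression=pd.DataFrame(
            np.column_stack(c_cols), index=dummy.classes, columns=comp_names
        ),
        keep_x=keep[: len(a_cols)],
        standardization=params,
        class_order=dummy.classes,
        study_labels=dataset.study_labels.copy(),
        class_labels=dataset.class_labels.copy(),
        diagnostics=diags,
    )
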