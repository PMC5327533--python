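"""Naive study-agnostic baseline for variable selection.

Standardizes the concatenated expression matrix globally (ignoring the study
partition) and ranks variables by the magnitude of their cross-product with
the centered class indicator.  This is the selection a single-study analysis
would perform on a naive concatenation; on confounded multi-study data it is
prone to missing true markers and picking study-driven false positives.
"""

from __future__ import annotations

import numpy as np

from .data import MultiStudyDataset, encode_dummy

__all__ = ["naive_study_agnostic_selection"]


def naive_study_agnostic_selection(dataset: MultiStudyDataset, n_select: int) -> list:
    """Top ``n_select`` variables by |X' Y| on globally standardized data."""
    x = dataset.expression.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    y = encode_dummy(dataset.class_labels).matrix
    y = y - y.mean(axis=0)
    score = np.linalg.norm(x.T @ y, axis=1)
    order = np.argsort(-score, kind="stable")[:n_select]
    return [dataset.variable_ids[j] for j in sorted(order)]
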