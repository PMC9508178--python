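"""Small comparison utilities for partitions."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["best_match_agreement"]


def best_match_agreement(found, planted) -> float:
    """Fraction of items on which two labelings agree after optimal label matching.

    Labels are matched by maximum-weight bipartite assignment on the confusion
    matrix, so the score is invariant to label permutations.  Works on
    Partition / MultilayerPartition objects or raw label arrays.
    """
    a = np.asarray(getattr(found, "labels", found)).ravel()
    b = np.asarray(getattr(planted, "labels", planted)).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same items")
    ka, kb = a.max() + 1, b.max() + 1
    confusion = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(confusion, (a, b), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return float(confusion[rows, cols].sum() / a.size)
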