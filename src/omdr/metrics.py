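"""Evaluation measures computed on a confusion matrix.

The headline measure is Kendall's tau-b, the ties-adjusted rank
correlation between true and predicted ordinal classes:

.. math::
   \\tau_b = \\frac{P - Q}{\\sqrt{(N_0 - T_r)(N_0 - T_c)}}

with P/Q the concordant/discordant pair counts, :math:`N_0 = n(n-1)/2`,
and :math:`T_r, T_c` the within-row/within-column tied-pair counts.  All
quantities come in closed form from the J x J table (pair counts are sums
of cell products), so the computation is exact and O(J^4) per table.

Balanced accuracy (macro-averaged per-class recall) is provided as the
conventional binary-MDR baseline measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifier import ConfusionMatrix


@dataclass
class MetricValue:
    name: str
    value: float  # nan marks an undefined (degenerate) table
    n_effective: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def tau_b_from_table(x: np.ndarray) -> float:
    """Kendall's tau-b of a two-way count table; ``nan`` when all mass lies
    in a single row or column (no pair is discriminated)."""
    x = np.asarray(x, dtype=float)
    J, K = x.shape
    n = x.sum()
    if n < 2:
        return float("nan")
    # concordant: cell (j,k) paired with the block strictly below-right;
    # discordant: with the block strictly below-left
    P = 0.0
    Q = 0.0
    for j in range(J):
        for k in range(K):
            if x[j, k] == 0:
                continue
            P += x[j, k] * x[j + 1 :, k + 1 :].sum()
            Q += x[j, k] * x[j + 1 :, :k].sum()
    n0 = n * (n - 1) / 2.0
    r = x.sum(axis=1)
    c = x.sum(axis=0)
    t_r = (r * (r - 1) / 2.0).sum()
    t_c = (c * (c - 1) / 2.0).sum()
    denom = (n0 - t_r) * (n0 - t_c)
    if denom <= 0:
        return float("nan")
    return float((P - Q) / math.sqrt(denom))


def tau_b(cm: ConfusionMatrix) -> MetricValue:
    """Tau-b between true and predicted classes; unclassified samples are
    omitted (``n_effective`` reports how many were scored)."""
    return MetricValue("tau_b", tau_b_from_table(cm.x), cm.n_classified)


def balanced_accuracy(cm: ConfusionMatrix) -> MetricValue:
    """Mean per-class recall; classes absent from the truth are skipped."""
    x = cm.x.astype(float)
    row = x.sum(axis=1)
    present = row > 0
    if not present.any():
        return MetricValue("balanced_accuracy", float("nan"), cm.n_classified)
    recall = np.diag(x)[present] / row[present]
    return MetricValue("balanced_accuracy", float(recall.mean()), cm.n_classified)


METRICS = {"tau_b": tau_b, "balanced_accuracy": balanced_accuracy}
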