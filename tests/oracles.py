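"""Independent oracles used only by the tests.

These deliberately re-derive quantities along a different route from the
package: tau-b by expanding a confusion matrix into per-sample (truth,
predicted) pairs and enumerating all O(n^2) pairs; cell assignment by
exhaustive comparison over classes; and a separately coded classic binary
MDR (case/control-ratio rule) for the two-class reduction.
"""

from __future__ import annotations

import math

import numpy as np


def expand_table(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unroll a J x K count table into per-sample truth/pred vectors."""
    truth, pred = [], []
    J, K = x.shape
    for j in range(J):
        for k in range(K):
            truth.extend([j] * int(x[j, k]))
            pred.extend([k] * int(x[j, k]))
    return np.array(truth), np.array(pred)


def tau_b_pair_enumeration(x: np.ndarray) -> float:
    """Kendall tau-b by enumerating every sample pair of the expanded table."""
    t, p = expand_table(np.asarray(x))
    n = len(t)
    if n < 2:
        return float("nan")
    st = np.sign(np.subtract.outer(t, t))
    sp = np.sign(np.subtract.outer(p, p))
    iu = np.triu_indices(n, k=1)
    prod = st[iu] * sp[iu]
    P = int((prod > 0).sum())
    Q = int((prod < 0).sum())
    n0 = n * (n - 1) / 2
    tr = sum(c * (c - 1) / 2 for c in np.bincount(t))
    tc = sum(c * (c - 1) / 2 for c in np.bincount(p))
    denom = (n0 - tr) * (n0 - tc)
    if denom <= 0:
        return float("nan")
    return (P - Q) / math.sqrt(denom)


def assign_cells_bruteforce(counts: np.ndarray, class_totals: np.ndarray):
    """Per-cell argmax of n_ij / n_+j with largest-class tie-break; 0 marks
    an empty cell.  Pure-python double loop, no vectorised shortcuts."""
    ncells, J = counts.shape
    assignment = []
    ties = set()
    for i in range(ncells):
        if counts[i].sum() == 0:
            assignment.append(0)
            continue
        best_j, best_r, n_best = 0, -float("inf"), 0
        for j in range(1, J + 1):
            if class_totals[j - 1] == 0:
                continue
            r = counts[i, j - 1] / class_totals[j - 1]
            if r > best_r:
                best_j, best_r, n_best = j, r, 1
            elif r == best_r:
                best_j = max(best_j, j)
                n_best += 1
        assignment.append(best_j)
        if n_best > 1:
            ties.add(i)
    return np.array(assignment), ties


class BinaryMDRReference:
    """Classic binary MDR coded from scratch: a genotype cell is high risk
    (class 2) iff its case:control count ratio is >= the training sample's
    overall case:control ratio (ties high risk); empty cells are
    unclassifiable."""

    def __init__(self, cells: np.ndarray, y: np.ndarray, ncells: int):
        # cells: per-sample cell index; y: 1=control, 2=case
        n_case = np.zeros(ncells)
        n_ctrl = np.zeros(ncells)
        for c, yy in zip(cells, y):
            if c < 0:
                continue
            if yy == 2:
                n_case[c] += 1
            else:
                n_ctrl[c] += 1
        total_case, total_ctrl = n_case.sum(), n_ctrl.sum()
        self.assignment = np.zeros(ncells, dtype=int)
        for i in range(ncells):
            if n_case[i] + n_ctrl[i] == 0:
                continue
            # n_case/n_ctrl >= total_case/total_ctrl, cross-multiplied
            if n_case[i] * total_ctrl >= n_ctrl[i] * total_case:
                self.assignment[i] = 2
            else:
                self.assignment[i] = 1

    def predict(self, cells: np.ndarray) -> np.ndarray:
        out = np.zeros(len(cells), dtype=int)
        ok = cells >= 0
        out[ok] = self.assignment[cells[ok]]
        return out
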