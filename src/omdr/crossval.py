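"""L-fold cross-validation, top-K selection and generalized CVC.

For every candidate SNP combination, a classifier is fitted on each set of
L-1 training folds and scored (tau-b by default) on both the training and
the held-out fold.  Within each fold, the K combinations with the largest
TRAINING score are the "top-K" classifiers; the generalized
cross-validation consistency of a combination is

.. math:: \\mathrm{GCVC}^K = \\sum_{l=1}^{L} I_l,

the number of folds in which it ranked among the top K.  With K=1 this is
the classic CVC of binary MDR.  Reporting criteria select combinations by
GCVC (all positive, at least a threshold, or the top N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (
    UNCLASSIFIED,
    GenotypeCellCounts,
    assign_cells,
    cell_indices,
    confusion_from_counts,
)
from .datamodel import DatasetError, GenotypeDataset
from .metrics import tau_b_from_table


@dataclass
class FoldPlan:
    """Partition of samples into L folds, stratified by phenotype class by
    default so no training fold loses a class entirely."""

    n_folds: int
    assignments: np.ndarray  # fold index in 0..L-1 per sample
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


@dataclass
class CVScanResult:
    """Per-combination cross-validation record."""

    combination: tuple[int, ...]
    train_scores: np.ndarray  # (L,), nan where undefined
    test_scores: np.ndarray  # (L,)
    topk_indicator: np.ndarray | None = None  # (L,) 0/1, filled by topk_select
    gcvc: int = 0

    @property
    def order(self) -> int:
        return len(self.combination)

    @property
    def mean_train(self) -> float:
        return _nanmean(self.train_scores)

    @property
    def mean_test(self) -> float:
        return _nanmean(self.test_scores)

    @property
    def n_defined_folds(self) -> int:
        return int((~np.isnan(self.test_scores)).sum())


def _nanmean(v: np.ndarray) -> float:
    ok = ~np.isnan(v)
    return float(v[ok].mean()) if ok.any() else float("nan")


def _key(v: float) -> float:
    """Ranking key: undefined (nan) sorts below any defined value."""
    return -np.inf if np.isnan(v) else v


def make_folds(
    ds: GenotypeDataset, n_folds: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Deterministically partition samples into ``n_folds`` folds.

    Under stratification each phenotype class is split as evenly as
    possible (fold sizes differing by at most one within a class); a class
    with fewer members than folds is spread over as many folds as it has
    members, with a warning.
    """
    if n_folds < 2:
        raise DatasetError("need at least 2 folds")
    if ds.n_samples < n_folds:
        raise DatasetError(f"{ds.n_samples} samples cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(ds.n_samples, dtype=np.int64)
    if stratified:
        for j in range(1, ds.n_classes + 1):
            idx = np.flatnonzero(ds.phenotype == j)
            if 0 < len(idx) < n_folds:
                warnings.warn(
                    f"class {j} has {len(idx)} samples < {n_folds} folds; "
                    "stratification is best-effort",
                    stacklevel=2,
                )
            rng.shuffle(idx)
            assignments[idx] = np.arange(len(idx)) % n_folds
    else:
        perm = rng.permutation(ds.n_samples)
        assignments[perm] = np.arange(ds.n_samples) % n_folds
    return FoldPlan(n_folds, assignments, seed, stratified)


def evaluate_combination(
    ds: GenotypeDataset,
    combo,
    folds: FoldPlan,
    metric: str = "tau_b",
    empty_cell: str = "exclude",
) -> CVScanResult:
    """Fit on each L-1 training split, score train and test confusion
    matrices; a convenience wrapper around :func:`scan` for one combination."""
    return scan(ds, [tuple(combo)], folds, metric=metric, empty_cell=empty_cell)[0]


def _metric_from_table(name: str):
    if name == "tau_b":
        return tau_b_from_table
    if name == "balanced_accuracy":
        def ba(x):
            row = x.sum(axis=1)
            p = row > 0
            return float((np.diag(x)[p] / row[p]).mean()) if p.any() else float("nan")
        return ba
    raise DatasetError(f"unknown metric {name!r}")


def scan(
    ds: GenotypeDataset,
    combos,
    folds: FoldPlan,
    metric: str = "tau_b",
    K: int | None = None,
    empty_cell: str = "exclude",
) -> list[CVScanResult]:
    """Cross-validate every combination; fill top-K fields when K given.

    Per fold the training contingency table is obtained by subtracting the
    test fold's table from the full-data table, so each combination costs
    one pass over the samples plus O(L * 3^m * J) arithmetic.
    """
    J = ds.n_classes
    L = folds.n_folds
    score = _metric_from_table(metric)
    y0 = ds.phenotype - 1
    fold_of = folds.assignments
    results: list[CVScanResult] = []
    for combo in combos:
        combo = tuple(combo)
        ncells = 3 ** len(combo)
        cells = cell_indices(ds, combo)
        ok = cells >= 0
        # per-fold cell x class tables in one bincount
        codes = (fold_of[ok] * ncells + cells[ok]) * J + y0[ok]
        per_fold = np.bincount(codes, minlength=L * ncells * J).reshape(L, ncells, J)
        total = per_fold.sum(axis=0)
        missing_per_fold = np.bincount(fold_of[~ok], minlength=L)
        train_scores = np.empty(L)
        test_scores = np.empty(L)
        for l in range(L):
            train = total - per_fold[l]
            cc = GenotypeCellCounts(
                counts=train,
                class_totals=train.sum(axis=0),
                snp_indices=combo,
                n_missing=int(missing_per_fold.sum() - missing_per_fold[l]),
            )
            model = assign_cells(cc, empty_cell=empty_cell)
            train_scores[l] = score(confusion_from_counts(cc, model).x)
            test = per_fold[l]
            xt = np.zeros((J, J), dtype=np.int64)
            for k in range(1, J + 1):
                xt[:, k - 1] = test[model.assignment == k].sum(axis=0)
            test_scores[l] = score(xt)
        results.append(CVScanResult(combo, train_scores, test_scores))
    if K is not None:
        topk_select(results, K, folds)
    return results


def topk_select(
    results: list[CVScanResult], K: int, folds: FoldPlan
) -> list[CVScanResult]:
    """Mark, per fold, the K combinations with the largest training score
    (ties at the rank-K boundary broken towards the lexicographically
    smallest combination) and fill ``gcvc`` in place."""
    if K < 1:
        raise DatasetError("K must be >= 1")
    if K > len(results):
        warnings.warn(
            f"K={K} exceeds the {len(results)} candidate combinations; "
            "every combination is selected in every fold",
            stacklevel=2,
        )
    L = folds.n_folds
    for r in results:
        r.topk_indicator = np.zeros(L, dtype=np.int64)
    order = list(range(len(results)))
    for l in range(L):
        ranked = sorted(
            order,
            key=lambda idx: (-_key(results[idx].train_scores[l]), results[idx].combination),
        )
        for idx in ranked[: min(K, len(results))]:
            results[idx].topk_indicator[l] = 1
    for r in results:
        r.gcvc = int(r.topk_indicator.sum())
    return results


def _rank_rows(results: list[CVScanResult]) -> list[CVScanResult]:
    return sorted(
        results,
        key=lambda r: (-r.gcvc, -_key(r.mean_test), r.combination),
    )


def report_candidates(
    results: list[CVScanResult],
    criterion: str = "gcvc_positive",
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Rank combinations by (GCVC desc, mean test score desc) and filter by
    one of the reporting criteria:

    - ``"gcvc_positive"`` -- every combination selected in at least one fold;
    - ``"gcvc_at_least:c"`` -- high-consistency candidates (e.g. >= 9 of 10);
    - ``"top_n:N"`` -- the N combinations with the largest GCVC.
    """
    ranked = _rank_rows(results)
    if criterion == "gcvc_positive":
        ranked = [r for r in ranked if r.gcvc > 0]
    elif criterion.startswith("gcvc_at_least:"):
        c = int(criterion.split(":", 1)[1])
        ranked = [r for r in ranked if r.gcvc >= c]
    elif criterion.startswith("top_n:"):
        n = int(criterion.split(":", 1)[1])
        if n > len(ranked):
            warnings.warn(
                f"top_n:{n} requested but only {len(ranked)} combinations scanned",
                stacklevel=2,
            )
        ranked = ranked[:n]
    elif criterion != "all":
        raise DatasetError(f"unknown reporting criterion {criterion!r}")
    rows = []
    for rank, r in enumerate(ranked, start=1):
        names = (
            ",".join(snp_ids[i] for i in r.combination)
            if snp_ids
            else ",".join(str(i) for i in r.combination)
        )
        rows.append(
            {
                "rank": rank,
                "snp_ids": names,
                "order": r.order,
                "gcvc": r.gcvc,
                "mean_train": r.mean_train,
                "mean_test": r.mean_test,
                "n_defined_folds": r.n_defined_folds,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "snp_ids",
            "order",
            "gcvc",
            "mean_train",
            "mean_test",
            "n_defined_folds",
        ],
    )


@dataclass
class BestSelection:
    per_order: dict[int, CVScanResult] = field(default_factory=dict)
    overall: CVScanResult | None = None
    overall_order: int | None = None


def select_best_over_orders(per_order_results: dict[int, list[CVScanResult]]) -> BestSelection:
    """Pick the best combination within each interaction order m (maximal
    GCVC, then mean test score), then the overall best across orders
    (maximal mean test score, ties to larger GCVC, then smaller m --
    parsimony)."""
    if not per_order_results:
        raise DatasetError("no orders scanned")
    sel = BestSelection()
    for m in sorted(per_order_results):
        results = per_order_results[m]
        if not results:
            continue
        sel.per_order[m] = min(
            results, key=lambda r: (-r.gcvc, -_key(r.mean_test), r.combination)
        )
    best_m = min(
        sel.per_order,
        key=lambda m: (
            -_key(sel.per_order[m].mean_test),
            -sel.per_order[m].gcvc,
            m,
        ),
    )
    sel.overall = sel.per_order[best_m]
    sel.overall_order = best_m
    return sel
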