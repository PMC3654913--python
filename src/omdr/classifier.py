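"""Construction and application of m-way OMDR classifiers.

An m-way classifier reduces the :math:`3^m` multi-locus genotype cells of m
SNPs to a single ordinal prediction per cell.  For cell ``i`` and class
``j``, the estimated odds ratio of class ``j`` against the baseline class 1
is

.. math:: \\hat\\theta_{ij} = (n_{ij}/n_{i1}) / (n_{+j}/n_{+1}),

where :math:`n_{ij}` is the number of training individuals with genotype
cell ``i`` in class ``j`` and :math:`n_{+j}` the class-``j`` total.  The
cell is assigned the class maximising :math:`\\hat\\theta_{ij}`, which is
algebraically the class maximising :math:`n_{ij}/n_{+j}`; the latter form
is used because it stays defined when :math:`n_{i1}=0`.  Ties are broken
towards the largest class, matching the binary-MDR convention of calling a
tied cell high risk.

Cell indexing is little-endian mixed-radix base 3: the cell of genotype
vector :math:`(g_1,\\dots,g_m)` is :math:`\\sum_k g_k 3^{k-1}` (0-based).

With J=2 classes the rule reduces exactly to classic binary MDR: a cell is
"case" (class 2) iff its case:control count ratio meets or exceeds the
sample-wide case:control ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, DatasetError, GenotypeDataset

#: Label used for empty cells in a model and unclassifiable samples in a
#: prediction vector (valid classes are 1..J).
UNCLASSIFIED = 0


@dataclass
class GenotypeCellCounts:
    """Contingency table of multi-locus genotype cells vs phenotype classes.

    ``counts[i, j-1]`` is :math:`n_{ij}`; ``class_totals[j-1]`` is
    :math:`n_{+j}` over the samples actually tabulated (samples with a
    missing genotype at any of the m SNPs are excluded -- pairwise deletion).
    """

    counts: np.ndarray  # (3^m, J)
    class_totals: np.ndarray  # (J,)
    snp_indices: tuple[int, ...]
    n_missing: int = 0

    @property
    def m(self) -> int:
        return len(self.snp_indices)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ClassifierModel:
    """A fitted OMDR classifier: one predicted class per genotype cell.

    ``assignment[i]`` is the class in ``1..J`` predicted for cell ``i``, or
    :data:`UNCLASSIFIED` for cells with no training observations.  Cells
    where the maximiser was not unique are recorded in ``tie_cells``.
    """

    assignment: np.ndarray  # (3^m,) int
    snp_indices: tuple[int, ...]
    n_classes: int
    tie_cells: frozenset[int] = field(default_factory=frozenset)

    def to_dict(self, snp_ids: list[str] | None = None) -> dict:
        """JSON-serialisable summary for reporting."""
        d = {
            "snp_indices": list(self.snp_indices),
            "n_classes": self.n_classes,
            "assignment": self.assignment.tolist(),
            "tie_cells": sorted(self.tie_cells),
        }
        if snp_ids is not None:
            d["snp_ids"] = [snp_ids[i] for i in self.snp_indices]
        return d


@dataclass
class ConfusionMatrix:
    """J x J table of true vs predicted class counts.

    ``x[j-1, k-1]`` counts individuals of true class ``j`` predicted as
    class ``k``.  Samples that could not be classified (empty training cell
    or missing genotype) are tallied in ``n_excluded`` and appear nowhere in
    ``x``.
    """

    x: np.ndarray
    n_excluded: int = 0

    @property
    def n_classes(self) -> int:
        return self.x.shape[0]

    @property
    def n_classified(self) -> int:
        return int(self.x.sum())


def cell_indices(ds: GenotypeDataset, snp_indices) -> np.ndarray:
    """Map each sample to its multi-locus genotype cell (little-endian base
    3 over the given SNPs); samples with a missing genotype map to -1."""
    snp_indices = tuple(snp_indices)
    g = ds.genotypes[:, snp_indices]
    powers = 3 ** np.arange(len(snp_indices))
    cells = g @ powers
    cells[(g == MISSING).any(axis=1)] = -1
    return cells


def _check_snps(ds: GenotypeDataset, snp_indices) -> tuple[int, ...]:
    snp_indices = tuple(int(i) for i in snp_indices)
    if len(set(snp_indices)) != len(snp_indices):
        raise DatasetError(f"duplicate SNP indices {snp_indices}")
    if any(i < 0 or i >= ds.n_snps for i in snp_indices):
        raise DatasetError(f"SNP index out of range in {snp_indices}")
    if list(snp_indices) != sorted(snp_indices):
        raise DatasetError(f"SNP indices must be sorted: {snp_indices}")
    return snp_indices


def tabulate_cells(ds: GenotypeDataset, snp_indices) -> GenotypeCellCounts:
    """Tally the (3^m cells) x (J classes) contingency table for m SNPs."""
    snp_indices = _check_snps(ds, snp_indices)
    J = ds.n_classes
    ncells = 3 ** len(snp_indices)
    cells = cell_indices(ds, snp_indices)
    keep = cells >= 0
    codes = cells[keep] * J + (ds.phenotype[keep] - 1)
    counts = np.bincount(codes, minlength=ncells * J).reshape(ncells, J)
    return GenotypeCellCounts(
        counts=counts,
        class_totals=counts.sum(axis=0),
        snp_indices=snp_indices,
        n_missing=int((~keep).sum()),
    )


def estimated_or(counts: GenotypeCellCounts, i: int, j: int) -> float:
    """Estimated odds ratio of class ``j`` (1-based) vs class 1 for cell
    ``i`` (0-based); ``nan`` when undefined (``n_i1 = 0`` or ``n_+j = 0``)."""
    if not 0 <= i < counts.counts.shape[0]:
        raise DatasetError(f"cell index {i} out of range")
    if not 1 <= j <= counts.n_classes:
        raise DatasetError(f"class {j} out of range 1..{counts.n_classes}")
    n_i1 = counts.counts[i, 0]
    n_ij = counts.counts[i, j - 1]
    n_p1 = counts.class_totals[0]
    n_pj = counts.class_totals[j - 1]
    if n_i1 == 0 or n_pj == 0 or n_p1 == 0:
        return float("nan")
    return (n_ij / n_i1) / (n_pj / n_p1)


def assign_cells(
    counts: GenotypeCellCounts, empty_cell: str = "exclude"
) -> ClassifierModel:
    """Assign each genotype cell the class with the largest
    :math:`n_{ij}/n_{+j}` (equivalently the largest odds ratio vs class 1).

    Ties go to the largest class index and the cell is flagged in
    ``tie_cells``.  Cells with no training observations are marked
    :data:`UNCLASSIFIED` by default; ``empty_cell`` may instead force them
    to the ``"largest"`` or ``"smallest"`` class (the binary-MDR-style
    default-to-high-risk behaviour and its mirror).
    """
    if empty_cell not in ("exclude", "largest", "smallest"):
        raise DatasetError(f"unknown empty_cell policy {empty_cell!r}")
    totals = counts.class_totals
    if totals.sum() == 0:
        raise DatasetError("cannot fit a classifier: all class totals are zero")
    J = counts.n_classes
    with np.errstate(invalid="ignore"):
        ratios = np.where(totals > 0, counts.counts / np.maximum(totals, 1), -np.inf)
    # argmax over reversed class axis returns the LARGEST class among ties
    rev_best = np.argmax(ratios[:, ::-1], axis=1)
    assignment = J - rev_best
    best_ratio = np.take_along_axis(ratios, (assignment - 1)[:, None], axis=1)[:, 0]
    n_tied = (ratios == best_ratio[:, None]).sum(axis=1)
    occupied = counts.counts.sum(axis=1) > 0
    tie_cells = frozenset(np.flatnonzero(occupied & (n_tied > 1)).tolist())
    assignment = np.where(occupied, assignment, UNCLASSIFIED)
    if empty_cell == "largest":
        assignment = np.where(occupied, assignment, J)
    elif empty_cell == "smallest":
        assignment = np.where(occupied, assignment, 1)
    return ClassifierModel(
        assignment=assignment.astype(np.int64),
        snp_indices=counts.snp_indices,
        n_classes=J,
        tie_cells=tie_cells,
    )


def predict(model: ClassifierModel, ds: GenotypeDataset) -> np.ndarray:
    """Predicted class per sample (:data:`UNCLASSIFIED` for samples hitting
    an empty training cell or missing a genotype at the model's SNPs)."""
    if any(i >= ds.n_snps for i in model.snp_indices):
        raise DatasetError("model SNPs absent from dataset")
    cells = cell_indices(ds, model.snp_indices)
    out = np.full(ds.n_samples, UNCLASSIFIED, dtype=np.int64)
    ok = cells >= 0
    out[ok] = model.assignment[cells[ok]]
    return out


def confusion(truth: np.ndarray, predicted: np.ndarray, n_classes: int) -> ConfusionMatrix:
    """Cross-tabulate true vs predicted classes into a J x J matrix."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise DatasetError("truth and predicted differ in length")
    if truth.size and (truth.min() < 1 or truth.max() > n_classes):
        raise DatasetError("true class label out of range")
    if predicted.size and (predicted.min() < UNCLASSIFIED or predicted.max() > n_classes):
        raise DatasetError("predicted class label out of range")
    scored = predicted != UNCLASSIFIED
    codes = (truth[scored] - 1) * n_classes + (predicted[scored] - 1)
    x = np.bincount(codes, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )
    return ConfusionMatrix(x=x, n_excluded=int((~scored).sum()))


def confusion_from_counts(
    counts: GenotypeCellCounts, model: ClassifierModel
) -> ConfusionMatrix:
    """Confusion matrix via the cell-sum identity
    :math:`x_{jk} = \\sum_{i: c(i)=k} n_{ij}` -- the table a fitted model
    produces on the data it was tabulated from, without per-sample predict."""
    J = counts.n_classes
    x = np.zeros((J, J), dtype=np.int64)
    for k in range(1, J + 1):
        x[:, k - 1] = counts.counts[model.assignment == k].sum(axis=0)
    excluded = int(counts.counts[model.assignment == UNCLASSIFIED].sum())
    return ConfusionMatrix(x=x, n_excluded=excluded + counts.n_missing)
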