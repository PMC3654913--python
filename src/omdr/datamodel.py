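"""Dataset container and delimited-text I/O for genotype/phenotype data.

A dataset is a samples x SNPs matrix of minor-allele counts (0/1/2, with
``-1`` as the in-memory missing sentinel) paired with an ordinal phenotype
coded as contiguous integer classes ``1..J``.  On disk the dialect is
tab-delimited text with one header row, one sample per row, the phenotype
in a named column and missing genotypes written as ``NA`` -- the additive
coding produced by ``plink --recode A``, so real genotype data can be
converted with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: In-memory sentinel for a missing genotype call.
MISSING = -1

#: String written to / read from disk for a missing genotype.
MISSING_TOKEN = "NA"


class DatasetError(ValueError):
    """Raised when a dataset violates its invariants or a file is malformed."""


@dataclass
class GenotypeDataset:
    """Genotype matrix plus ordinal phenotype.

    Parameters
    ----------
    genotypes
        ``(n, p)`` integer matrix with entries in ``{0, 1, 2}`` or
        :data:`MISSING`.
    phenotype
        Length-``n`` integer vector with entries in ``1..n_classes``.
    snp_ids
        Unique marker names, one per genotype column.
    n_classes
        Number of ordered phenotype classes ``J`` (>= 2).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    n_classes: int = 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetError("genotypes must be a 2-D samples x SNPs matrix")
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        if not self.snp_ids:
            self.snp_ids = [f"SNP{i + 1}" for i in range(self.genotypes.shape[1])]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.n_classes == 0:
            self.n_classes = int(self.phenotype.max(initial=2))
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, p = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise DatasetError(
                f"phenotype length {self.phenotype.shape} does not match {n} samples"
            )
        if len(self.snp_ids) != p:
            raise DatasetError(f"{len(self.snp_ids)} snp_ids for {p} genotype columns")
        if len(set(self.snp_ids)) != p:
            raise DatasetError("snp_ids are not unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DatasetError(
                f"invalid genotype value {self.genotypes[r, c]} at sample {r}, "
                f"SNP {self.snp_ids[c]!r} (must be 0/1/2 or missing)"
            )
        if self.n_classes < 2:
            raise DatasetError("n_classes must be >= 2")
        if n and (self.phenotype.min() < 1 or self.phenotype.max() > self.n_classes):
            j = int(np.argmax((self.phenotype < 1) | (self.phenotype > self.n_classes)))
            raise DatasetError(
                f"phenotype value {self.phenotype[j]} at sample {j} outside 1..{self.n_classes}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def class_counts(self) -> np.ndarray:
        """Observed sample count per phenotype class (length ``n_classes``)."""
        return np.bincount(self.phenotype, minlength=self.n_classes + 1)[1:]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.n_classes == other.n_classes
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


def read_dataset(
    path, phenotype_column: str = "phenotype", n_classes: int | None = None
) -> GenotypeDataset:
    """Read a tab-delimited genotype/phenotype file.

    The header row names the SNP columns and the phenotype column.  When
    ``n_classes`` is omitted, ``J`` is inferred as the largest observed
    phenotype label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if phenotype_column not in df.columns:
        raise DatasetError(f"phenotype column {phenotype_column!r} not in header")
    snp_ids = [c for c in df.columns if c != phenotype_column]
    n = len(df)
    genotypes = np.full((n, len(snp_ids)), MISSING, dtype=np.int8)
    for c, sid in enumerate(snp_ids):
        col = df[sid].to_numpy()
        for r, tok in enumerate(col):
            if tok == MISSING_TOKEN or tok == "":
                continue
            if tok not in ("0", "1", "2"):
                raise DatasetError(
                    f"malformed genotype {tok!r} at row {r + 1}, column {sid!r}"
                )
            genotypes[r, c] = int(tok)
    try:
        phenotype = df[phenotype_column].astype(int).to_numpy()
    except ValueError as exc:
        raise DatasetError(f"non-integer phenotype label: {exc}") from exc
    if n_classes is None:
        n_classes = int(phenotype.max(initial=2))
    return GenotypeDataset(genotypes, phenotype, snp_ids, n_classes)


def write_dataset(ds: GenotypeDataset, path) -> None:
    """Write a dataset in the dialect read by :func:`read_dataset`."""
    g = ds.genotypes.astype(object)
    g[ds.genotypes == MISSING] = MISSING_TOKEN
    df = pd.DataFrame(g, columns=ds.snp_ids)
    df.insert(0, "phenotype", ds.phenotype)
    df.to_csv(path, sep="\t", index=False)


def binarize_phenotype(ds: GenotypeDataset, cut: int) -> GenotypeDataset:
    """Collapse an ordinal phenotype to binary: classes ``<= cut`` become 1
    (control), classes ``> cut`` become 2 (case).  Genotypes are untouched.

    With three risk classes and ``cut=2`` this is the conventional reduction
    of (normal, low risk) to control and high risk to case.
    """
    if not 1 <= cut < ds.n_classes:
        raise DatasetError(f"cut {cut} not in 1..{ds.n_classes - 1}")
    pheno = np.where(ds.phenotype <= cut, 1, 2)
    return replace(ds, phenotype=pheno, n_classes=2)
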