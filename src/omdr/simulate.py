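"""Simulator for ordinal phenotypes driven by a multi-locus interaction.

A genetic model specifies, for each multi-locus genotype of the causal
SNPs, the odds ratio of every phenotype class against the baseline class
(or, equivalently, the penetrance row directly), together with population
class prevalences and causal minor allele frequencies.  Genotypes are
drawn under Hardy-Weinberg equilibrium independently per SNP; each
sample's phenotype is drawn from the penetrance row of its causal genotype
cell; non-causal SNPs are drawn under HWE independently of the phenotype.

Penetrances are derived from odds ratios by proportional scaling,

.. math:: p_{j|i} \\propto \\theta_{ij} \\, p_j / p_1,

normalised so each row sums to one; with all odds ratios equal to 1 this
recovers :math:`p_{j|i} = p_j` exactly (the null model), and recomputing
odds ratios from expected cell counts recovers the input table.

The default study conditions are the reference simulation design: three
classes with prevalences 0.3/0.4/0.3, 50 SNPs of which one pair is causal,
1000 samples per replicate, causal MAFs of 0.3 or 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterator

import numpy as np

from .datamodel import DatasetError, GenotypeDataset


@dataclass
class GeneticModel:
    """Simulator specification for one causal m-way interaction."""

    n_classes: int
    prevalences: np.ndarray  # (J,), sums to 1
    mafs: np.ndarray  # (m_causal,) minor allele frequencies of causal SNPs
    penetrance: np.ndarray  # (3^m_causal, J), rows sum to 1
    or_table: np.ndarray | None = None  # (3^m_causal, J), column 1 all 1.0
    pattern_id: str | None = None

    def __post_init__(self) -> None:
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.prevalences.shape != (self.n_classes,):
            raise DatasetError("prevalences must have one entry per class")
        if (self.prevalences <= 0).any() or abs(self.prevalences.sum() - 1) > 1e-9:
            raise DatasetError("prevalences must be positive and sum to 1")
        ncells = 3 ** len(self.mafs)
        if self.penetrance.shape != (ncells, self.n_classes):
            raise DatasetError(
                f"penetrance table must be {ncells} x {self.n_classes}"
            )
        if (self.penetrance < 0).any() or (self.penetrance > 1).any():
            raise DatasetError("penetrances must lie in [0, 1]")
        if not np.allclose(self.penetrance.sum(axis=1), 1.0, atol=1e-8):
            bad = int(np.argmax(np.abs(self.penetrance.sum(axis=1) - 1)))
            raise DatasetError(f"penetrance row {bad} does not sum to 1")
        if self.or_table is not None:
            self.or_table = np.asarray(self.or_table, dtype=float)
            if not np.allclose(self.or_table[:, 0], 1.0):
                raise DatasetError("odds-ratio column for class 1 must be 1.0")

    @property
    def n_causal(self) -> int:
        return len(self.mafs)


@dataclass
class SimulationConfig:
    """Replicate-generation settings (defaults follow the reference
    simulation design: n=1000 samples, 50 SNPs, 100 replicates)."""

    n_samples: int = 1000
    n_snps: int = 50
    n_replicates: int = 100
    seed: int = 0
    causal_positions: tuple[int, ...] = (0, 1)
    noncausal_maf: float = 0.3

    def __post_init__(self) -> None:
        self.causal_positions = tuple(int(i) for i in self.causal_positions)
        if len(set(self.causal_positions)) != len(self.causal_positions):
            raise DatasetError("causal positions must be distinct")
        if max(self.causal_positions, default=-1) >= self.n_snps:
            raise DatasetError("causal position beyond the SNP panel")


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Genotype probabilities ((1-q)^2, 2q(1-q), q^2) for allele frequency q
    under Hardy-Weinberg equilibrium."""
    if not 0 < maf <= 0.5:
        raise DatasetError(f"minor allele frequency {maf} not in (0, 0.5]")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def penetrance_from_ors(or_table: np.ndarray, prevalences: np.ndarray) -> np.ndarray:
    """Per-genotype class probabilities implied by odds ratios vs class 1.

    Row i becomes ``theta_ij * p_j / p_1`` renormalised to sum to one, so a
    table of all-1 odds ratios reproduces the prevalences in every row.
    """
    or_table = np.asarray(or_table, dtype=float)
    prevalences = np.asarray(prevalences, dtype=float)
    if (or_table < 0).any():
        raise DatasetError("odds ratios must be nonnegative")
    w = or_table * (prevalences / prevalences[0])
    return w / w.sum(axis=1, keepdims=True)


def ors_from_penetrance(penetrance: np.ndarray, prevalences: np.ndarray) -> np.ndarray:
    """Inverse of :func:`penetrance_from_ors` (odds ratios vs class 1)."""
    penetrance = np.asarray(penetrance, dtype=float)
    prevalences = np.asarray(prevalences, dtype=float)
    return (penetrance / penetrance[:, :1]) / (prevalences / prevalences[0])


def null_model(
    prevalences=(0.3, 0.4, 0.3), mafs=(0.3, 0.5)
) -> GeneticModel:
    """No-effect model: every penetrance row equals the prevalences, so the
    phenotype is independent of every SNP."""
    prevalences = np.asarray(prevalences, dtype=float)
    ncells = 3 ** len(mafs)
    or_table = np.ones((ncells, len(prevalences)))
    return GeneticModel(
        n_classes=len(prevalences),
        prevalences=prevalences,
        mafs=np.asarray(mafs, dtype=float),
        penetrance=penetrance_from_ors(or_table, prevalences),
        or_table=or_table,
        pattern_id="null",
    )


def cell_hwe_probs(model: GeneticModel) -> np.ndarray:
    """Probability of each causal multi-locus genotype cell under HWE
    (little-endian base-3 cell order, matching the classifier)."""
    per_snp = [hwe_genotype_freqs(q) for q in model.mafs]
    probs = np.ones(3 ** model.n_causal)
    for i, gts in enumerate(product(*[range(3)] * model.n_causal)):
        # product() varies the LAST snp fastest; cell index uses little-endian
        cell = sum(g * 3**k for k, g in enumerate(gts))
        probs[cell] = np.prod([per_snp[k][g] for k, g in enumerate(gts)])
    return probs


def implied_prevalences(model: GeneticModel) -> np.ndarray:
    """Marginal class probabilities implied by (HWE cell probabilities x
    penetrances) -- a diagnostic for drift from the target prevalences."""
    return cell_hwe_probs(model) @ model.penetrance


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, individually reproducible stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def simulate_dataset(
    model: GeneticModel,
    config: SimulationConfig,
    rng: np.random.Generator | int,
) -> GenotypeDataset:
    """Draw one dataset: causal genotypes under HWE, phenotype from the
    causal cell's penetrance row, non-causal SNPs under HWE independent of
    the phenotype."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(config.causal_positions) != model.n_causal:
        raise DatasetError(
            f"model has {model.n_causal} causal SNPs but config names "
            f"{len(config.causal_positions)} positions"
        )
    n, p = config.n_samples, config.n_snps
    genotypes = np.empty((n, p), dtype=np.int8)
    causal = set(config.causal_positions)
    # causal SNP draws in position order, so the cell index convention below
    # matches tabulate_cells on sorted SNP indices
    causal_g = np.empty((n, model.n_causal), dtype=np.int8)
    for k, pos in enumerate(config.causal_positions):
        freqs = hwe_genotype_freqs(model.mafs[k])
        causal_g[:, k] = rng.choice(3, size=n, p=freqs)
        genotypes[:, pos] = causal_g[:, k]
    for pos in range(p):
        if pos in causal:
            continue
        freqs = hwe_genotype_freqs(config.noncausal_maf)
        genotypes[:, pos] = rng.choice(3, size=n, p=freqs)
    cells = causal_g @ (3 ** np.arange(model.n_causal))
    u = rng.random(n)
    cum = model.penetrance.cumsum(axis=1)
    phenotype = 1 + (u[:, None] > cum[cells]).sum(axis=1)
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_ids=[f"SNP{i + 1}" for i in range(p)],
        n_classes=model.n_classes,
    )


def simulate_replicates(
    model: GeneticModel, config: SimulationConfig
) -> Iterator[GenotypeDataset]:
    """Stream ``config.n_replicates`` independent datasets; replicate r is
    reproducible in isolation via ``replicate_rng(config.seed, r)``."""
    for r in range(config.n_replicates):
        yield simulate_dataset(model, config, replicate_rng(config.seed, r))


# -- model-spec files -----------------------------------------------------

def load_model_spec(path) -> GeneticModel:
    """Load a genetic model from a JSON spec.

    Keys: ``classes``, ``prevalences``, ``mafs``, ``genotype_rows`` (one
    entry per multi-locus genotype with ``genotype: [g1..gm]`` and either
    ``or: [...]`` or ``penetrance: [...]``), optional ``pattern_id``.
    """
    spec = json.loads(Path(path).read_text())
    return model_from_dict(spec)


def model_from_dict(spec: dict) -> GeneticModel:
    J = int(spec["classes"])
    prevalences = np.asarray(spec["prevalences"], dtype=float)
    mafs = np.asarray(spec["mafs"], dtype=float)
    m = len(mafs)
    ncells = 3**m
    rows = spec.get("genotype_rows", [])
    pen = np.full((ncells, J), np.nan)
    ors = np.full((ncells, J), np.nan)
    has_or = False
    has_pen = False
    for row in rows:
        g = row["genotype"]
        if len(g) != m or any(x not in (0, 1, 2) for x in g):
            raise DatasetError(f"bad genotype vector {g} in model spec")
        cell = sum(int(x) * 3**k for k, x in enumerate(g))
        if "penetrance" in row:
            pen[cell] = row["penetrance"]
            has_pen = True
        if "or" in row:
            ors[cell] = row["or"]
            has_or = True
    if has_pen:
        if np.isnan(pen).any():
            missing = int(np.argmax(np.isnan(pen).any(axis=1)))
            g = [(missing // 3**k) % 3 for k in range(m)]
            raise DatasetError(f"model spec missing penetrance row for genotype {g}")
        penetrance = pen
        or_table = ors if has_or and not np.isnan(ors).any() else None
    elif has_or:
        if np.isnan(ors).any():
            missing = int(np.argmax(np.isnan(ors).any(axis=1)))
            g = [(missing // 3**k) % 3 for k in range(m)]
            raise DatasetError(f"model spec missing OR row for genotype {g}")
        or_table = ors
        penetrance = penetrance_from_ors(ors, prevalences)
    else:
        raise DatasetError("model spec has neither penetrance nor OR rows")
    return GeneticModel(
        n_classes=J,
        prevalences=prevalences,
        mafs=mafs,
        penetrance=penetrance,
        or_table=or_table,
        pattern_id=spec.get("pattern_id"),
    )


def builtin_model(name: str) -> GeneticModel:
    """Load a model shipped with the package (``null_3class``,
    ``strong_checkerboard``, ``demo_moderate``)."""
    ref = resources.files("omdr.models").joinpath(f"{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise DatasetError(f"no built-in model named {name!r}") from None
    return model_from_dict(json.loads(text))
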