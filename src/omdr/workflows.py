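"""High-level pipelines: multi-order interaction scans and power studies.

These tie the enumeration, cross-validation and simulation layers into the
two workflows users actually run: scanning one dataset for the best 1..m-way
interactions, and estimating empirical power / selection stability /
predictability of the method over simulated replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import (
    BestSelection,
    CVScanResult,
    make_folds,
    scan,
    select_best_over_orders,
)
from .datamodel import DatasetError, GenotypeDataset
from .search import enumerate_exhaustive, staged_candidates
from .simulate import GeneticModel, SimulationConfig, replicate_rng, simulate_dataset


@dataclass
class ScanOutcome:
    per_order: dict[int, list[CVScanResult]]
    best: BestSelection
    fold_seed: int


def scan_dataset(
    ds: GenotypeDataset,
    orders=(1, 2),
    n_folds: int = 10,
    K: int = 1,
    seed: int = 0,
    metric: str = "tau_b",
    mode: str = "exhaustive",
    carry_k: int = 300,
    empty_cell: str = "exclude",
) -> ScanOutcome:
    """Cross-validated scan of candidate combinations at each order.

    In ``exhaustive`` mode every C(p, m) combination is evaluated at every
    order; in ``staged`` mode order m only examines SNPs carried forward
    from the top ``carry_k`` combinations at order m-1.
    """
    if ds.n_classes < 2:
        raise DatasetError("phenotype must have at least 2 classes")
    orders = sorted(set(int(m) for m in orders))
    folds = make_folds(ds, n_folds=n_folds, seed=seed, stratified=True)
    per_order: dict[int, list[CVScanResult]] = {}
    if mode not in ("exhaustive", "staged"):
        raise DatasetError(f"unknown search mode {mode!r}")
    if mode == "staged" and orders != list(range(1, len(orders) + 1)):
        raise DatasetError("staged mode requires consecutive orders starting at 1")
    prev: list[CVScanResult] | None = None
    for m in orders:
        if mode == "exhaustive" or m == 1:
            combos = enumerate_exhaustive(ds.n_snps, m)
        else:
            combos = staged_candidates(prev, carry_k, m)
        per_order[m] = scan(ds, combos, folds, metric=metric, K=K, empty_cell=empty_cell)
        prev = per_order[m]
    return ScanOutcome(per_order, select_best_over_orders(per_order), seed)


@dataclass
class PowerSummary:
    """Per-order power/stability/predictability summary over replicates.

    ``table`` columns mirror the standard simulation report: empirical
    power EP (fraction of replicates in which the causal combination was
    the top-ranked classifier at its own order), mean GCVC of the causal
    combination as a fraction of L, and the average test (TSTB) and train
    (TRTB) scores of the per-replicate best classifier.
    """

    table: pd.DataFrame
    causal: tuple[int, ...]
    n_replicates: int
    per_order_gcvc: dict[int, np.ndarray] = field(default_factory=dict)
    per_order_combos: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)
    overall_power: float = float("nan")


def power_study(
    model: GeneticModel,
    config: SimulationConfig,
    orders=(1, 2),
    n_folds: int = 10,
    K: int = 1,
    metric: str = "tau_b",
    track_gcvc_orders=(),
) -> PowerSummary:
    """Estimate empirical power of the scan over simulated replicates.

    At the causal order a replicate counts as a success when the causal
    combination is the top-ranked combination (GCVC first, then mean test
    score).  At lower orders success means the winner is a subset of the
    causal combination (a causal SNP won the single-locus scan); at higher
    orders, a superset (the winning triple contains the causal pair).
    ``overall_power`` requires the causal combination to win across orders.
    ``track_gcvc_orders`` collects the full per-combination GCVC matrix
    (replicates x combinations) at the named orders, for selection-
    stability comparisons between causal and non-causal combinations.
    """
    causal = tuple(sorted(config.causal_positions))
    orders = sorted(set(int(m) for m in orders))
    track = set(track_gcvc_orders)
    rows = {
        m: {"ep": 0, "gcvc": [], "tstb": [], "trtb": []} for m in orders
    }
    per_order_gcvc: dict[int, list[np.ndarray]] = {m: [] for m in track}
    per_order_combos: dict[int, list[tuple[int, ...]]] = {}
    overall_hits = 0
    for r in range(config.n_replicates):
        ds = simulate_dataset(model, config, replicate_rng(config.seed, r))
        fold_seed = int(replicate_rng(config.seed, r).integers(2**31 - 1))
        outcome = scan_dataset(
            ds, orders=orders, n_folds=n_folds, K=K, seed=fold_seed, metric=metric
        )
        for m in orders:
            results = outcome.per_order[m]
            best = outcome.best.per_order[m]
            rows[m]["tstb"].append(best.mean_test)
            rows[m]["trtb"].append(best.mean_train)
            rows[m]["gcvc"].append(best.gcvc)
            won, causal_set = set(best.combination), set(causal)
            if m == len(causal):
                rows[m]["ep"] += won == causal_set
            elif m < len(causal):
                rows[m]["ep"] += won <= causal_set
            else:
                rows[m]["ep"] += won >= causal_set
            if m in track:
                combos = [x.combination for x in results]
                if m not in per_order_combos:
                    per_order_combos[m] = combos
                per_order_gcvc[m].append(np.array([x.gcvc for x in results]))
        if outcome.best.overall is not None and outcome.best.overall.combination == causal:
            overall_hits += 1
    records = []
    for m in orders:
        d = rows[m]
        records.append(
            {
                "order": m,
                "ep": d["ep"] / config.n_replicates,
                "mean_gcvc": float(np.mean(d["gcvc"])) / n_folds,
                "tstb": float(np.nanmean(d["tstb"])),
                "trtb": float(np.nanmean(d["trtb"])),
            }
        )
    return PowerSummary(
        table=pd.DataFrame(records),
        causal=causal,
        n_replicates=config.n_replicates,
        per_order_gcvc={m: np.vstack(v) for m, v in per_order_gcvc.items()},
        per_order_combos=per_order_combos,
        overall_power=overall_hits / config.n_replicates,
    )
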