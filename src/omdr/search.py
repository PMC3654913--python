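"""Candidate SNP-combination enumeration.

Two strategies: an exhaustive scan of all C(p, m) m-subsets (feasible for
tens of SNPs), and a staged scan for large marker panels in which only the
SNPs appearing in the top-ranked combinations at order m-1 are carried
forward to order m -- the strategy used to take a genome-wide panel from
single-SNP effects up to 4-way interactions.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Iterator

from .crossval import CVScanResult, _key
from .datamodel import DatasetError


def enumerate_exhaustive(p: int, m: int) -> Iterator[tuple[int, ...]]:
    """Yield all C(p, m) sorted m-subsets of ``range(p)`` in lexicographic
    order (a generator, so order-4 scans never materialise the list)."""
    if not 1 <= m <= p:
        raise DatasetError(f"order m={m} not in 1..{p}")
    return combinations(range(p), m)


def staged_candidates(
    prev_results: Iterable[CVScanResult], carry_k: int, m: int
) -> Iterator[tuple[int, ...]]:
    """Carry forward the SNPs of the top ``carry_k`` combinations at order
    m-1 (ranked by GCVC, then mean test score) and yield all m-subsets of
    that pool."""
    prev = list(prev_results)
    if not prev:
        raise DatasetError("staged search needs results from the previous order")
    ranked = sorted(prev, key=lambda r: (-r.gcvc, -_key(r.mean_test), r.combination))
    pool: set[int] = set()
    for r in ranked[: min(carry_k, len(ranked))]:
        pool.update(r.combination)
    pool_sorted = sorted(pool)
    if len(pool_sorted) < m:
        warnings.warn(
            f"carried-forward SNP pool of size {len(pool_sorted)} is smaller "
            f"than order {m}; no candidates",
            stacklevel=2,
        )
        return iter(())
    return combinations(pool_sorted, m)
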