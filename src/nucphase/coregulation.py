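"""Co-regulation analysis of two differential-expression tables.

Genes responding to two independent depletions more often than chance
suggests the depleted proteins act in a common pathway. Each table is
filtered to its significantly regulated genes (fold change beyond a
threshold in either direction, with both raw and FDR-adjusted p below
cutoffs), the overlap of the two sets over the commonly measured universe is
tested with a one-sided (enrichment) hypergeometric tail computed in log
space -- the observed overlaps can push p far below the double-precision
underflow limit of a naive summation -- and effect-size concordance over the
shared genes is measured by Spearman rank correlation of signed log2 fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, spearmanr

from .io import GeneRecord

__all__ = [
    "OverlapResult",
    "filter_significant",
    "overlap_test",
    "concordance",
    "coregulation_analysis",
]


@dataclass(frozen=True)
class OverlapResult:
    """Counts and statistics for the overlap of two filtered gene sets."""

    n_universe: int
    n_a: int
    n_b: int
    n_shared: int
    hypergeom_p: float
    log10_hypergeom_p: float
    spearman_rho: float | None = None
    spearman_p: float | None = None


def filter_significant(
    table: Sequence[GeneRecord],
    fc_threshold: float = 1.5,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> set[str]:
    """Gene ids passing the differential-regulation filter.

    A gene is kept iff its fold change is strictly beyond ``fc_threshold``
    in either direction (``fc > t`` or ``fc < 1/t``) and both p and q are
    strictly below their cutoffs.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    lo = 1.0 / fc_threshold
    return {
        g.gene_id
        for g in table
        if (g.fold_change > fc_threshold or g.fold_change < lo)
        and g.p_value < p_max
        and g.q_value < q_max
    }


def _log_hypergeom_sf(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(n_universe, n_a, n_b).

    Summed term-by-term in log space from the hypergeometric log-pmf, which
    stays accurate at tails far below the underflow limit of the plain sf.
    """
    upper = min(n_a, n_b)
    if k <= 0:
        return 0.0
    if k > upper:
        return -math.inf
    ks = np.arange(k, upper + 1)
    return float(logsumexp(hypergeom.logpmf(ks, n_universe, n_a, n_b)))


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided hypergeometric enrichment test for the overlap of two sets.

    ``hypergeom_p = P(X >= |A & B|)`` for ``X`` counting the overlap of a
    random ``|B|``-subset with a fixed ``|A|``-subset of the universe;
    symmetric in the two sets.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both gene sets must be contained in the universe")
    k = len(a & b)
    log_p = _log_hypergeom_sf(k, len(u), len(a), len(b))
    return OverlapResult(
        n_universe=len(u),
        n_a=len(a),
        n_b=len(b),
        n_shared=k,
        hypergeom_p=float(math.exp(log_p)),
        log10_hypergeom_p=log_p / math.log(10.0),
    )


def concordance(
    table_a: Sequence[GeneRecord],
    table_b: Sequence[GeneRecord],
    shared: Iterable[str],
) -> tuple[float, float]:
    """Spearman correlation of signed log2 fold changes over shared genes.

    Ties get average ranks; the p-value uses the large-sample t
    approximation. Requires at least 3 shared genes.
    """
    shared = set(shared)
    if len(shared) < 3:
        raise ValueError("concordance requires at least 3 shared genes")
    fc_a = {g.gene_id: g.fold_change for g in table_a}
    fc_b = {g.gene_id: g.fold_change for g in table_b}
    missing = shared - (fc_a.keys() & fc_b.keys())
    if missing:
        raise ValueError(f"shared genes missing from a table: {sorted(missing)[:5]}")
    ids = sorted(shared)
    x = np.log2([fc_a[i] for i in ids])
    y = np.log2([fc_b[i] for i in ids])
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def coregulation_analysis(
    table_a: Sequence[GeneRecord],
    table_b: Sequence[GeneRecord],
    fc_threshold: float = 1.5,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> OverlapResult:
    """Full two-table analysis: filter, overlap test, concordance.

    The universe is the set of genes measured in both tables; concordance
    is computed over the shared significant genes when there are at least 3.
    """
    ids_a = {g.gene_id for g in table_a}
    ids_b = {g.gene_id for g in table_b}
    universe = ids_a & ids_b
    sig_a = filter_significant(table_a, fc_threshold, p_max, q_max) & universe
    sig_b = filter_significant(table_b, fc_threshold, p_max, q_max) & universe
    result = overlap_test(sig_a, sig_b, universe)
    shared = sig_a & sig_b
    rho = p = None
    if len(shared) >= 3:
        rho, p = concordance(table_a, table_b, shared)
    return OverlapResult(
        n_universe=result.n_universe,
        n_a=result.n_a,
        n_b=result.n_b,
        n_shared=result.n_shared,
        hypergeom_p=result.hypergeom_p,
        log10_hypergeom_p=result.log10_hypergeom_p,
        spearman_rho=rho,
        spearman_p=p,
    )
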