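"""Gene-set over-representation analysis.

Upper-tail hypergeometric p-values (optionally the conservative EASE
variant that removes one overlap member), Benjamini-Hochberg adjustment,
a p-value cutoff, and pathway membership mapping. The universe defaults to
the union of all collection members when not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core_io import GeneSetCollection
from .errors import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's overlap and significance.

    k: overlap between query and set within the universe; K: set size in
    the universe; n: query size in the universe; N: universe size.
    """

    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    overlap_genes: tuple[str, ...] = ()


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
    if K > N or n > N:
        raise ValidationError(f"need K <= N and n <= N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K={K}, n={n})")


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    # survival function at k-1 gives the inclusive upper tail
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """EASE variant: upper tail with one overlap member removed."""
    _check_counts(k, K, n, N)
    return hypergeometric_upper(max(k - 1, 0), K, n, N)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


def run_enrichment(query_genes, collection: GeneSetCollection,
                   universe_genes=None, p_cutoff: float = 0.01,
                   use_ease: bool = False
                   ) -> tuple[list[EnrichmentResult], int]:
    """Over-representation of query genes in each collection set.

    Returns (results sorted by ascending raw p-value and filtered to
    p_value < p_cutoff, number of query genes dropped for lying outside
    the universe). BH adjustment is computed across all sets with nonzero
    universe membership before the cutoff is applied, so both raw and
    adjusted values are reported.
    """
    if universe_genes is None:
        universe = set(collection.all_members())
    else:
        universe = {g.strip().upper() for g in universe_genes}
    if not universe:
        raise ValidationError("empty gene universe")
    query_raw = {g.strip().upper() for g in query_genes}
    query = query_raw & universe
    n_dropped = len(query_raw - universe)
    N, n = len(universe), len(query)

    tested: list[tuple[str, str, int, int, frozenset[str]]] = []
    for set_id, desc, members in collection:
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = query & in_universe
        tested.append((set_id, desc, len(overlap), len(in_universe),
                       frozenset(overlap)))
    if not tested:
        return [], n_dropped
    score = ease_score if use_ease else hypergeometric_upper
    pvals = [score(k, K, n, N) for _s, _d, k, K, _o in tested]
    qvals = bh_adjust(pvals)
    results = [EnrichmentResult(set_id=s, description=d, k=k, K=K, n=n, N=N,
                                p_value=p, p_adjusted=float(q),
                                overlap_genes=tuple(sorted(o)))
               for (s, d, k, K, o), p, q in zip(tested, pvals, qvals)]
    results = [r for r in results if r.p_value < p_cutoff]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results, n_dropped


def map_to_pathway(target_genes, pathway_set) -> tuple[list[str], list[str]]:
    """Partition target genes by membership in one pathway's gene set.

    pathway_set may be a set/frozenset of symbols or a (set_id,
    description, members) triple from a GeneSetCollection. Returns sorted
    (mapped, unmapped) lists.
    """
    if isinstance(pathway_set, tuple) and len(pathway_set) == 3:
        members = pathway_set[2]
    else:
        members = pathway_set
    members = {g.strip().upper() for g in members}
    genes = {g.strip().upper() for g in target_genes}
    mapped = sorted(genes & members)
    unmapped = sorted(genes - members)
    return mapped, unmapped
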