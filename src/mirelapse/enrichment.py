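"""Gene-set over-representation analysis (GO/KEGG-style, flat GMT sets).

Given a query gene list (here, the genes hit by anti-correlated miRNA
pairs) and a collection of named gene sets, each set is tested for
over-representation with the one-sided hypergeometric tail
P(X >= k) for X ~ Hypergeometric(N, K, n), where N is the background
universe size, K the set size within the universe, n the query size within
the universe and k their overlap.  The background defaults to the genes
present in the expression data — the defensible universe for a query that
was itself derived from that data.  Benjamini-Hochberg correction is
applied across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets plus a background universe.

    Sets are intersected with the universe before testing; empty sets are
    rejected.
    """

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class EnrichmentRow:
    set_id: str
    overlap: int  # k
    query_size: int  # n
    set_size: int  # K (within universe)
    universe_size: int  # N
    p_value: float
    adjusted_p: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Delegates to the survival function of ``scipy.stats.hypergeom``, which
    evaluates the tail stably in log space.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"impossible configuration k={k}, n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError("k cannot exceed min(n, K)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    collection: GeneSetCollection,
    correction: str = "BH",
) -> list[EnrichmentRow]:
    """Over-representation of a query gene list in each set of a collection.

    Returns one row per set that intersects the universe, sorted by
    p-value; ``adjusted_p`` is BH across all tested sets (or equal to the
    raw p with ``correction="none"``).
    """
    if correction not in ("BH", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    universe = set(collection.universe)
    q = set(query) & universe
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(universe), len(q)

    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id] & universe
        if not members:
            continue
        K = len(members)
        overlap = q & members
        k = len(overlap)
        p = hypergeom_tail(k, n, K, N)
        rows.append(
            EnrichmentRow(set_id, k, n, K, N, p, p, tuple(sorted(overlap)))
        )
    if correction == "BH" and rows:
        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, a in zip(rows, adj):
            r.adjusted_p = float(a)
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in rows],
            "overlap": [r.overlap for r in rows],
            "query_size": [r.query_size for r in rows],
            "set_size": [r.set_size for r in rows],
            "universe_size": [r.universe_size for r in rows],
            "p": [r.p_value for r in rows],
            "adjusted_p": [r.adjusted_p for r in rows],
        }
    )
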