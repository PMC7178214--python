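"""Gene-set enrichment and interaction-network hub ranking.

Enrichment of a query gene list against named gene sets uses the two-sided
hypergeometric test (doubled smaller tail, capped at 1) with Holm
("Bonferroni step-down") correction across sets; direction (enriched vs
depleted) is called by comparing the observed overlap with its expectation
n*K/N.  Hub ranking takes a user-supplied undirected edge list (physical,
genetic, co-expression, co-localization or predicted interactions) and
orders the query genes by interaction degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "InteractionEdge",
    "enrich_gene_sets",
    "rank_hubs",
    "load_edges",
    "write_edges",
    "enrichment_to_frame",
]

logger = logging.getLogger(__name__)

EDGE_TYPES = ("physical", "genetic", "coexpression", "colocalization", "predicted")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    set_name: str
    k: int           # overlap of query with the set (within background)
    K: int           # set size within background
    n: int           # query size
    N: int           # background size
    proportion: float  # k / K
    p_value: float
    p_corrected: float
    direction: str   # enriched | depleted


@dataclass(frozen=True)
class InteractionEdge:
    gene_a: str
    gene_b: str
    edge_type: str = "physical"
    weight: float = 1.0

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction for {self.gene_a!r}")
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        # canonical undirected ordering
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def key(self) -> tuple[str, str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return (a, b, self.edge_type)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down family-wise correction (per-rank multipliers m, m-1,
    ... with enforced monotonicity), as applied across gene sets."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="holm")[1]


def enrich_gene_sets(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
    descriptions: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Two-sided hypergeometric enrichment of ``query`` in each gene set.

    Set members are intersected with the background before testing; sets
    that vanish under the background are skipped with a log entry.  Results
    are sorted by raw p-value (ties by set id).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    stray = sorted(q - bg)
    if stray:
        raise ValueError(f"query genes not in background: {stray[:10]}")
    N, n = len(bg), len(q)
    descriptions = descriptions or {}

    tested = []
    for set_id in sets:
        members = set(sets[set_id]) & bg
        K = len(members)
        if K == 0:
            logger.info("set %s has no members in the background, skipped", set_id)
            continue
        k = len(q & members)
        upper = float(stats.hypergeom.sf(k - 1, N, K, n))
        lower = float(stats.hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(upper, lower))
        direction = "enriched" if k >= n * K / N else "depleted"
        tested.append((set_id, k, K, p, direction))

    if not tested:
        return []
    raw = [t[3] for t in tested]
    corrected = holm_correction(raw)
    results = [
        EnrichmentResult(
            set_id=set_id,
            set_name=descriptions.get(set_id, set_id),
            k=k, K=K, n=n, N=N,
            proportion=k / K,
            p_value=p,
            p_corrected=float(pc),
            direction=direction,
        )
        for (set_id, k, K, p, direction), pc in zip(tested, corrected)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_id))


def rank_hubs(
    edges: Iterable[InteractionEdge], query: Iterable[str]
) -> pd.DataFrame:
    """Degree-based hub ranking of the query genes.

    Duplicate edges (same unordered pair and type) count once.  Reported
    per query gene: total degree, degree per edge type, and degree split
    by neighbour class (query vs non-query).  Ranking is by total degree
    descending, ties broken lexicographically by gene id.
    """
    q = set(query)
    unique = {}
    for e in edges:
        unique[e.key] = e
    degree: dict[str, int] = {g: 0 for g in q}
    by_type: dict[str, dict[str, int]] = {g: {t: 0 for t in EDGE_TYPES} for g in q}
    to_query: dict[str, int] = {g: 0 for g in q}
    to_other: dict[str, int] = {g: 0 for g in q}
    for e in unique.values():
        for gene, nbr in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            if gene not in q:
                continue
            degree[gene] += 1
            by_type[gene][e.edge_type] += 1
            if nbr in q:
                to_query[gene] += 1
            else:
                to_other[gene] += 1
    rows = [
        {
            "gene_id": g,
            "degree": degree[g],
            "degree_query": to_query[g],
            "degree_nonquery": to_other[g],
            **{f"degree_{t}": by_type[g][t] for t in EDGE_TYPES},
        }
        for g in q
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(["degree", "gene_id"], ascending=[False, True])
    return df.reset_index(drop=True)


def load_edges(path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    edges = []
    for row in df.itertuples(index=False):
        edges.append(InteractionEdge(
            gene_a=row.gene_a, gene_b=row.gene_b,
            edge_type=getattr(row, "edge_type", "physical"),
            weight=float(getattr(row, "weight", 1.0)),
        ))
    return edges


def write_edges(edges: Iterable[InteractionEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tedge_type\tweight\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.edge_type}\t{repr(e.weight)}\n")


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
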