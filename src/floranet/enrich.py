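"""Pathway over-representation of DEG sets.

KEGG-style enrichment: for a DEG set of size n drawn from a universe of N
annotated genes, a pathway with K annotated members and k DEG members is
scored with the upper-tail hypergeometric probability P(X >= k). P-values
are corrected across pathways with the Benjamini-Hochberg step-up procedure
and a pathway is called significant at corrected p (q) < 0.05. Only
over-representation is tested, and the universe is restricted to genes that
carry at least one pathway annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichError(ValueError):
    pass


@dataclass
class PathwayAnnotation:
    """gene -> pathways mapping plus pathway display names.

    Genes with empty pathway sets are not stored; the universe for testing
    is exactly the annotated genes.
    """

    gene_pathways: dict[str, set[str]]
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [g for g, ps in self.gene_pathways.items() if not ps]
        for g in empty:
            del self.gene_pathways[g]

    @property
    def universe(self) -> set[str]:
        return set(self.gene_pathways)

    @property
    def pathways(self) -> set[str]:
        out: set[str] = set()
        for ps in self.gene_pathways.values():
            out |= ps
        return out

    def members(self, pathway: str) -> set[str]:
        return {g for g, ps in self.gene_pathways.items() if pathway in ps}

    def name_of(self, pathway: str) -> str:
        return self.pathway_names.get(pathway, pathway)


def hypergeom_upper_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise EnrichError("invalid hypergeometric configuration")
    return float(min(stats.hypergeom.sf(k - 1, big_n, big_k, n), 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise EnrichError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    deg_set: set[str],
    annotation: PathwayAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per pathway with >= 1 DEG member.

    Returns one row per tested pathway with columns pathway, name, k, K, n,
    N, p, q, significant; sorted by ascending p (ties by pathway id).
    """
    universe = annotation.universe
    if not universe:
        raise EnrichError("empty annotation universe")
    degs = set(deg_set) & universe
    n, big_n = len(degs), len(universe)
    rows = []
    for pathway in sorted(annotation.pathways):
        members = annotation.members(pathway)
        k = len(degs & members)
        if k == 0:
            continue
        big_k = len(members)
        p = hypergeom_upper_tail(k, big_n, big_k, n)
        rows.append(
            {"pathway": pathway, "name": annotation.name_of(pathway),
             "k": k, "K": big_k, "n": n, "N": big_n, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "name", "k", "K", "n", "N", "p", "q", "significant"]
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
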