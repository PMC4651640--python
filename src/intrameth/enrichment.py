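"""Hypergeometric over-representation along a ranked gene list.

Given genes ordered best-first by some single-gene classifier score,
each prefix (gene #1 up to the current gene) is tested for
over-representation of a functional gene set: the p-value is the
upper-tail hypergeometric probability that at least the observed number
of set members entered the prefix by drawing that many genes at random
from the whole pool.  The null is rejected where p < 0.01; no
multiple-testing correction gates the flag (a Bonferroni column is
provided for reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them in the set, ``n`` drawn;
    the observed overlap ``k`` is included in the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentCurve:
    """Per-prefix over-representation p-values for one gene set."""

    gene_set_name: str
    universe_size: int
    set_size_in_universe: int
    table: pd.DataFrame  # columns: prefix_n, gene, overlap_k, p_value, rejected
    rejection_threshold: float = DEFAULT_THRESHOLD

    @property
    def min_p(self) -> float:
        return float(self.table["p_value"].min())

    @property
    def any_rejected(self) -> bool:
        return bool(self.table["rejected"].any())


def progressive_enrichment(
    ranking: Sequence[str],
    gene_set: Sequence[str],
    universe: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    gene_set_name: str = "gene_set",
) -> EnrichmentCurve:
    """Scan all prefixes of a ranked gene list against one gene set.

    The gene set is intersected with the universe before testing; the
    overlap count is maintained incrementally over prefix lengths
    1..len(ranking).  An empty intersection yields a constant p = 1
    curve with a warning.
    """
    universe_set = set(universe)
    if len(universe_set) != len(list(universe)):
        raise ValueError("universe contains duplicated genes")
    ranking = list(ranking)
    missing = [g for g in ranking if g not in universe_set]
    if missing:
        raise ValueError(f"ranked genes outside the universe: {missing[:5]}")
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains duplicated genes")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")

    members = set(gene_set) & universe_set
    N = len(universe_set)
    K = len(members)
    if K == 0:
        logger.warning(
            "gene set %r has no overlap with the universe; emitting p=1 curve",
            gene_set_name,
        )
    rows = []
    k = 0
    for n, gene in enumerate(ranking, start=1):
        if gene in members:
            k += 1
        p = hypergeom_pvalue(k, K, n, N) if K else 1.0
        rows.append((n, gene, k, p))
    table = pd.DataFrame(rows, columns=["prefix_n", "gene", "overlap_k", "p_value"])
    table["rejected"] = table["p_value"] < threshold
    table["p_bonferroni"] = (table["p_value"] * len(table)).clip(upper=1.0)
    return EnrichmentCurve(
        gene_set_name=gene_set_name,
        universe_size=N,
        set_size_in_universe=K,
        table=table,
        rejection_threshold=threshold,
    )


def enrich_collection(
    ranking: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
    universe: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, EnrichmentCurve]:
    """One enrichment curve per gene set in a collection."""
    return {
        name: progressive_enrichment(
            ranking, genes, universe, threshold=threshold, gene_set_name=name
        )
        for name, genes in gene_sets.items()
    }


def curves_to_frame(curves: dict[str, EnrichmentCurve]) -> pd.DataFrame:
    """Long-format table across gene sets, for CSV output."""
    frames = []
    for name, c in curves.items():
        t = c.table.copy()
        t.insert(0, "gene_set", name)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
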