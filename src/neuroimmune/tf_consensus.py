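"""Upstream-regulator discovery by over-representation and consensus.

Up-regulated DEGs are tested for over-representation in each
transcription factor's target set (one-sided hypergeometric test over a
declared gene universe), TFs are ranked per library by p-value (ties:
descending odds ratio, then name), and the top-k lists from several
independent regulon libraries are intersected to yield consensus hub
regulators.  Libraries use GMT semantics (TF, description, targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegulonLibrary",
    "EnrichmentResult",
    "ConsensusHubs",
    "read_gmt",
    "write_gmt",
    "enrich_tfs",
    "consensus_hubs",
]


@dataclass
class RegulonLibrary:
    """Named TF -> target-set map over an optional declared universe.

    Symbols are upper-cased for matching.
    """

    name: str
    regulons: dict[str, frozenset]
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        clean: dict[str, frozenset] = {}
        for tf, targets in self.regulons.items():
            targets = frozenset(str(g).upper() for g in targets)
            if not targets:
                raise ValueError(f"regulon {tf!r} has an empty target set")
            tf_u = str(tf).upper()
            clean[tf_u] = clean.get(tf_u, frozenset()) | targets
        self.regulons = clean
        if self.universe is not None:
            self.universe = frozenset(str(g).upper() for g in self.universe)
            for tf, targets in self.regulons.items():
                if not targets <= self.universe:
                    raise ValueError(
                        f"regulon {tf!r} has targets outside the declared universe"
                    )

    def __len__(self) -> int:
        return len(self.regulons)


def read_gmt(path) -> RegulonLibrary:
    """Read a GMT file (TF <tab> description <tab> gene1 <tab> gene2 ...)."""
    path = Path(path)
    regulons: dict[str, frozenset] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need >= 3 tab-separated fields)"
                )
            tf = fields[0].upper()
            targets = frozenset(g.upper() for g in fields[2:] if g)
            regulons[tf] = regulons.get(tf, frozenset()) | targets
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return RegulonLibrary(name=path.stem, regulons=regulons)


def write_gmt(library: RegulonLibrary, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for tf in sorted(library.regulons):
            targets = "\t".join(sorted(library.regulons[tf]))
            fh.write(f"{tf}\t{description}\t{targets}\n")


@dataclass
class EnrichmentResult:
    """Ranked per-TF over-representation table for one library."""

    library: str
    table: pd.DataFrame  # index TF; columns k, K, n, N, p, odds_ratio, rank

    def top(self, k: int) -> list[str]:
        return self.table.sort_values("rank").index[:k].tolist()


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich_tfs(query_genes, library: RegulonLibrary, universe) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of a query gene set.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the universe
    size, K the TF's in-universe target count, n the query size and k
    the observed overlap.
    """
    from scipy import stats

    universe = frozenset(str(g).upper() for g in universe)
    query = frozenset(str(g).upper() for g in query_genes)
    if not query:
        raise ValueError("empty query gene set")
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:10]}")
    N = len(universe)
    n = len(query)
    rows = []
    for tf, targets in library.regulons.items():
        in_universe = targets & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        rows.append((tf, k, K, n, N, p, _odds_ratio(k, K, n, N)))
    table = pd.DataFrame(
        rows, columns=["tf", "k", "K", "n", "N", "p", "odds_ratio"]
    ).set_index("tf")
    order = table.sort_values(
        by=["p", "odds_ratio", "tf"], ascending=[True, False, True], kind="mergesort"
    ).index
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return EnrichmentResult(library.name, table)


@dataclass
class ConsensusHubs:
    top_lists: dict[str, list]
    intersection: set = field(default_factory=set)
    top_k: int = 20


def consensus_hubs(results: list[EnrichmentResult], top_k: int = 20) -> ConsensusHubs:
    """Intersect the top-k ranked TFs across >= 2 libraries."""
    if not results:
        raise ValueError("no enrichment results supplied")
    if len(results) < 2:
        raise ValueError("consensus requires at least 2 libraries")
    top_lists = {res.library: res.top(top_k) for res in results}
    sets = [set(t) for t in top_lists.values()]
    intersection = set.intersection(*sets)
    return ConsensusHubs(top_lists=top_lists, intersection=intersection, top_k=top_k)
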