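"""Over-representation analysis of a prioritized gene list.

For each gene set, the overlap with the query list is scored by the
one-sided (upper-tail) hypergeometric test — the probability of drawing at
least the observed overlap when sampling the list size from a reference
universe containing the set — plus the enrichment ratio
(k/n) / (K/N), i.e. the overlap proportion in the list relative to the
set's share of the reference.  P-values are Benjamini-Hochberg adjusted
within each collection, since different databases (pathways vs. disease
gene sets) form separate testing families.

The reference universe size N is always an explicit input: "the whole
genome" is not a number, and the choice moves every p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import top_gene_list  # re-exported: list extraction feeds ORA

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "enrichment_ratio",
    "bh_fdr",
    "ora_test",
    "top_gene_list",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the size of the reference universe."""

    sets: dict
    reference_size: int
    name: str = ""

    def __post_init__(self):
        if self.reference_size <= 0:
            raise ValueError("reference_size must be positive")
        clean = {}
        for set_name, genes in self.sets.items():
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set '{set_name}' is empty")
            if len(genes) > self.reference_size:
                raise ValueError(f"gene set '{set_name}' larger than the reference universe")
            clean[set_name] = genes
        self.sets = clean

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.sets.values())


def read_gmt(path, reference_size: int, name: str = "") -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> gene ...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, reference_size=reference_size, name=name)


def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): over-representation of a set within a list."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    if k > min(n, K):
        raise ValueError("overlap exceeds list or set size")
    return (k / n) / (K / N)


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0 <= x <= 1) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q.tolist()


def ora_test(
    gene_list,
    collection: GeneSetCollection,
    restrict_to_universe: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of a gene list against a collection.

    Matching is case-insensitive (symbols upper-cased).  With
    ``restrict_to_universe`` genes absent from the union of the collection's
    sets are dropped (with the effective n reduced) before testing; the
    default keeps the full list as the draw, which is the conservative
    choice when the collection covers only part of the reference genome.
    The upper-tail probability at k = 0 is 1 by convention.
    """
    genes = {str(g).upper() for g in gene_list}
    if not genes:
        raise ValueError("empty gene list")
    if restrict_to_universe:
        genes = genes & collection.universe
        if not genes:
            raise ValueError("no query gene overlaps the collection universe")
    n = len(genes)
    N = collection.reference_size
    rows = []
    for set_name, members in sorted(collection.sets.items()):
        K = len(members)
        k = len(genes & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": set_name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "enrichment_ratio": enrichment_ratio(k, n, K, N),
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"])
    return out
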