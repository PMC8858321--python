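"""Hypergeometric overrepresentation of a hit list against gene sets.

For a term whose set covers K of the N universe genes, and a hit list of n
genes overlapping the set in k, the enrichment p-value is the upper tail
P(X >= k) for X ~ Hypergeometric(N, K, n). p-values are adjusted across all
tested terms by Benjamini-Hochberg. The universe defaults to the targeting
genes of the screened library — the screen can only nominate genes it
contains — rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats


class GmtParseError(ValueError):
    """Raised on malformed GMT input (includes the line number)."""


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> genes) with a free-text source tag."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise GmtParseError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes...; tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path} line {lineno}: expected term, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            term = fields[0]
            if term in sets:
                raise GmtParseError(f"{path} line {lineno}: duplicate term {term!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise GmtParseError(f"{path} line {lineno}: gene set {term!r} is empty")
            sets[term] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in collection.sets.items():
            fh.write("\t".join([term, collection.source or term] + sorted(genes)) + "\n")


def overrepresentation(
    hits,
    universe,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric upper-tail ORA of ``hits`` within ``universe``.

    Returns one row per term with k, K, n, N, p and BH-adjusted q, sorted
    by ascending p. Raises if any hit gene falls outside the universe.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hit genes outside the universe: {sorted(stray)}")
    n, N = len(hits), len(universe)

    rows = []
    for term, genes in collection.sets.items():
        K = len(genes & universe)
        k = len(genes & hits)
        # P(X >= k); sf(k-1) is exact for the discrete hypergeometric
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["q"] = stats.false_discovery_control(out["p"], method="bh") if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)
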