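"""Hypergeometric gene-set enrichment over screen hit lists.

Over-representation of each gene-set term in a hit list (e.g. the combined
short- plus long-lived strains) is scored by the hypergeometric upper tail
P(X >= k) with X ~ Hypergeometric(N, K, n), where N is the background size
(default: all strains analysed in the screen — the deletion collection's
sampling frame, not the whole genome), K the term size within the
background, n the hit-list size and k the overlap. Rows are filtered by
the triple (minimum overlap 3, p < 0.05, minimum enrichment 1.5);
Benjamini–Hochberg q-values are reported but not filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "hypergeom_enrich"]


@dataclass
class GeneSetCollection:
    """Term -> member-gene sets with optional descriptions.

    Gene identifiers are case-normalized (upper-cased) so hit lists and
    set files with inconsistent casing still intersect.
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for term, genes in self.sets.items():
            members = frozenset(g.upper() for g in genes)
            if not members:
                raise ValueError(f"term {term!r} has no members")
            norm[term] = members
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term <tab> description <tab> gene...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">= 1 gene (got {len(fields)} fields)"
                )
            term, desc, *genes = fields
            sets[term] = frozenset(g for g in genes if g)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (members sorted for stable output)."""
    with open(path, "w") as fh:
        for term in collection.sets:
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def hypergeom_enrich(
    hits,
    collection: GeneSetCollection,
    background,
    min_overlap: int = 3,
    p_cut: float = 0.05,
    min_enrich: float = 1.5,
) -> pd.DataFrame:
    """Score and filter term over-representation in a hit list.

    Parameters mirror the screen's published filter: a term is reported
    only if overlap >= ``min_overlap``, p < ``p_cut`` and enrichment
    (k/n)/(K/N) >= ``min_enrich``. Terms are intersected with the
    background before testing; hits must be a subset of the background.

    Returns a table sorted by p with columns term, description, N, K, n,
    k, enrichment, p, q (BH over all tested terms, computed before
    filtering).
    """
    bg = {g.upper() for g in background}
    if not bg:
        raise ValueError("empty background")
    hit_set = {g.upper() for g in hits}
    stray = hit_set - bg
    if stray:
        raise ValueError(f"hit genes absent from background: {sorted(stray)}")
    N, n = len(bg), len(hit_set)

    rows = []
    for term, members in collection.sets.items():
        members_bg = members & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & hit_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        enrichment = (k / n) / (K / N) if n else 0.0
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "enrichment": enrichment,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "description", "N", "K", "n", "k", "enrichment", "p"]
    )
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        return table
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    keep = (
        (table["k"] >= min_overlap)
        & (table["p"] < p_cut)
        & (table["enrichment"] >= min_enrich)
    )
    return table[keep].sort_values("p", kind="stable").reset_index(drop=True)
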