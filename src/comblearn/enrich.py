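"""Local gene-set over-representation analysis.

Hypergeometric (one-sided, upper tail) enrichment of a query gene list
against a GMT gene-set collection, with Benjamini-Hochberg correction
across tested terms.  Three constraints shape the tested universe: terms
are intersected with the gene universe before testing, terms whose
(intersected) size reaches ``max_term_size`` are excluded, and a term is
reported significant only if its adjusted p-value is below ``alpha`` AND it
covers at least ``min_coverage`` of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_MAX_TERM_SIZE = 500
DEFAULT_MIN_COVERAGE = 0.02
DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (terms)."""

    name: str
    terms: dict[str, frozenset] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: Path | str, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (term, description, member genes...).

    Duplicate genes within a term are deduplicated; malformed lines raise
    an error naming the line number.
    """
    path = Path(path)
    terms: dict[str, frozenset] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    if not any(line.strip() for line in lines):
        raise EnrichmentError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EnrichmentError(
                f"{path}:{lineno}: malformed GMT line "
                "(need term, description, >= 1 gene)")
        term = fields[0]
        if term in terms:
            raise EnrichmentError(f"{path}:{lineno}: duplicate term "
                                  f"{term!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise EnrichmentError(f"{path}:{lineno}: term {term!r} has "
                                  "no genes")
        terms[term] = genes
    return GeneSetCollection(name=name or path.stem, terms=terms)


def write_gmt(collection: GeneSetCollection, path: Path | str) -> None:
    lines = ["\t".join([term, collection.name, *sorted(genes)])
             for term, genes in collection.terms.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def hypergeometric_enrichment(query: Iterable, universe: Iterable,
                              collection: GeneSetCollection,
                              max_term_size: int = DEFAULT_MAX_TERM_SIZE,
                              min_coverage: float = DEFAULT_MIN_COVERAGE,
                              alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Over-representation of ``query`` within ``universe`` per term.

    Returns a DataFrame sorted by raw p with columns term, overlap, size,
    raw_p, adj_p, coverage, significant.  ``raw_p`` is the upper-tail
    hypergeometric probability P(overlap >= observed); ``adj_p`` is BH
    across the tested terms; ``coverage`` is overlap / |query|;
    ``significant`` requires adj_p < alpha and coverage >= min_coverage.
    Terms whose intersection with the universe has size >= max_term_size
    (or is empty) are excluded before testing.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    if not query:
        raise EnrichmentError("empty query")
    stray = query - universe
    if stray:
        raise EnrichmentError(
            f"query genes outside the universe: {sorted(stray)[:5]}...")
    M, N = len(universe), len(query)
    rows = []
    for term, genes in collection.terms.items():
        in_universe = genes & universe
        n = len(in_universe)
        if n == 0 or n >= max_term_size:
            continue
        k = len(in_universe & query)
        raw_p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append({"term": term, "overlap": k, "size": n,
                     "raw_p": min(raw_p, 1.0), "coverage": k / N})
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "size", "raw_p",
                                     "adj_p", "coverage", "significant"])
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["raw_p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["adj_p"] < alpha) & \
        (out["coverage"] >= min_coverage)
    out = out[["term", "overlap", "size", "raw_p", "adj_p", "coverage",
               "significant"]]
    return out.sort_values(["raw_p", "term"],
                           kind="mergesort").reset_index(drop=True)
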