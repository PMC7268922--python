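"""Gene-list arithmetic, hypergeometric overlap significance and
over-representation analysis with Benjamini-Hochberg control.

Two curated lists (e.g. senescence-associated genes and disease-associated
genes) are partitioned into A-only / common / B-only; the significance of
the intersection is the upper hypergeometric tail P(X >= n_overlap) given
the background universe.  Enrichment of a query list in a GMT term
collection is the one-sided Fisher exact (equivalently hypergeometric)
over-representation test per term, with BH-adjusted FDR over all tested
terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .studies import GeneSetCollection

#: default background size for overlap significance when no explicit
#: universe is supplied (approximate protein-coding gene count)
DEFAULT_UNIVERSE = 20_000


def partition_sets(a, b) -> tuple[frozenset, frozenset, frozenset]:
    """Disjoint partition (A-only, common, B-only) of two gene sets."""
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return a - b, a & b, b - a


@dataclass(frozen=True)
class OverlapResult:
    """Significance of the intersection of two gene sets."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p_overlap: float
    a_only: frozenset = frozenset()
    b_only: frozenset = frozenset()
    common: frozenset = frozenset()

    @property
    def pct_a_only(self) -> float:
        """A-only genes as a percentage of A."""
        return 100.0 * (self.n_a - self.n_overlap) / self.n_a

    def summary(self) -> str:
        return (
            f"|A|={self.n_a}, |B|={self.n_b}, overlap={self.n_overlap} "
            f"of universe {self.n_universe}; "
            f"A-only={self.n_a - self.n_overlap} ({self.pct_a_only:.2f}% "
            f"of A); P(X >= {self.n_overlap}) = {self.p_overlap:.3g}"
        )


def hypergeom_overlap(n_a: int, n_b: int, n_overlap: int,
                      n_universe: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """Upper-tail hypergeometric probability of an overlap at least this
    large between a set of size n_a and one of size n_b drawn from
    n_universe genes."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if n_a + n_b - n_overlap > n_universe:
        raise ValueError("universe smaller than the union")
    if min(n_a, n_b) < 1 or n_overlap < 0 or n_universe < 1:
        raise ValueError("counts must be positive (overlap >= 0)")
    # P(X >= n_overlap), X ~ Hypergeom(M=n_universe, n=n_a, N=n_b)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
    return OverlapResult(n_a=n_a, n_b=n_b, n_overlap=n_overlap,
                         n_universe=n_universe, p_overlap=min(p, 1.0))


def overlap_from_sets(a, b, n_universe: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """Partition two gene sets and score their intersection."""
    a_only, common, b_only = partition_sets(a, b)
    base = hypergeom_overlap(len(a), len(b), len(common), n_universe)
    return OverlapResult(
        n_a=base.n_a, n_b=base.n_b, n_overlap=base.n_overlap,
        n_universe=base.n_universe, p_overlap=base.p_overlap,
        a_only=a_only, b_only=b_only, common=common,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, idempotent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentRow:
    """Over-representation of a query in one term."""

    term: str
    description: str
    term_size: int
    overlap: int
    p: float
    fdr: float
    genes: frozenset = frozenset()


def enrich(query, terms: GeneSetCollection,
           universe=DEFAULT_UNIVERSE) -> list[EnrichmentRow]:
    """Fisher-exact over-representation of a query gene list in every term.

    ``universe`` may be a count or an explicit gene set; with a set, both
    the query and each term are intersected with it first.  Rows are sorted
    by ascending p then term label; ``fdr`` is BH-adjusted over all tested
    terms.
    """
    query = frozenset(g.upper() for g in query)
    if not query:
        raise ValueError("empty query gene list")
    if len(terms) == 0:
        raise ValueError("empty term collection")

    if isinstance(universe, (int, np.integer)):
        n_universe = int(universe)
        universe_set = None
    else:
        universe_set = frozenset(g.upper() for g in universe)
        n_universe = len(universe_set)
        query = query & universe_set
        if not query:
            raise ValueError("query disjoint from the universe")

    rows = []
    for term in sorted(terms.sets):
        members = terms.sets[term]
        if universe_set is not None:
            members = members & universe_set
        hit = len(query & members)
        # one-sided Fisher upper tail == hypergeometric P(X >= hit)
        p = float(stats.hypergeom.sf(hit - 1, n_universe, len(members),
                                     len(query))) if members else 1.0
        rows.append((term, members, hit, min(p, 1.0)))

    fdr = benjamini_hochberg([r[3] for r in rows])
    out = [
        EnrichmentRow(term=term, description=terms.descriptions.get(term, ""),
                      term_size=len(members), overlap=hit, p=p,
                      fdr=float(q), genes=frozenset(query & members))
        for (term, members, hit, p), q in zip(rows, fdr)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a DataFrame (the TSV export layout)."""
    return pd.DataFrame(
        [(r.term, r.description, r.term_size, r.overlap, r.p, r.fdr)
         for r in rows],
        columns=["term", "description", "term_size", "overlap", "p", "fdr"],
    )
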