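"""One-tailed gene-set enrichment and sliding-window enrichment curves.

A one-tailed Fisher exact test on a 2x2 table with fixed margins is exactly
the upper tail of the hypergeometric distribution; it is computed that way
here for numerical stability.  Fold enrichment is observed over expected,
with expectation ``group * category / universe``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .io_formats import GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentWindow",
    "hypergeom_enrichment",
    "sliding_window_enrichment",
    "domain_set_overlap",
]


@dataclass
class EnrichmentWindow:
    """One window of a ranked-gene enrichment curve."""

    window_index: int
    rank_range: tuple[int, int]
    gene_ids: list[str] = field(repr=False, default_factory=list)
    observed: int = 0
    expected: float = 0.0
    fold: float = 0.0
    p_value: float = 1.0


def hypergeom_enrichment(
    observed: int, group_size: int, category_size: int, universe_size: int
) -> tuple[float, float]:
    """Fold enrichment and one-tailed (upper) hypergeometric p value.

    ``p = P(X >= observed)`` for X hypergeometric with population
    ``universe_size``, ``category_size`` successes and ``group_size`` draws;
    identical to a one-tailed Fisher exact test on the 2x2 table.
    """
    if not 0 <= observed <= min(group_size, category_size):
        raise ValueError("observed must lie in [0, min(group, category)]")
    if max(group_size, category_size) > universe_size:
        raise ValueError("group and category must fit in the universe")
    expected = group_size * category_size / universe_size
    if expected == 0:
        raise ZeroDivisionError("expected count is 0; fold undefined")
    fold = observed / expected
    p = float(hypergeom.sf(observed - 1, universe_size, category_size, group_size))
    return fold, p


def sliding_window_enrichment(
    ranked_gene_ids: list[str],
    category: GeneSet,
    universe: GeneSet,
    window: int = 1500,
    shared: int = 500,
) -> list[EnrichmentWindow]:
    """Score overlapping fixed-size windows along a gene ranking.

    Windows of ``window`` genes start every ``window - shared`` ranks, so
    consecutive windows share ``shared`` genes; a trailing partial window is
    dropped.  Genes absent from the universe are dropped from the ranking
    with a warning.  Each window is scored against the full universe.
    """
    if not window > shared >= 0:
        raise ValueError("require window > shared >= 0")
    ranked = [g for g in ranked_gene_ids if g in universe]
    n_dropped = len(ranked_gene_ids) - len(ranked)
    if n_dropped:
        log.warning("dropped %d ranked genes not in the universe", n_dropped)
    if window > len(ranked):
        raise ValueError(
            f"window ({window}) exceeds the {len(ranked)}-gene ranking; "
            "use a single window no larger than the ranking"
        )
    cat = category.gene_ids & universe.gene_ids
    step = window - shared
    out: list[EnrichmentWindow] = []
    for wi, start in enumerate(range(0, len(ranked) - window + 1, step)):
        ids = ranked[start : start + window]
        obs = sum(1 for g in ids if g in cat)
        fold, p = hypergeom_enrichment(obs, window, len(cat), len(universe))
        out.append(
            EnrichmentWindow(
                window_index=wi,
                rank_range=(start, start + window),
                gene_ids=ids,
                observed=obs,
                expected=window * len(cat) / len(universe),
                fold=fold,
                p_value=p,
            )
        )
    return out


def domain_set_overlap(domains_a, domains_b) -> tuple[int, int]:
    """Count domains in each set that overlap (>= 1 bp) the other set.

    Inputs are ``(chrom, start, end)`` triples; returns ``(n_a_hit,
    n_b_hit)``.  Used e.g. to compare BGRDs against other broad-domain
    catalogs such as LOCKs.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in domains_b:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    n_a_hit = sum(
        1
        for chrom, s, e in domains_a
        if chrom in trees and trees[chrom].overlap(s, e)
    )
    trees_a: dict[str, IntervalTree] = {}
    for chrom, s, e in domains_a:
        trees_a.setdefault(chrom, IntervalTree()).addi(s, e)
    n_b_hit = sum(
        1
        for chrom, s, e in domains_b
        if chrom in trees_a and trees_a[chrom].overlap(s, e)
    )
    return n_a_hit, n_b_hit
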