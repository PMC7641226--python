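"""Filter cascade nominating putative tumor-promoting genes and lncRNAs.

Starting from a reference panel of normal samples, a gene is a candidate in
a given cancer sample when it (1) carries a BGRD in at least
``min_panel_count`` panel samples, (2) has no known driver mutation signal
(mutation Q value absent or above an aggressive cutoff), (3) is expressed
above the median of all genes in the cancer sample, and (4) has its
H3K27me3 width shortened to at most ``1 - shrink_frac`` of the panel mean
width (candidate lncRNAs additionally require an absolute shrink in bp and
skip the mutation filter).  Lengthened controls mirror the cascade with a
widening requirement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel
from .multi_sample import WidthMatrix

__all__ = [
    "CandidateCall",
    "candidate_genes",
    "candidate_lncrnas",
    "lengthened_controls",
]


@dataclass
class CandidateCall:
    """A gene with its filter-cascade evidence for tumor-promoting status."""

    gene_id: str
    biotype: str
    panel_bgrd_count: int
    panel_mean_width: float
    sample_width: float
    expression: float
    mutation_q: float | None
    recurrent_bgrd: bool
    not_mut_driver: bool
    expressed: bool
    shortened: bool  # widening flag in lengthened-control mode

    @property
    def is_candidate(self) -> bool:
        return (
            self.recurrent_bgrd
            and self.not_mut_driver
            and self.expressed
            and self.shortened
        )


def _median(values) -> float:
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


def _cascade(
    panel: WidthMatrix,
    sample_widths: dict[str, float],
    expression: dict[str, float],
    mutation_q: dict[str, float] | None,
    min_panel_count: int,
    q_cutoff: float | None,
    width_flag,
    biotypes: dict[str, str] | None,
    restrict_biotype: str | None,
) -> list[CandidateCall]:
    if not expression:
        raise ValueError("expression table is empty")
    if panel.bgrd_mask is None:
        raise ValueError("panel has no BGRD mask")
    expr_median = _median(expression.values())
    counts = panel.bgrd_mask.sum(axis=1)
    # panel mean width averages over ALL panel samples, zeros included
    mean_w = panel.widths.mean(axis=1)
    out = []
    for gid in panel.gene_ids:
        biotype = (biotypes or {}).get(gid, "coding")
        if restrict_biotype is not None and biotype != restrict_biotype:
            continue
        q = (mutation_q or {}).get(gid)
        not_driver = True if q_cutoff is None else (q is None or q >= q_cutoff)
        expr = expression.get(gid, float("-inf"))
        sw = float(sample_widths.get(gid, 0.0))
        pm = float(mean_w[gid])
        out.append(
            CandidateCall(
                gene_id=gid,
                biotype=biotype,
                panel_bgrd_count=int(counts[gid]),
                panel_mean_width=pm,
                sample_width=sw,
                expression=expr if expr != float("-inf") else float("nan"),
                mutation_q=q,
                recurrent_bgrd=int(counts[gid]) >= min_panel_count,
                not_mut_driver=not_driver,
                expressed=expr > expr_median,
                shortened=width_flag(sw, pm),
            )
        )
    return out


def candidate_genes(
    panel: WidthMatrix,
    sample_widths: dict[str, float],
    expression: dict[str, float],
    mutation_q: dict[str, float] | None = None,
    min_panel_count: int = 2,
    q_cutoff: float = 0.5,
    shrink_frac: float = 0.5,
) -> list[CandidateCall]:
    """Putative tumor-promoting genes with shortened BGRDs in one cancer
    sample.

    The shortening flag requires ``sample_width <= (1 - shrink_frac) *
    panel_mean_width`` (inclusive); genes absent from the mutation table are
    treated as non-drivers (no evidence of a driver mutation).
    """

    def flag(sw: float, pm: float) -> bool:
        return pm > 0 and sw <= (1 - shrink_frac) * pm

    return _cascade(
        panel, sample_widths, expression, mutation_q,
        min_panel_count, q_cutoff, flag, None, None,
    )


def candidate_lncrnas(
    panel: WidthMatrix,
    sample_widths: dict[str, float],
    expression: dict[str, float],
    biotypes: dict[str, str] | list[GeneModel] | None = None,
    min_panel_count: int = 2,
    shrink_frac: float = 0.5,
    min_shrink_bp: float = 20000.0,
) -> list[CandidateCall]:
    """Putative tumor-promoting lncRNAs: as :func:`candidate_genes` but
    restricted to lncRNAs, without the mutation filter, and with the
    shortening required to be both 50% (``shrink_frac``) and at least
    ``min_shrink_bp`` in absolute width (both inclusive)."""
    if isinstance(biotypes, list):
        biotypes = {g.gene_id: g.biotype for g in biotypes}

    def flag(sw: float, pm: float) -> bool:
        return pm > 0 and sw <= (1 - shrink_frac) * pm and pm - sw >= min_shrink_bp

    return _cascade(
        panel, sample_widths, expression, None,
        min_panel_count, None, flag, biotypes, "lncRNA",
    )


def lengthened_controls(
    panel: WidthMatrix,
    sample_widths: dict[str, float],
    expression: dict[str, float],
    mutation_q: dict[str, float] | None = None,
    min_panel_count: int = 2,
    q_cutoff: float = 0.5,
    grow_frac: float = 0.5,
) -> list[CandidateCall]:
    """Mirror cascade for lengthened domains: ``sample_width >= (1 +
    grow_frac) * panel_mean_width`` (inclusive), all other filters as in
    :func:`candidate_genes`.  Disjoint from the shortened candidates for any
    input since a width cannot be both <= half and >= 1.5x a positive mean."""

    def flag(sw: float, pm: float) -> bool:
        return pm > 0 and sw >= (1 + grow_frac) * pm

    return _cascade(
        panel, sample_widths, expression, mutation_q,
        min_panel_count, q_cutoff, flag, None, None,
    )
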