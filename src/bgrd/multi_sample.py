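"""Genes x samples width matrices, quantile normalization, conservation and
optimal reference-panel selection.

A gene's conservation level is the fraction of samples in which it carries a
BGRD, under either the per-sample top-N rule (default, N=500) or an absolute
width cutoff.  Widths are quantile-normalized to a chosen reference sample so
width distributions are comparable across samples of different depth.  The
reference-panel selector ranks samples by the oncogene-enrichment p value of
their BGRD set and grows a cumulative union, keeping the panel size that
minimizes the union's p value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .domain_calling import GeneDomainStats
from .enrichment import hypergeom_enrichment
from .io_formats import GeneSet

__all__ = [
    "BgrdRule",
    "WidthMatrix",
    "PanelSelection",
    "build_width_matrix",
    "quantile_normalize_to_reference",
    "conservation_vs_width",
    "forward_dataset_selection",
]


@dataclass(frozen=True)
class BgrdRule:
    """Per-sample BGRD membership rule: ``top_n`` genes by width, or an
    absolute width ``cutoff`` in bp (set exactly one)."""

    top_n: int | None = None
    cutoff: float | None = None

    def __post_init__(self):
        if (self.top_n is None) == (self.cutoff is None):
            raise ValueError("set exactly one of top_n / cutoff")

    def mask(self, widths: pd.Series) -> pd.Series:
        if self.cutoff is not None:
            return widths >= self.cutoff
        order = widths.sort_values(
            ascending=False, kind="stable"
        )  # ties: gene_id order via stable sort on the index-sorted frame
        top = set(order.index[: self.top_n])
        return pd.Series(widths.index.isin(top), index=widths.index)


@dataclass
class WidthMatrix:
    """BGRD widths of genes (rows) across samples (columns)."""

    widths: pd.DataFrame  # genes x samples, bp
    labels: dict[str, str] = field(default_factory=dict)  # sample -> normal/cancer
    bgrd_mask: pd.DataFrame | None = None  # genes x samples, bool

    @property
    def gene_ids(self) -> list[str]:
        return list(self.widths.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.widths.columns)

    @property
    def conservation(self) -> pd.Series:
        """Per-gene fraction of samples with a BGRD at the gene."""
        if self.bgrd_mask is None:
            raise ValueError("bgrd_mask not computed")
        return self.bgrd_mask.mean(axis=1)

    @property
    def max_width(self) -> pd.Series:
        return self.widths.max(axis=1)

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == label]


def build_width_matrix(
    per_sample_stats: dict[str, list[GeneDomainStats]],
    bgrd_rule: BgrdRule = BgrdRule(top_n=500),
    labels: dict[str, str] | None = None,
) -> WidthMatrix:
    """Assemble the genes x samples width matrix and per-sample BGRD masks.

    All samples must share the gene universe; the membership rule is applied
    within each sample independently.
    """
    samples = sorted(per_sample_stats)
    universe = sorted(s.gene_id for s in per_sample_stats[samples[0]])
    cols = {}
    for sample in samples:
        ids = sorted(s.gene_id for s in per_sample_stats[sample])
        if ids != universe:
            missing = set(universe).symmetric_difference(ids)
            raise ValueError(
                f"sample {sample} gene universe differs; e.g. {sorted(missing)[:5]}"
            )
        cols[sample] = pd.Series(
            {s.gene_id: float(s.width_sum) for s in per_sample_stats[sample]}
        )
    widths = pd.DataFrame(cols).loc[universe, samples]
    mask = pd.DataFrame({s: bgrd_rule.mask(widths[s]) for s in samples})
    return WidthMatrix(widths=widths, labels=dict(labels or {}), bgrd_mask=mask)


def quantile_normalize_to_reference(
    matrix: WidthMatrix, reference_sample: str
) -> WidthMatrix:
    """Map every sample's widths onto the reference sample's distribution.

    The value at rank r in a sample is replaced by the reference's order
    statistic at rank r; tied values receive the mean of the reference order
    statistics their ranks span.  The reference column is unchanged, and
    within-sample ranking is preserved.
    """
    if reference_sample not in matrix.widths.columns:
        raise KeyError(f"reference sample {reference_sample!r} not in matrix")
    ref = matrix.widths[reference_sample].to_numpy(dtype=float)
    if not ref.any():
        raise ValueError("reference column is all zero; cannot normalize to it")
    ref_sorted = np.sort(ref)
    out = {}
    for sample in matrix.widths.columns:
        if sample == reference_sample:
            out[sample] = matrix.widths[sample].copy()
            continue
        x = matrix.widths[sample].to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        mapped = np.empty_like(ref_sorted)
        mapped[order] = ref_sorted
        # average the mapped values over ties in x
        s = pd.Series(mapped)
        mapped = s.groupby(x).transform("mean").to_numpy()
        out[sample] = pd.Series(mapped, index=matrix.widths.index)
    widths = pd.DataFrame(out)[matrix.widths.columns]
    return WidthMatrix(widths=widths, labels=dict(matrix.labels), bgrd_mask=matrix.bgrd_mask)


def conservation_vs_width(matrix: WidthMatrix):
    """Per-gene (conservation, max width) and their Spearman correlation.

    Returns ``(conservation, max_width, rho)``; ``rho`` is nan (flagged) when
    either vector is constant.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    cons = matrix.conservation
    mw = matrix.max_width
    if cons.nunique() < 2 or mw.nunique() < 2:
        return cons, mw, float("nan")
    rho = float(spearmanr(cons.to_numpy(), mw.to_numpy()).statistic)
    return cons, mw, rho


@dataclass
class PanelSelection:
    """Samples ranked by BGRD-set enrichment p, with the cumulative-union
    p curve and the chosen panel size."""

    ranked_sample_ids: list[str]
    sample_p: list[float]
    p_curve: list[float]  # p_curve[k-1] = union-of-top-k enrichment p
    chosen_k: int

    @property
    def panel(self) -> list[str]:
        return self.ranked_sample_ids[: self.chosen_k]


def forward_dataset_selection(
    per_sample_bgrd_sets: dict[str, GeneSet],
    category: GeneSet,
    universe: GeneSet,
    stop_rule: str = "argmin",
) -> PanelSelection:
    """Choose the sample panel whose combined BGRD gene list is most enriched.

    Samples are ranked by the enrichment p of their own BGRD set (ascending,
    ties by sample id); the union over the top-k sets is scored for every k.
    ``stop_rule='argmin'`` keeps the global minimum of the union p curve
    (ties toward smaller k); ``stop_rule='threshold'`` keeps the last k
    before the union p first exceeds the k=1 p.
    """
    if not per_sample_bgrd_sets:
        raise ValueError("no samples")
    if not category.gene_ids & universe.gene_ids:
        raise ValueError("category is empty within the universe")
    n_univ, n_cat = len(universe), len(category.gene_ids & universe.gene_ids)

    def score(ids: set[str]) -> float:
        ids = ids & universe.gene_ids
        obs = len(ids & category.gene_ids)
        if not ids:
            return 1.0
        return hypergeom_enrichment(obs, len(ids), n_cat, n_univ)[1]

    sample_p = {
        s: score(gs.gene_ids) for s, gs in per_sample_bgrd_sets.items()
    }
    ranked = sorted(sample_p, key=lambda s: (sample_p[s], s))
    p_curve: list[float] = []
    union: set[str] = set()
    for s in ranked:
        union |= per_sample_bgrd_sets[s].gene_ids
        p_curve.append(score(union))
    if stop_rule == "argmin":
        chosen_k = int(np.argmin(p_curve)) + 1
    elif stop_rule == "threshold":
        chosen_k = len(ranked)
        for k in range(2, len(ranked) + 1):
            if p_curve[k - 1] > p_curve[0]:
                chosen_k = k - 1
                break
    else:
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    return PanelSelection(
        ranked_sample_ids=ranked,
        sample_p=[sample_p[s] for s in ranked],
        p_curve=p_curve,
        chosen_k=chosen_k,
    )
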