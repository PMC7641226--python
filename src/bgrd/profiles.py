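"""Strand-aware signal profiles, Pol II pausing index and H3K27me3 PTB ratio.

Profiles are oriented so that positive offsets always point into the gene
body: the TSS is ``start`` on the + strand and ``end`` on the - strand, and
minus-strand rows are reversed.  The pausing index is the promoter
([TSS-30, TSS+300)) to body ([TSS+300, TTS)) ratio of summed Pol II signal;
the H3K27me3 promoter-to-body (PTB) ratio uses the broader +/-3 kb promoter
window.  Both use sums of per-bp read density; the eligibility filter uses
mean densities with a strict floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, SignalTrack

log = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "PausingStats",
    "tss_profile",
    "scaled_body_profile",
    "pausing_index",
    "ptb_ratio",
    "compute_pausing_stats",
    "eligibility_filter",
    "rank_slices",
    "motif_track",
    "motif_fold_enrichment",
]

PAUSING_PROMOTER = (-30, 300)  # bp around TSS for the Pol II pausing index
PTB_PROMOTER = (-3000, 3000)  # bp around TSS for the H3K27me3 PTB ratio


@dataclass
class ProfileMatrix:
    """Genes x positions signal matrix with TSS-relative offsets."""

    gene_ids: list[str]
    positions: np.ndarray  # bp offset of each column (bin start)
    values: np.ndarray  # shape (n_genes, n_positions)

    @property
    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class PausingStats:
    gene_id: str
    pol2_pausing_index: float  # nan if undefined (body sum 0)
    k27_ptb_ratio: float
    eligible: bool = False


def _oriented_window(track: SignalTrack, gene: GeneModel, rel_start: int, rel_end: int):
    """Per-step values over [TSS+rel_start, TSS+rel_end), strand-oriented.

    Offsets are in transcript direction; on the minus strand the genomic
    window is mirrored and the values reversed.
    """
    if gene.strand == "+":
        return track.at(gene.chrom, gene.tss + rel_start, gene.tss + rel_end)
    return track.at(gene.chrom, gene.tss - rel_end, gene.tss - rel_start)[::-1]


def tss_profile(
    track: SignalTrack, genes: list[GeneModel], flank: int = 10000, bin: int = 100
) -> ProfileMatrix:
    """Average signal in fixed bins around the TSS, strand-oriented.

    Columns run from ``-flank`` to ``+flank`` in ``bin`` bp bins; positions
    beyond chromosome bounds contribute 0.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if bin < track.step or bin % track.step:
        raise ValueError("bin must be a multiple of the track step")
    n_bins = 2 * flank // bin
    per_bin = bin // track.step
    rows = np.zeros((len(genes), n_bins))
    for i, g in enumerate(genes):
        vals = _oriented_window(track, g, -flank, flank)
        rows[i] = vals.reshape(n_bins, per_bin).mean(axis=1)
    positions = np.arange(-flank, flank, bin)
    return ProfileMatrix([g.gene_id for g in genes], positions, rows)


def scaled_body_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    n_body_bins: int = 100,
    flank: int = 0,
    flank_bin: int = 100,
) -> ProfileMatrix:
    """Gene bodies resampled to ``n_body_bins`` equal fractions.

    Each body bin holds the mean signal over its fraction of the gene, so
    genes of different lengths align; optional fixed-bp flank bins surround
    the body.  Genes too short to fill the bins at the track step are
    skipped with a warning.
    """
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    n_flank_bins = flank // flank_bin if flank else 0
    kept_ids, kept_rows = [], []
    for g in genes:
        if g.length < n_body_bins * track.step:
            log.warning("gene %s (%d bp) too short for %d body bins; skipped",
                        g.gene_id, g.length, n_body_bins)
            continue
        body = _oriented_window(track, g, 0, (g.length // track.step) * track.step)
        # mean within each equal fraction of the body
        edges = np.linspace(0, len(body), n_body_bins + 1).astype(int)
        body_bins = np.array(
            [body[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        )
        if n_flank_bins:
            per = flank_bin // track.step
            up = _oriented_window(track, g, -flank, 0)
            dn = _oriented_window(track, g, g.length, g.length + flank)
            up_bins = up.reshape(n_flank_bins, per).mean(axis=1)
            dn_bins = dn.reshape(n_flank_bins, per).mean(axis=1)
            row = np.concatenate([up_bins, body_bins, dn_bins])
        else:
            row = body_bins
        kept_ids.append(g.gene_id)
        kept_rows.append(row)
    n_cols = n_body_bins + 2 * n_flank_bins
    values = np.array(kept_rows) if kept_rows else np.zeros((0, n_cols))
    positions = np.arange(n_cols) - n_flank_bins  # body bins start at 0
    return ProfileMatrix(kept_ids, positions, values)


def _window_sum(track: SignalTrack, gene: GeneModel, rel_start: int, rel_end: int) -> float:
    """Sum of per-bp read density over a strand-oriented window.

    Track values are per-bp densities sampled at the track step, so each
    stored value stands for ``step`` base pairs.
    """
    return float(_oriented_window(track, gene, rel_start, rel_end).sum()) * track.step


def pausing_index(pol2: SignalTrack, gene: GeneModel) -> float:
    """Pol II pausing index: promoter / body summed signal; nan if body is 0."""
    if gene.length <= PAUSING_PROMOTER[1]:
        raise ValueError(f"gene {gene.gene_id} shorter than the promoter window")
    prom = _window_sum(pol2, gene, *PAUSING_PROMOTER)
    body = _window_sum(pol2, gene, PAUSING_PROMOTER[1], gene.length)
    return prom / body if body > 0 else float("nan")


def ptb_ratio(k27: SignalTrack, gene: GeneModel) -> float:
    """H3K27me3 promoter-to-body ratio with the +/-3 kb promoter window."""
    if gene.length <= PTB_PROMOTER[1]:
        raise ValueError(f"gene {gene.gene_id} shorter than the 3 kb promoter window")
    prom = _window_sum(k27, gene, *PTB_PROMOTER)
    body = _window_sum(k27, gene, PTB_PROMOTER[1], gene.length)
    return prom / body if body > 0 else float("nan")


def compute_pausing_stats(
    pol2: SignalTrack,
    k27: SignalTrack,
    genes: list[GeneModel],
    density_floor: float = 0.01,
) -> list[PausingStats]:
    """Pausing index and PTB ratio per gene, with the eligibility flag.

    Eligible genes have mean Pol II density strictly above ``density_floor``
    in both the promoter and body windows.
    """
    out = []
    for g in genes:
        if g.length <= PTB_PROMOTER[1]:
            continue
        prom_vals = _oriented_window(pol2, g, *PAUSING_PROMOTER)
        body_vals = _oriented_window(pol2, g, PAUSING_PROMOTER[1], g.length)
        eligible = (
            prom_vals.mean() > density_floor and body_vals.mean() > density_floor
        )
        out.append(
            PausingStats(
                gene_id=g.gene_id,
                pol2_pausing_index=pausing_index(pol2, g),
                k27_ptb_ratio=ptb_ratio(k27, g),
                eligible=bool(eligible),
            )
        )
    return out


def eligibility_filter(
    stats: list[PausingStats], density_floor: float | None = None
) -> list[PausingStats]:
    """Keep genes flagged eligible (detectable Pol II in promoter and body).

    The flag is computed by :func:`compute_pausing_stats`; ``density_floor``
    is accepted for signature symmetry but the flag already encodes it.
    """
    return [s for s in stats if s.eligible]


def rank_slices(values: dict[str, float], slice_size: int = 1000) -> dict[str, list[str]]:
    """Top / median / bottom ``slice_size`` gene ids by value.

    The median slice is centered on the middle of the ranking.  Ties break by
    gene id for determinism.
    """
    ranked = sorted(values, key=lambda g: (-values[g], g))
    n = len(ranked)
    if slice_size > n:
        raise ValueError("slice_size exceeds the number of genes")
    mid = (n - slice_size) // 2
    return {
        "top": ranked[:slice_size],
        "median": ranked[mid : mid + slice_size],
        "bottom": ranked[-slice_size:],
    }


def motif_track(
    occurrences, chrom_lengths: dict[str, int], step: int = 1
) -> SignalTrack:
    """Binary per-bp track: 1 where >= 1 motif occurrence covers the base.

    With ``step > 1`` a bin is 1 if any base in it is covered.  Overlapping
    occurrences do not double count.
    """
    values = {
        chrom: np.zeros(-(-length // step)) for chrom, length in chrom_lengths.items()
    }
    for chrom, s, e in occurrences:
        if chrom in values:
            arr = values[chrom]
            arr[max(s // step, 0) : min(-(-e // step), len(arr))] = 1.0
    return SignalTrack(values=values, step=step)


def motif_fold_enrichment(
    motif: SignalTrack,
    bgrd_genes: list[GeneModel],
    control_genes: list[GeneModel],
    n_body_bins: int = 100,
    flank: int = 0,
) -> float:
    """Mean scaled-body motif density in BGRD genes over control genes."""
    if not bgrd_genes or not control_genes:
        raise ValueError("both gene groups must be nonempty")
    num = scaled_body_profile(motif, bgrd_genes, n_body_bins, flank).values.mean()
    den = scaled_body_profile(motif, control_genes, n_body_bins, flank).values.mean()
    if den == 0:
        raise ZeroDivisionError("control group has zero motif density; fold undefined")
    return float(num / den)
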