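"""Per-gene repression-domain statistics and BGRD/FGRD classification.

A gene's repression-domain width is the summed width of every H3K27me3 peak
overlapping it (full peak widths by default, overlap-clipped on request), and
its height is the tallest overlapping peak.  Broad genic repression domains
(BGRDs) are the top-``n_top`` genes by total width, subject to a cutoff
derived from the turning point (knee) of the sorted width curve; focal
domains (FGRDs) are the top-``n_top`` by peak height.  Gene groups a1/a2/b/c
partition the universe by domain status, length and H3K27me3 coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import gaussian_kde

from .io_formats import GeneModel, GeneSet, Peak, SignalTrack

__all__ = [
    "GeneDomainStats",
    "TurningPoint",
    "DegenerateCurveError",
    "NoBoundaryError",
    "compute_gene_peak_stats",
    "find_turning_point",
    "classify_domains",
    "coverage_boundary",
    "assign_gene_groups",
    "intron_fraction",
    "call_peaks_from_signal",
]


@dataclass
class GeneDomainStats:
    """Per-gene aggregate of overlapping repression peaks."""

    gene_id: str
    width_sum: int = 0
    height_max: float = 0.0
    coverage: float = 0.0
    domain_class: str = "none"  # {BGRD, FGRD, none}
    group: str = "unassigned"  # {a1, a2, b, c, unassigned}


@dataclass(frozen=True)
class TurningPoint:
    """The knee of the sorted width curve and the cutoff derived from it.

    ``cutoff = multiplier * width_at_turn``; the default multiplier of 2
    reproduces e.g. a 121 kb cutoff from a 60.5 kb turning-point width.
    """

    rank_index: int
    width_at_turn: float
    multiplier: float = 2.0

    @property
    def cutoff(self) -> float:
        return self.multiplier * self.width_at_turn

    @classmethod
    def from_width(cls, width_at_turn: float, multiplier: float = 2.0) -> "TurningPoint":
        return cls(rank_index=0, width_at_turn=width_at_turn, multiplier=multiplier)


class DegenerateCurveError(ValueError):
    """All values equal: the curve has no L shape and no knee."""


class NoBoundaryError(ValueError):
    """The coverage density is unimodal; no valley between two modes."""

    def __init__(self, mode: float):
        super().__init__(f"coverage density is unimodal (single mode at {mode:.4g})")
        self.mode = mode


def compute_gene_peak_stats(
    genes: list[GeneModel], peaks: list[Peak], clip: bool = False
) -> list[GeneDomainStats]:
    """Aggregate overlapping peaks per gene.

    Overlap is strand-blind and requires >= 1 bp.  With ``clip=False`` the
    full width of every overlapping peak is summed (a peak spanning beyond the
    gene still contributes its whole width); with ``clip=True`` only the
    overlapping portions count.  Genes without peaks get width 0, height 0.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    out = []
    for g in genes:
        width_sum, height_max = 0, 0.0
        tree = trees.get(g.chrom)
        if tree is not None:
            for iv in tree.overlap(g.start, g.end):
                p: Peak = iv.data
                if clip:
                    width_sum += min(p.end, g.end) - max(p.start, g.start)
                else:
                    width_sum += p.width
                height_max = max(height_max, p.height)
        out.append(
            GeneDomainStats(
                gene_id=g.gene_id,
                width_sum=width_sum,
                height_max=height_max,
                coverage=width_sum / g.length,
            )
        )
    return out


def find_turning_point(values, multiplier: float = 2.0) -> TurningPoint:
    """Locate the knee of the sorted (ascending) value curve.

    The curve plots value against rank; both axes are affinely rescaled to
    [0, n-1] and the turning point is the curve point closest (Euclidean) to
    the bottom-right corner (n-1, 0).  Ties break toward the larger rank
    (broader width).  The returned cutoff is ``multiplier`` times the value at
    the turning point, on the original scale.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 3:
        raise ValueError(f"need >= 3 values for a turning point, got {n}")
    vmin, vmax = v[0], v[-1]
    if vmax == vmin:
        raise DegenerateCurveError("all values are equal; the curve has no knee")
    x = np.arange(n, dtype=float)
    y = (v - vmin) / (vmax - vmin) * (n - 1)
    d2 = (n - 1 - x) ** 2 + y**2
    # ties toward larger rank
    idx = n - 1 - int(np.argmin(d2[::-1]))
    return TurningPoint(rank_index=idx, width_at_turn=float(v[idx]), multiplier=multiplier)


def classify_domains(
    stats: list[GeneDomainStats],
    turning: TurningPoint,
    n_top: int = 500,
    seed: int = 1,
) -> tuple[list[GeneDomainStats], GeneSet]:
    """Label BGRD / FGRD genes and draw a random control set.

    BGRD: the ``n_top`` genes with the largest total width that also satisfy
    ``width_sum >= turning.cutoff`` (fewer than ``n_top`` if the cutoff
    bites).  FGRD: the ``n_top`` genes with the largest peak height, excluding
    genes already labeled BGRD.  The control set draws ``n_top`` genes
    uniformly without replacement from the remainder.  Ranking ties break by
    gene_id so the call is deterministic.
    """
    if not stats:
        raise ValueError("stats is empty")
    if n_top > len(stats):
        raise ValueError(f"n_top={n_top} exceeds {len(stats)} genes")
    stats = [replace(s, domain_class="none") for s in stats]
    by_width = sorted(stats, key=lambda s: (-s.width_sum, s.gene_id))
    bgrd_ids = {
        s.gene_id for s in by_width[:n_top] if s.width_sum >= turning.cutoff
    }
    by_height = sorted(stats, key=lambda s: (-s.height_max, s.gene_id))
    fgrd_ids: set[str] = set()
    for s in by_height:
        if len(fgrd_ids) == n_top:
            break
        if s.gene_id not in bgrd_ids:
            fgrd_ids.add(s.gene_id)
    for s in stats:
        if s.gene_id in bgrd_ids:
            s.domain_class = "BGRD"
        elif s.gene_id in fgrd_ids:
            s.domain_class = "FGRD"
    remainder = sorted(
        s.gene_id for s in stats if s.gene_id not in bgrd_ids | fgrd_ids
    )
    rng = np.random.default_rng(seed)
    k = min(n_top, len(remainder))
    control = set(rng.choice(remainder, size=k, replace=False)) if k else set()
    return stats, GeneSet(name="random_control", gene_ids=control)


def coverage_boundary(coverages, grid_size: int = 512) -> float:
    """Valley of the bimodal coverage density.

    Builds a Gaussian KDE (Silverman bandwidth) over the positive coverage
    values and returns the location of the minimum density between the two
    highest local maxima.  Raises :class:`NoBoundaryError` if the density is
    unimodal.
    """
    cov = np.asarray([c for c in coverages if c > 0], dtype=float)
    if len(np.unique(cov)) < 2:
        raise NoBoundaryError(float(cov[0]) if len(cov) else float("nan"))
    kde = gaussian_kde(cov, bw_method="silverman")
    lo, hi = cov.min(), cov.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if len(interior) < 2:
        mode = float(grid[int(np.argmax(dens))])
        raise NoBoundaryError(mode)
    top2 = interior[np.argsort(dens[interior])][-2:]
    i, j = int(min(top2)), int(max(top2))
    valley = i + int(np.argmin(dens[i : j + 1]))
    return float(grid[valley])


def assign_gene_groups(
    stats: list[GeneDomainStats],
    genes: list[GeneModel],
    bgrd_ids: GeneSet,
    boundary: float,
) -> list[GeneDomainStats]:
    """Partition genes into groups a1/a2/b/c.

    a1 = BGRD genes; the minimal gene length among them, L*, splits the rest:
    a2 = length >= L* and coverage >= boundary; b = length >= L* and coverage
    below the boundary; c = length < L*.  The four groups partition the
    universe.
    """
    if not bgrd_ids.gene_ids:
        raise ValueError("bgrd_ids is empty")
    lengths = {g.gene_id: g.length for g in genes}
    missing = bgrd_ids.gene_ids - set(lengths)
    if missing:
        raise ValueError(f"BGRD ids missing from gene list: {sorted(missing)[:5]}")
    l_star = min(lengths[gid] for gid in bgrd_ids.gene_ids)
    for s in stats:
        if s.gene_id in bgrd_ids:
            s.group = "a1"
        elif lengths[s.gene_id] < l_star:
            s.group = "c"
        elif s.coverage >= boundary:
            s.group = "a2"
        else:
            s.group = "b"
    return stats


def intron_fraction(gene: GeneModel) -> float:
    """Fraction of the gene that is intronic: 1 - exon bp / gene length."""
    if gene.exons is None or not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exon structure")
    exon_total = sum(e - s for s, e in gene.exons)
    return 1.0 - exon_total / gene.length


def call_peaks_from_signal(
    track: SignalTrack,
    threshold: float,
    min_width: int = 0,
    merge_gap: int = 0,
) -> list[Peak]:
    """Threshold a signal track into peaks.

    Maximal runs of signal >= threshold become peaks; runs separated by less
    than ``merge_gap`` bp merge; merged runs narrower than ``min_width`` are
    dropped.  Height is the maximum signal inside the (merged) run.  This is
    deliberately simple plumbing for synthetic tracks, not a statistical
    peak caller.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks: list[Peak] = []
    step = track.step
    for chrom in sorted(track.values):
        arr = track.values[chrom]
        above = arr >= threshold
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(arr))
        runs = [[s * step, e * step] for s, e in zip(starts, ends)]
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= max(min_width, step):
                height = float(arr[s // step : e // step].max())
                peaks.append(Peak(chrom, s, e, height))
    return peaks
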