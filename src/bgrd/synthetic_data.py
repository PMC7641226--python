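"""Synthetic genomes, peak sets, signal tracks, sample panels and
cancer/normal cohorts with planted structure.

The generator emulates the statistical features the analysis relies on: gene
lengths with a log-normal spread; a minority of (long) genes carrying broad
promoter-plus-body repression domains built as peak tilings (BGRD-like); a
minority carrying a single tall narrow promoter peak (FGRD-like); short
background noise peaks; multi-sample panels sharing a conserved planted core;
cancer/normal cohorts in which a planted subset of core domains is shortened
and a few genes gain new domains; and expression negatively coupled to
repression coverage.  Every planted truth set is returned alongside the data,
and identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel, GeneSet, Peak, SignalTrack

__all__ = [
    "SyntheticSpec",
    "make_genome",
    "choose_planted",
    "make_sample",
    "make_panel",
    "make_cancer_cohort",
    "make_expression",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study; defaults size a full pipeline run
    to well under a minute."""

    seed: int = 1
    # genome
    n_genes: int = 2000
    chrom: str = "chr1"
    chrom_length: int = 300_000_000
    track_step: int = 100
    gene_len_mu: float = math.log(20_000)  # log-normal location (median 20 kb)
    gene_len_sigma: float = 1.3
    min_gene_gap: int = 2_000
    # planted domains
    frac_bgrd: float = 0.10
    frac_fgrd: float = 0.05
    bgrd_min_gene_length: int = 80_000  # plant broad domains only on long genes
    bgrd_cov_range: tuple[float, float] = (0.6, 0.9)
    bgrd_height_range: tuple[float, float] = (1.0, 4.0)
    bgrd_tile_width: int = 10_000
    bgrd_tile_gap: tuple[int, int] = (500, 2_000)
    promoter_peak_width: int = 3_000
    fgrd_width: int = 2_000
    fgrd_height_boost: float = 3.0
    # background
    noise_peak_rate: float = 2.0  # peaks per Mb
    noise_width_range: tuple[int, int] = (200, 2_000)
    noise_height_range: tuple[float, float] = (0.5, 2.0)
    track_noise_sd: float = 0.05
    # expression
    expression_baseline: float = 4.0
    expression_coupling: float = 3.0  # slope of log-expression on coverage
    expression_noise_sd: float = 0.5
    # panels and cohorts
    n_samples: int = 10
    conserved_core_frac: float = 0.5
    noncore_present_prob: float = 0.5
    n_cancer: int = 8
    shorten_frac: float = 0.2  # fraction of the conserved core shortened
    lengthen_frac: float = 0.1  # (relative to core size) genes gaining domains
    shorten_factor: float = 0.1  # cancer width = factor * normal width
    shorten_remnant_cap: int = 10_000  # max width of a shortened remnant, bp
    bgrd_mask_cutoff: float = 40_000.0  # membership cutoff for cohort matrices

    def _rng(self, *tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *tag])


def make_genome(spec: SyntheticSpec) -> list[GeneModel]:
    """Place non-overlapping genes with log-normal lengths on one chromosome.

    Exon structure is generated so the intron fraction grows with gene
    length: the exonic total grows sublinearly, so short genes are mostly
    exonic and long genes mostly intronic.
    """
    if spec.n_genes == 0:
        return []
    rng = spec._rng(0)
    lengths = np.maximum(
        rng.lognormal(spec.gene_len_mu, spec.gene_len_sigma, spec.n_genes), 200
    ).astype(int)
    occupied = int(lengths.sum()) + spec.min_gene_gap * (spec.n_genes + 1)
    if occupied > spec.chrom_length // 2:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes ({occupied} bp incl. gaps) into "
            f"half of a {spec.chrom_length} bp chromosome"
        )
    free = spec.chrom_length - occupied
    gaps = (rng.dirichlet(np.ones(spec.n_genes + 1)) * free).astype(int)
    genes = []
    pos = 0
    width_id = len(str(spec.n_genes - 1))
    for i, length in enumerate(lengths):
        pos += spec.min_gene_gap + int(gaps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(rng, pos, int(length))
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width_id}d}",
                chrom=spec.chrom,
                strand=strand,
                start=pos,
                end=pos + int(length),
                exons=exons,
            )
        )
        pos += int(length)
    return genes


def _make_exons(rng: np.random.Generator, start: int, length: int):
    """Exon blocks whose total shrinks (as a fraction) with gene length."""
    exon_total = int(min(length, 200 + 3000 * (length / 1000) ** 0.3))
    n_exons = max(1, exon_total // 1500)
    sizes = np.full(n_exons, exon_total // n_exons)
    sizes[: exon_total % n_exons] += 1
    intron_total = length - exon_total
    gaps = (rng.dirichlet(np.ones(n_exons + 1)) * intron_total).astype(int)
    exons, pos = [], start
    for k in range(n_exons):
        pos += int(gaps[k])
        exons.append((pos, pos + int(sizes[k])))
        pos += int(sizes[k])
    return tuple(exons)


def choose_planted(
    genes: list[GeneModel], spec: SyntheticSpec
) -> tuple[GeneSet, GeneSet]:
    """Pick the genes that carry planted broad (BGRD) and focal (FGRD)
    domains.  Broad domains go to genes of at least ``bgrd_min_gene_length``
    (falling back to the longest genes if too few qualify)."""
    rng = spec._rng(1)
    n_bgrd = round(spec.frac_bgrd * len(genes))
    n_fgrd = round(spec.frac_fgrd * len(genes))
    eligible = sorted(
        (g.gene_id for g in genes if g.length >= spec.bgrd_min_gene_length)
    )
    if len(eligible) < n_bgrd:
        eligible = [
            g.gene_id
            for g in sorted(genes, key=lambda g: (-g.length, g.gene_id))[:n_bgrd]
        ]
    bgrd = set(rng.choice(sorted(eligible), size=n_bgrd, replace=False)) if n_bgrd else set()
    rest = sorted(g.gene_id for g in genes if g.gene_id not in bgrd)
    fgrd = set(rng.choice(rest, size=min(n_fgrd, len(rest)), replace=False)) if n_fgrd else set()
    return GeneSet("planted_bgrd", bgrd), GeneSet("planted_fgrd", fgrd)


def _plant_gene_peaks(
    rng: np.random.Generator, gene: GeneModel, spec: SyntheticSpec,
    coverage: float | None = None,
) -> list[Peak]:
    """Promoter peak plus body tiling summing exactly to coverage * length."""
    cov = coverage if coverage is not None else rng.uniform(*spec.bgrd_cov_range)
    target = int(cov * gene.length)
    lo, hi = spec.bgrd_height_range
    peaks = []
    # sharp-ish promoter peak: 1 kb upstream of the TSS into the gene body
    pw = min(spec.promoter_peak_width, target)
    if gene.strand == "+":
        p0 = gene.tss - 1000
    else:
        p0 = gene.tss + 1000 - pw
    peaks.append(Peak(gene.chrom, p0, p0 + pw, rng.uniform((lo + hi) / 2, hi)))
    total = pw
    pos = gene.start + spec.promoter_peak_width  # tile after the promoter zone
    while total < target and pos < gene.end:
        w = int(spec.bgrd_tile_width * rng.uniform(0.5, 1.5))
        w = min(w, target - total, gene.end - pos)
        if w <= 0:
            break
        peaks.append(Peak(gene.chrom, pos, pos + w, rng.uniform(lo, hi)))
        total += w
        pos += w + int(rng.integers(*spec.bgrd_tile_gap))
    return peaks


def _fgrd_peak(rng: np.random.Generator, gene: GeneModel, spec: SyntheticSpec) -> Peak:
    height = spec.fgrd_height_boost * spec.bgrd_height_range[1] * rng.uniform(1.0, 1.5)
    if gene.strand == "+":
        s = gene.tss
    else:
        s = gene.tss - spec.fgrd_width
    return Peak(gene.chrom, s, s + spec.fgrd_width, height)


def _noise_peaks(
    rng: np.random.Generator, spec: SyntheticSpec, avoid: list[GeneModel]
) -> list[Peak]:
    """Short background peaks placed away from planted genes."""
    n = rng.poisson(spec.noise_peak_rate * spec.chrom_length / 1e6)
    starts = np.sort(rng.integers(0, spec.chrom_length - spec.noise_width_range[1], n))
    avoid_iv = sorted((g.start - spec.noise_width_range[1], g.end) for g in avoid)
    bounds = [iv[0] for iv in avoid_iv]
    peaks = []
    for s in starts:
        i = np.searchsorted(bounds, s, side="right") - 1
        if i >= 0 and s < avoid_iv[i][1]:
            continue
        w = int(rng.integers(*spec.noise_width_range))
        peaks.append(
            Peak(spec.chrom, int(s), int(s) + w, rng.uniform(*spec.noise_height_range))
        )
    return peaks


def _render_track(spec: SyntheticSpec, peaks: list[Peak], rng) -> SignalTrack:
    n = -(-spec.chrom_length // spec.track_step)
    arr = np.abs(rng.normal(0.0, spec.track_noise_sd, n))
    for p in peaks:
        arr[p.start // spec.track_step : -(-p.end // spec.track_step)] += p.height
    return SignalTrack(values={spec.chrom: arr}, step=spec.track_step)


def _sample_parts(
    genes: list[GeneModel],
    spec: SyntheticSpec,
    planted_bgrd: GeneSet,
    planted_fgrd: GeneSet,
    rng: np.random.Generator,
) -> tuple[dict[str, list[Peak]], list[Peak]]:
    """Per-gene planted peaks and background noise peaks for one sample."""
    by_id = {g.gene_id: g for g in genes}
    gene_peaks: dict[str, list[Peak]] = {}
    for gid in sorted(planted_bgrd.gene_ids):
        gene_peaks[gid] = _plant_gene_peaks(rng, by_id[gid], spec)
    for gid in sorted(planted_fgrd.gene_ids):
        gene_peaks.setdefault(gid, []).append(_fgrd_peak(rng, by_id[gid], spec))
    planted_genes = [by_id[gid] for gid in sorted(gene_peaks)]
    noise = _noise_peaks(rng, spec, planted_genes)
    return gene_peaks, noise


def _flatten(gene_peaks: dict[str, list[Peak]], noise: list[Peak]) -> list[Peak]:
    peaks = [p for plist in gene_peaks.values() for p in plist] + noise
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))


def make_sample(
    genes: list[GeneModel],
    spec: SyntheticSpec,
    planted_bgrd: GeneSet,
    planted_fgrd: GeneSet,
    seed_tag: int = 10,
    with_track: bool = True,
) -> tuple[list[Peak], SignalTrack | None]:
    """One sample's peak set (and optionally its signal track).

    Planted broad-domain genes get a promoter peak plus body tiling summing
    to a coverage drawn from ``bgrd_cov_range``; focal-domain genes get one
    narrow peak whose height exceeds every broad-domain peak; background
    noise peaks avoid planted genes so the planted margins are controlled.
    The track is the peak superposition plus small nonnegative noise.
    """
    rng = spec._rng(seed_tag)
    gene_peaks, noise = _sample_parts(genes, spec, planted_bgrd, planted_fgrd, rng)
    peaks = _flatten(gene_peaks, noise)
    track = _render_track(spec, peaks, rng) if with_track else None
    return peaks, track


def make_panel(
    genes: list[GeneModel],
    spec: SyntheticSpec,
    with_tracks: bool = False,
) -> tuple[dict[str, tuple[list[Peak], SignalTrack | None]], dict]:
    """A multi-sample panel with a conserved planted core.

    Core genes (``conserved_core_frac`` of the planted broad domains) appear
    in every sample; the rest appear independently with probability
    ``noncore_present_prob``.  Returns the samples and a truth dict with the
    planted sets, the core, and the per-gene true conservation level.
    """
    planted_bgrd, planted_fgrd = choose_planted(genes, spec)
    rng = spec._rng(2)
    bgrd_sorted = sorted(planted_bgrd.gene_ids)
    n_core = round(spec.conserved_core_frac * len(bgrd_sorted))
    core = set(rng.choice(bgrd_sorted, size=n_core, replace=False)) if n_core else set()
    noncore = [g for g in bgrd_sorted if g not in core]
    samples: dict[str, tuple[list[Peak], SignalTrack | None]] = {}
    presence: dict[str, set[str]] = {}
    for i in range(spec.n_samples):
        present = set(core)
        present |= {
            g for g in noncore if rng.random() < spec.noncore_present_prob
        }
        name = f"normal{i:02d}"
        presence[name] = present
        samples[name] = make_sample(
            genes, spec, GeneSet("present", present), planted_fgrd,
            seed_tag=100 + i, with_track=with_tracks,
        )
    conservation_truth = {
        g.gene_id: sum(g.gene_id in presence[s] for s in presence) / len(presence)
        for g in genes
    }
    truth = {
        "planted_bgrd": planted_bgrd,
        "planted_fgrd": planted_fgrd,
        "core": GeneSet("core", core),
        "presence": presence,
        "conservation": conservation_truth,
    }
    return samples, truth


def _gene_width(peaks: list[Peak]) -> int:
    return sum(p.width for p in peaks)


def make_cancer_cohort(
    genes: list[GeneModel], spec: SyntheticSpec
) -> tuple[dict[str, list[Peak]], dict[str, str], dict]:
    """Normal + cancer peak sets with planted shortening and lengthening.

    Normal samples come from :func:`make_panel`.  Each cancer sample copies a
    base normal sample's planted peaks (with fresh background noise), then a
    ``shorten_frac`` subset of the conserved core is re-tiled to
    ``shorten_factor`` times its width in the base sample, and a few long
    unplanted genes gain full new domains (the lengthened truth set).
    Returns ``(peak_sets, labels, truth)``.
    """
    by_id = {g.gene_id: g for g in genes}
    rng = spec._rng(3)
    planted_bgrd, planted_fgrd = choose_planted(genes, spec)
    panel_samples, panel_truth = make_panel(genes, spec, with_tracks=False)
    core_sorted = sorted(panel_truth["core"].gene_ids)
    n_short = round(spec.shorten_frac * len(core_sorted))
    shortened = (
        set(rng.choice(core_sorted, size=n_short, replace=False)) if n_short else set()
    )
    unplanted_long = sorted(
        g.gene_id
        for g in genes
        if g.gene_id not in planted_bgrd.gene_ids
        and g.length >= spec.bgrd_min_gene_length
    )
    n_long = min(round(spec.lengthen_frac * len(core_sorted)), len(unplanted_long))
    lengthened = (
        set(rng.choice(unplanted_long, size=n_long, replace=False)) if n_long else set()
    )

    # regenerate normals at the parts level so cancer samples can copy them
    peak_sets: dict[str, list[Peak]] = {}
    labels: dict[str, str] = {}
    parts: dict[str, tuple[dict[str, list[Peak]], list[Peak]]] = {}
    for i, name in enumerate(sorted(panel_samples)):
        srng = spec._rng(100 + i)
        present = panel_truth["presence"][name]
        gp, noise = _sample_parts(
            genes, spec, GeneSet("present", present), planted_fgrd, srng
        )
        parts[name] = (gp, noise)
        peak_sets[name] = _flatten(gp, noise)
        labels[name] = "normal"

    normal_names = sorted(parts)
    for j in range(spec.n_cancer):
        crng = spec._rng(200 + j)
        base = normal_names[j % len(normal_names)]
        gp = {gid: list(plist) for gid, plist in parts[base][0].items()}
        for gid in sorted(shortened):
            if gid not in gp or spec.shorten_factor >= 1:
                continue  # factor 1 = null cohort, leave domains untouched
            target = min(
                spec.shorten_factor * _gene_width(gp[gid]), spec.shorten_remnant_cap
            )
            gp[gid] = _plant_gene_peaks(
                crng, by_id[gid], spec, coverage=target / by_id[gid].length
            )
        for gid in sorted(lengthened):
            gp[gid] = _plant_gene_peaks(crng, by_id[gid], spec)
        planted_now = [by_id[gid] for gid in sorted(gp)]
        noise = _noise_peaks(crng, spec, planted_now)
        name = f"cancer{j:02d}"
        peak_sets[name] = _flatten(gp, noise)
        labels[name] = "cancer"

    truth = {
        **panel_truth,
        "shortened": GeneSet("shortened", shortened),
        "lengthened": GeneSet("lengthened", lengthened),
    }
    return peak_sets, labels, truth


def make_expression(
    genes: list[GeneModel],
    domain_stats,
    spec: SyntheticSpec,
    seed_tag: int = 4,
) -> dict[str, float]:
    """Expression negatively coupled to repression coverage.

    ``log expression = baseline - coupling * coverage + Gaussian noise``,
    exponentiated, so all values are finite and positive and genes under
    broad repression sit below the genome-wide median.
    """
    rng = spec._rng(seed_tag)
    cov = {s.gene_id: s.coverage for s in domain_stats}
    out = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        mu = spec.expression_baseline - spec.expression_coupling * cov.get(g.gene_id, 0.0)
        out[g.gene_id] = float(np.exp(mu + rng.normal(0.0, spec.expression_noise_sd)))
    return out
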