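"""Shortened / lengthened BGRD calls between conditions.

Pairwise mode (one cancer sample vs one normal sample) ranks genes by width
difference; each tail of the resulting L-shaped curve gets its own
turning-point cutoff (a change must exceed ``multiplier`` times the tail's
turning-point value), optionally capped at the ``n_top`` most extreme genes
per class.  Cohort mode (groups of normal and cancer samples) requires both
the difference in mean width and the difference in BGRD conservation level
to clear thresholds (defaults 5 kb and 0.3, strict).  A label-shuffle mock
comparison estimates the number of calls expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_calling import DegenerateCurveError, find_turning_point
from .enrichment import hypergeom_enrichment
from .io_formats import GeneSet
from .multi_sample import WidthMatrix

__all__ = [
    "DifferentialCall",
    "MockNull",
    "pairwise_differential",
    "cohort_differential",
    "mock_shuffle",
    "differential_enrichment",
]


@dataclass
class DifferentialCall:
    gene_id: str
    delta_width: float  # test - reference; negative = shortened
    call: str  # {shortened, lengthened, unchanged}
    delta_conservation: float | None = None  # cohort mode only


def _tail_cutoff(tail_values: np.ndarray, multiplier: float) -> float | None:
    """Turning-point cutoff for one tail of the delta curve; None if flat."""
    try:
        tp = find_turning_point(tail_values, multiplier=multiplier)
    except (DegenerateCurveError, ValueError):
        return None
    return tp.cutoff


def pairwise_differential(
    widths_ref: dict[str, float],
    widths_test: dict[str, float],
    multiplier: float = 2.0,
    n_top: int | None = 350,
) -> list[DifferentialCall]:
    """Call shortened/lengthened genes between two samples.

    ``delta = test - ref`` per gene.  The shortened side feeds the positive
    part of ``-delta`` (zeros included, so the curve keeps its L shape) to
    the turning-point search; a gene is shortened when ``-delta`` is positive
    and at least ``multiplier`` times the turning-point value.  The
    lengthened side is symmetric.  With ``n_top`` set, only the most extreme
    ``n_top`` genes per class keep their call.  Widths should be
    quantile-normalized beforehand.
    """
    if set(widths_ref) != set(widths_test):
        raise ValueError("gene universes of ref and test differ")
    genes = sorted(widths_ref)
    delta = np.array([widths_test[g] - widths_ref[g] for g in genes])

    calls = {g: "unchanged" for g in genes}
    for sign, label in ((-1, "shortened"), (1, "lengthened")):
        tail = np.maximum(sign * delta, 0.0)
        if not tail.any():
            continue  # no changes on this side: zero calls
        cutoff = _tail_cutoff(tail, multiplier)
        if cutoff is None:
            continue
        hits = [
            (tail[i], g)
            for i, g in enumerate(genes)
            if tail[i] > 0 and tail[i] >= cutoff
        ]
        if n_top is not None:
            hits = sorted(hits, key=lambda t: (-t[0], t[1]))[:n_top]
        for _, g in hits:
            calls[g] = label
    return [
        DifferentialCall(g, float(d), calls[g]) for g, d in zip(genes, delta)
    ]


def cohort_differential(
    matrix: WidthMatrix,
    min_delta_width: float = 5000.0,
    min_delta_conservation: float = 0.3,
) -> list[DifferentialCall]:
    """Call shortened/lengthened genes between cancer and normal cohorts.

    Per gene, the cancer-minus-normal difference in mean width and in BGRD
    conservation level must both exceed their thresholds (strictly) with the
    same sign: shortened when both are below the negated thresholds,
    lengthened symmetrically.
    """
    normal = matrix.samples_with_label("normal")
    cancer = matrix.samples_with_label("cancer")
    if not normal or not cancer:
        raise ValueError("matrix needs both normal and cancer samples")
    if matrix.bgrd_mask is None:
        raise ValueError("matrix has no BGRD mask; build with a membership rule")
    d_width = matrix.widths[cancer].mean(axis=1) - matrix.widths[normal].mean(axis=1)
    d_cons = matrix.bgrd_mask[cancer].mean(axis=1) - matrix.bgrd_mask[normal].mean(axis=1)
    out = []
    for g in matrix.gene_ids:
        dw, dc = float(d_width[g]), float(d_cons[g])
        if dw < -min_delta_width and dc < -min_delta_conservation:
            call = "shortened"
        elif dw > min_delta_width and dc > min_delta_conservation:
            call = "lengthened"
        else:
            call = "unchanged"
        out.append(DifferentialCall(g, dw, call, delta_conservation=dc))
    return out


@dataclass
class MockNull:
    """Label-shuffle null for the cohort comparison (mean +/- SD call counts)."""

    n_reps: int
    seed: int
    mean_shortened: float
    sd_shortened: float
    mean_lengthened: float
    sd_lengthened: float


def mock_shuffle(
    matrix: WidthMatrix,
    n_reps: int = 1000,
    seed: int = 1,
    min_delta_width: float = 5000.0,
    min_delta_conservation: float = 0.3,
) -> MockNull:
    """Repeat the cohort comparison under shuffled sample labels.

    Each replicate permutes the normal/cancer labels across samples (class
    sizes preserved), reruns :func:`cohort_differential`, and records the
    number of shortened and lengthened calls.  Deterministic for a given
    seed.
    """
    samples = matrix.sample_ids
    label_list = [matrix.labels[s] for s in samples]
    rng = np.random.default_rng(seed)
    n_short, n_long = [], []
    for _ in range(n_reps):
        perm = rng.permutation(len(samples))
        shuffled = WidthMatrix(
            widths=matrix.widths,
            labels={samples[i]: label_list[j] for i, j in enumerate(perm)},
            bgrd_mask=matrix.bgrd_mask,
        )
        calls = cohort_differential(shuffled, min_delta_width, min_delta_conservation)
        n_short.append(sum(c.call == "shortened" for c in calls))
        n_long.append(sum(c.call == "lengthened" for c in calls))
    return MockNull(
        n_reps=n_reps,
        seed=seed,
        mean_shortened=float(np.mean(n_short)),
        sd_shortened=float(np.std(n_short)),
        mean_lengthened=float(np.mean(n_long)),
        sd_lengthened=float(np.std(n_long)),
    )


def differential_enrichment(
    calls: list[DifferentialCall], category: GeneSet, universe: GeneSet
) -> dict[str, tuple[float, float]]:
    """Category enrichment (fold, p) of the shortened and lengthened sets.

    Empty classes are skipped (absent from the result).
    """
    n_cat = len(category.gene_ids & universe.gene_ids)
    out: dict[str, tuple[float, float]] = {}
    for label in ("shortened", "lengthened"):
        ids = {c.gene_id for c in calls if c.call == label} & universe.gene_ids
        if not ids:
            continue
        obs = len(ids & category.gene_ids)
        out[label] = hypergeom_enrichment(obs, len(ids), n_cat, len(universe))
    return out
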