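"""Call repression domains on the reference sample: per-gene width/height
statistics, the knee of the sorted width curve, BGRD/FGRD classification,
the bimodal coverage boundary, and the a1/a2/b/c gene groups.

Reads the synthetic data written by 01_simulate.py and reports how well the
classification recovers the planted truth.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bgrd import (  # noqa: E402
    GeneSet,
    assign_gene_groups,
    classify_domains,
    compute_gene_peak_stats,
    coverage_boundary,
    find_turning_point,
    intron_fraction,
)
from bgrd.domain_calling import NoBoundaryError  # noqa: E402
from bgrd.io_formats import read_gene_annotation, read_gene_set, read_peaks  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    genes = read_gene_annotation(SCRATCH / "genes.bed", "bed12")
    peaks = read_peaks(SCRATCH / "peaks_reference.bed", "bed")
    truth = read_gene_set(SCRATCH / "truth_planted_bgrd.txt", "planted_bgrd")

    stats = compute_gene_peak_stats(genes, peaks)
    tp = find_turning_point([s.width_sum for s in stats])
    stats, control = classify_domains(stats, tp, n_top=len(truth))
    called = {s.gene_id for s in stats if s.domain_class == "BGRD"}
    recall = len(called & truth.gene_ids) / len(truth)
    precision = len(called & truth.gene_ids) / len(called)

    try:
        boundary = coverage_boundary([s.coverage for s in stats])
    except NoBoundaryError as err:
        boundary = float("nan")
        print(f"coverage density unimodal (mode {err.mode:.3f}); no boundary")
    else:
        stats = assign_gene_groups(stats, genes, GeneSet("bgrd", called), boundary)

    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "width_sum": [s.width_sum for s in stats],
            "height_max": [s.height_max for s in stats],
            "coverage": [s.coverage for s in stats],
            "domain_class": [s.domain_class for s in stats],
            "group": [s.group for s in stats],
        }
    ).set_index("gene_id")
    df.to_csv(SCRATCH / "stats_reference.tsv", sep="\t")

    by_id = {g.gene_id: g for g in genes}
    group_sizes = df["group"].value_counts().to_dict()
    mean_intron = {
        grp: pd.Series(
            [intron_fraction(by_id[g]) for g in df.index[df["group"] == grp]]
        ).mean()
        for grp in sorted(group_sizes)
    }
    summary = pd.DataFrame(
        [
            ("turning_point_width_bp", tp.width_at_turn),
            ("width_cutoff_bp", tp.cutoff),
            ("n_bgrd_called", len(called)),
            ("planted_recall", round(recall, 4)),
            ("planted_precision", round(precision, 4)),
            ("coverage_boundary", round(boundary, 4)),
            *[(f"n_group_{g}", n) for g, n in sorted(group_sizes.items())],
            *[(f"mean_intron_fraction_{g}", round(v, 3)) for g, v in mean_intron.items()],
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "02_domain_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nknee at {tp.width_at_turn / 1000:.1f} kb -> cutoff "
        f"{tp.cutoff / 1000:.1f} kb; BGRD recovery recall {recall:.2f}, "
        f"precision {precision:.2f}"
    )


if __name__ == "__main__":
    main()
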