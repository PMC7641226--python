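"""Cross-sample conservation and optimal reference-panel selection.

Builds the genes x samples width matrix over the normal samples,
quantile-normalizes widths to the first sample, ranks genes by BGRD
conservation level, correlates conservation with maximum width, and runs the
forward panel selection against the planted broad-domain gene set.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bgrd import (  # noqa: E402
    GeneSet,
    SyntheticSpec,
    build_width_matrix,
    compute_gene_peak_stats,
    conservation_vs_width,
    forward_dataset_selection,
    quantile_normalize_to_reference,
)
from bgrd.io_formats import read_gene_annotation, read_gene_set, read_peaks  # noqa: E402
from bgrd.multi_sample import BgrdRule  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    spec = SyntheticSpec(seed=1)
    genes = read_gene_annotation(SCRATCH / "genes.bed", "bed12")
    labels = pd.read_csv(SCRATCH / "labels.tsv", sep="\t", index_col=0)["label"]
    normals = sorted(labels.index[labels == "normal"])
    per_sample = {
        s: compute_gene_peak_stats(genes, read_peaks(SCRATCH / f"peaks_{s}.bed", "bed"))
        for s in normals
    }
    matrix = build_width_matrix(per_sample, BgrdRule(cutoff=spec.bgrd_mask_cutoff))
    matrix = quantile_normalize_to_reference(matrix, normals[0])

    core = read_gene_set(SCRATCH / "truth_core.txt", "core")
    cons, max_w, rho = conservation_vs_width(matrix)
    top = cons.sort_values(ascending=False, kind="stable")
    n_core_at_top = len(set(top.index[: len(core)]) & core.gene_ids)

    category = read_gene_set(SCRATCH / "truth_planted_bgrd.txt", "planted")
    universe = GeneSet("all", set(matrix.gene_ids))
    sets = {
        s: GeneSet(s, set(matrix.bgrd_mask.index[matrix.bgrd_mask[s]]))
        for s in matrix.sample_ids
    }
    sel = forward_dataset_selection(sets, category, universe)
    curve = pd.DataFrame(
        {
            "k": range(1, len(sel.p_curve) + 1),
            "sample": sel.ranked_sample_ids,
            "sample_p": sel.sample_p,
            "union_p": sel.p_curve,
        }
    )
    curve.to_csv(RESULTS / "05_panel_selection.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        [
            ("normal_samples", len(normals)),
            ("core_genes", len(core)),
            ("core_genes_in_top_conservation_ranks", n_core_at_top),
            ("conservation_vs_max_width_rho", round(rho, 3)),
            ("panel_chosen_k", sel.chosen_k),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "05_conservation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\n{n_core_at_top}/{len(core)} conserved-core genes occupy the top "
        f"conservation ranks; forward selection keeps k={sel.chosen_k} samples"
    )


if __name__ == "__main__":
    main()
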