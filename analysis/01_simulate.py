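"""Generate the synthetic study data: a genome, a reference H3K27me3 sample,
and a cancer/normal cohort with planted domain shortening/lengthening.

Bulky intermediates (annotation, peak calls, expression) go to
scratch/synthetic/; a small summary table goes to results/.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bgrd import (  # noqa: E402
    SyntheticSpec,
    choose_planted,
    compute_gene_peak_stats,
    make_cancer_cohort,
    make_expression,
    make_genome,
    make_sample,
)
from bgrd.io_formats import write_bedgraph, write_gene_annotation, write_peaks  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    spec = SyntheticSpec(seed=1)
    genes = make_genome(spec)
    write_gene_annotation(SCRATCH / "genes.bed", genes)
    planted_bgrd, planted_fgrd = choose_planted(genes, spec)

    peaks, track = make_sample(genes, spec, planted_bgrd, planted_fgrd)
    write_peaks(SCRATCH / "peaks_reference.bed", peaks)
    write_bedgraph(SCRATCH / "signal_reference.bedgraph", track)

    peak_sets, labels, truth = make_cancer_cohort(genes, spec)
    for name, pk in peak_sets.items():
        write_peaks(SCRATCH / f"peaks_{name}.bed", pk)
    pd.Series(labels, name="label").rename_axis("sample").to_csv(
        SCRATCH / "labels.tsv", sep="\t"
    )
    for key in ("planted_bgrd", "planted_fgrd", "core", "shortened", "lengthened"):
        (SCRATCH / f"truth_{key}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(truth[key].gene_ids))
        )
    stats = compute_gene_peak_stats(genes, peak_sets["cancer00"])
    expr = make_expression(genes, stats, spec)
    pd.Series(expr, name="expression").rename_axis("gene_id").to_csv(
        SCRATCH / "expression_cancer00.tsv", sep="\t"
    )

    summary = pd.DataFrame(
        [
            ("genes", len(genes)),
            ("planted_bgrd_genes", len(planted_bgrd)),
            ("planted_fgrd_genes", len(planted_fgrd)),
            ("conserved_core_genes", len(truth["core"])),
            ("planted_shortened", len(truth["shortened"])),
            ("planted_lengthened", len(truth["lengthened"])),
            ("normal_samples", sum(v == "normal" for v in labels.values())),
            ("cancer_samples", sum(v == "cancer" for v in labels.values())),
            ("reference_sample_peaks", len(peaks)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "01_synthetic_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote data to {SCRATCH}")


if __name__ == "__main__":
    main()
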