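import pytest

from bgrd import (
    SyntheticSpec,
    choose_planted,
    compute_gene_peak_stats,
    make_cancer_cohort,
    make_genome,
    make_sample,
)
from bgrd.multi_sample import BgrdRule, build_width_matrix


@pytest.fixture(scope="session")
def spec():
    """The default synthetic study conditions (fixed seed)."""
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def genome(spec):
    return make_genome(spec)


@pytest.fixture(scope="session")
def planted(genome, spec):
    return choose_planted(genome, spec)


@pytest.fixture(scope="session")
def sample(genome, spec, planted):
    """One synthetic sample: (peaks, signal track)."""
    return make_sample(genome, spec, *planted, with_track=True)


@pytest.fixture(scope="session")
def cohort(genome, spec):
    """Default cancer/normal cohort: (peak_sets, labels, truth)."""
    return make_cancer_cohort(genome, spec)


@pytest.fixture(scope="session")
def cohort_matrix(genome, spec, cohort):
    peak_sets, labels, _ = cohort
    per_sample = {n: compute_gene_peak_stats(genome, p) for n, p in peak_sets.items()}
    return build_width_matrix(
        per_sample, BgrdRule(cutoff=spec.bgrd_mask_cutoff), labels=labels
    )
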