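import numpy as np
import pytest

from geneburden.cohort_data import (
    GenotypeMatrix,
    SampleRecord,
    VariantSite,
)


def make_matrix(calls, statuses, genes=None, chrom="1", pos_step=10):
    """Build a small GenotypeMatrix from a 2-D list (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = [
        SampleRecord(f"S{i}", "toy", status)
        for i, status in enumerate(statuses)
    ]
    assert len(samples) == n_samples
    genes = genes or [""] * n_sites
    sites = [
        VariantSite(chrom=chrom, pos=100 + pos_step * j, ref="A", alt="G",
                    gene=genes[j], consequence="missense")
        for j in range(n_sites)
    ]
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


@pytest.fixture
def toy_matrix():
    """3 cases + 3 controls x 4 sites, no missingness."""
    calls = [
        [1, 0, 0, 0],
        [0, 1, 1, 0],
        [2, 0, 0, 0],
        [0, 0, 0, 1],
        [0, 0, 0, 0],
        [0, 0, 0, 0],
    ]
    return make_matrix(calls, ["case"] * 3 + ["control"] * 3)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A written-to-disk synthetic study shared across file-IO tests."""
    from geneburden.synthetic_cohorts import (
        GeneSpec,
        SimulationConfig,
        simulate_cohort,
        write_simulated_study,
    )

    config = SimulationConfig(
        seed=7, n_cases=120, n_controls=110,
        genes=[
            GeneSpec("GENEA", carrier_freq_controls=0.05, odds_ratio=3.0,
                     n_qualifying_sites=5, n_nonqualifying_sites=2),
            GeneSpec("GENEB", carrier_freq_controls=0.04, odds_ratio=1.0,
                     n_qualifying_sites=4, n_nonqualifying_sites=2),
        ],
        per_sample_missing_rate=0.01, per_site_missing_rate=0.005,
        cohort_splits=[("north", 0.6), ("south", 0.4)],
    )
    study = simulate_cohort(config)
    directory = tmp_path_factory.mktemp("study")
    paths = write_simulated_study(study, directory)
    return config, study, paths
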