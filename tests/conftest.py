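import pytest

from methclass import cnv, datasets, preprocess


@pytest.fixture(scope="session")
def annotation():
    """Full-size (20k probes) reduced-genome annotation."""
    return datasets.build_genome_annotation(datasets.GenomeModel(), seed=11)


@pytest.fixture(scope="session")
def small_annotation():
    """Cheap annotation for algorithmic tests."""
    return datasets.build_genome_annotation(datasets.GenomeModel(probe_count=4000), seed=5)


@pytest.fixture(scope="session")
def cohort(annotation):
    """Default three-class cohort with ground truth."""
    return datasets.simulate_cohort(annotation, datasets.default_class_specs(), seed=11)


@pytest.fixture(scope="session")
def filtered_beta(cohort, annotation):
    beta, _ = preprocess.filter_probes(cohort.beta, annotation)
    return beta


@pytest.fixture(scope="session")
def log2_ratios(cohort, filtered_beta):
    ratios = cnv.cohort_log2_ratios(
        2.0 ** cohort.log2_intensity, 2.0 ** cohort.reference_log2_intensity
    )
    return ratios.loc[filtered_beta.index]


@pytest.fixture(scope="session")
def cohort_segments(log2_ratios, annotation):
    return cnv.segment_cohort(log2_ratios, annotation)
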