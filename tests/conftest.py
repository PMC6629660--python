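import pytest

from syssvm.simulate import CohortSpec, generate_cohort, generate_worked_fixture


@pytest.fixture(scope="session")
def worked_cohort():
    """Tiny hand-checkable cohort: 4 patients, 40 genes."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def desk_cohort():
    """Mid-size cohort for pipeline-level tests."""
    spec = CohortSpec(
        n_patients=20, n_genes=400, n_known_cancer_genes=20, n_planted_helpers=15,
        damaged_genes_per_patient=40.0, n_pathways=20, n_planted_clusters=2,
        n_germline_variants=200, seed=11,
    )
    return generate_cohort(spec)
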