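import pytest

from genofacet import fixtures as fx


@pytest.fixture(scope="session")
def uterus():
    return fx.build_worked_example("uterus")


@pytest.fixture(scope="session")
def k562():
    return fx.build_worked_example("k562")


@pytest.fixture(scope="session")
def boris():
    return fx.build_worked_example("boris")


@pytest.fixture(scope="session")
def eye():
    return fx.build_worked_example("eye")


@pytest.fixture(scope="session")
def brain():
    return fx.build_worked_example("brain")


@pytest.fixture(scope="session")
def prostate():
    return fx.build_worked_example("prostate")


@pytest.fixture(scope="session")
def small_random():
    """One deterministic random repository with brute-force ground truth."""
    return fx.random_repository(11, n_items=150)


@pytest.fixture(scope="session")
def patient_cohort():
    """A cancer-cohort-style repository: 401 items spread over 7 datasets,
    several items per donor, for summarization and export tests."""
    rb = fx.RepositoryBuilder()
    pid = rb.add_project("cohort project", "tcga")
    cid = rb.add_case(pid)
    eid = rb.add_experiment_type(technique="genotyping array")
    sizes = [45, 50, 55, 60, 65, 56, 70]
    for j, n in enumerate(sizes):
        did = rb.add_dataset(f"cohort dataset {j}", data_type=f"type {j}")
        rb.add_item_group(n, prefix=f"coh{j}", dataset_id=did,
                          experiment_type_id=eid, case_ids=(cid,),
                          disease="cholangiocarcinoma",
                          is_healthy=["true", "false"][j % 2])
    return rb.build(), sizes
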