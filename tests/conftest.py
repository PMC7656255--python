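import pytest

from oncopanel.simulate import CohortSpec, generate


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory 150-sample synthetic cohort shared across tests."""
    return generate(CohortSpec(n_samples=150, seed=7))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 150-sample cohort written to disk in every input dialect."""
    outdir = tmp_path_factory.mktemp("cohort") / "c150"
    generate(CohortSpec(n_samples=150, seed=7), outdir)
    return outdir
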