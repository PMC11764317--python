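import pytest

from delscape.simulate import SyntheticTruth, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests (read-only)."""
    return generate_cohort(SyntheticTruth(seed=11))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same cohort written to disk."""
    outdir = tmp_path_factory.mktemp("cohort")
    cohort.write(outdir)
    return outdir
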