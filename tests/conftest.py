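import pytest

from panloc.simulate import SimConfig, simulate_cohort

# A small, fast cohort reused across modules: 6 kb locus, 3 x 400 bp
# insertion, 4 carrier + 6 non-carrier samples at 20x.
SMALL = SimConfig(
    seed=7,
    backbone_length=6_000,
    sv_breakpoint=3_000,
    sv_unit_length=400,
    sv_copies=3,
    n_carrier_samples=4,
    n_noncarrier_samples=6,
    read_length=100,
    depth=20.0,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_reads(small_cohort):
    return small_cohort.reads()


def backbone_path_of(cohort) -> str:
    """The ordering backbone: first non-carrier haplotype path."""
    return next(h.name for h in cohort.haplotypes if not h.carrier)
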