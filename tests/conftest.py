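import pytest

from tmburden.pipeline import make_fixture
from tmburden.synthetic_cohort import SimulationConfig
from tmburden.variant_core import AnnotatedVariant, VariantKey


def av(chrom="chr1", pos=100, ref="A", alt="T", impact="MODERATE", gene=""):
    """Shorthand for building an annotated variant in tests."""
    return AnnotatedVariant(key=VariantKey(chrom, pos, ref, alt),
                            impact=impact, gene=gene)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged 3-patient micro-cohort, written once per session."""
    d = tmp_path_factory.mktemp("micro_cohort")
    make_fixture(d)
    return d


@pytest.fixture
def small_config():
    """A small two-group simulation config for object-level tests."""
    return SimulationConfig(
        n_patients_by_group={"White": 6, "Black": 4},
        n_sites=800,
        db_samples_by_pop={"EUR": 200, "AFR": 40},
        seed=11,
    )
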