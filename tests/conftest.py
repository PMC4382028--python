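import pytest

from sectorloh import generate_snp_map


@pytest.fixture(scope="session")
def chr4_map():
    """Chromosome-IV-scale scaffold: ~2300 SNPs over the ~1.1 Mb CEN-to-marker
    interval."""
    return generate_snp_map(2300, 1_100_000, seed=11)


@pytest.fixture(scope="session")
def small_map():
    """A small, fast scaffold for per-event pipeline tests."""
    return generate_snp_map(300, 150_000, seed=7)
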