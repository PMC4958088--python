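import pytest
from hypothesis import HealthCheck, settings

from ssrcid import (
    CultivarRecord,
    GenotypeCall,
    GenotypeTable,
    load_fixtures,
    load_genotype_table,
    load_marker_stats,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_table(marker_calls: dict[str, list[str]], names=None) -> GenotypeTable:
    """Small builder: marker -> list of genotype strings, one per cultivar."""
    from ssrcid import parse_genotype_string

    markers = list(marker_calls)
    n = len(next(iter(marker_calls.values())))
    cultivars = [
        CultivarRecord(code=i + 1, name=(names[i] if names else f"C{i + 1}"))
        for i in range(n)
    ]
    calls = {
        (i + 1, m): parse_genotype_string(marker_calls[m][i])
        for m in markers
        for i in range(n)
    }
    return GenotypeTable(cultivars, markers, calls)


@pytest.fixture(scope="session")
def tea_table():
    return load_genotype_table()


@pytest.fixture(scope="session")
def printed_stats():
    return load_marker_stats()


@pytest.fixture()
def toy_symmetric():
    """Three diploids at one locus: A/A, A/B, B/B with allele sizes 100/104."""
    return make_table({"L1": ["100/100", "100/104", "104/104"]})
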