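import pytest
from hypothesis import settings

from mifish import DEFAULT_PANEL, NucleusRecord
from mifish.panel import Probe, ProbePanel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def panel():
    return DEFAULT_PANEL


@pytest.fixture
def gene_panel():
    """The eight gene probes without centromere references."""
    return ProbePanel([p for p in DEFAULT_PANEL if p.role == "gene"])


def make_records(pattern_multiplicities, centromeres=(2, 2)):
    """Expand [(gene_vector, multiplicity), ...] into nucleus records,
    appending the centromere counts to each vector."""
    records = []
    for vec, mult in pattern_multiplicities:
        for _ in range(mult):
            records.append(
                NucleusRecord(str(len(records) + 1), tuple(vec) + tuple(centromeres))
            )
    return records


# the two clone patterns printed for the low-instability case, plus
# three distinct minor patterns, totalling 250 nuclei in 5 patterns
CASE_7L = [
    ((2, 1, 3, 2, 1, 2, 2, 2), 217),
    ((2, 1, 4, 2, 1, 2, 2, 2), 29),
    ((2, 1, 3, 2, 1, 2, 2, 3), 2),
    ((2, 2, 3, 2, 1, 2, 2, 2), 1),
    ((1, 1, 3, 2, 1, 2, 2, 2), 1),
]


@pytest.fixture
def case_7l_records():
    return make_records(CASE_7L)
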