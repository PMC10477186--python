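import numpy as np
import pytest

from dartpop import (
    GenotypeMatrix,
    MarkerRecord,
    SimulationConfig,
    simulate_structured_populations,
)
from dartpop.io_formats import MISSING, SILICODART, SNP


def make_matrix(calls, marker_type=SNP, chroms=None, sample_ids=None, positions=None):
    """Small hand-built genotype matrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int16)
    n, L = calls.shape
    markers = []
    for j in range(L):
        markers.append(
            MarkerRecord(
                f"m{j:02d}",
                marker_type,
                chroms[j] if chroms else "CpA01",
                positions[j] if positions else 100 * (j + 1),
                "A" if marker_type == SNP else None,
                "G" if marker_type == SNP else None,
            )
        )
    ids = sample_ids or [f"s{i:02d}" for i in range(n)]
    return GenotypeMatrix(ids, markers, calls)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two Balding-Nichols populations at F = 0.10 (the differentiation
    benchmark used across the diversity tests)."""
    cfg = SimulationConfig(
        n_pops=2, pop_sizes=(100, 100), n_markers=2000, fst=0.10, seed=42
    )
    gm, labels, freqs = simulate_structured_populations(cfg)
    grouping = {s: f"pop{l + 1}" for s, l in zip(gm.sample_ids, labels)}
    return gm, labels, freqs, grouping


@pytest.fixture(scope="session")
def panmictic_panel():
    """A single undifferentiated population."""
    cfg = SimulationConfig(n_pops=1, pop_sizes=(120,), n_markers=2000, fst=0.10, seed=7)
    gm, _, freqs = simulate_structured_populations(cfg)
    return gm, freqs
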