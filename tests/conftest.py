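import numpy as np
import pytest

import linediff as ld


@pytest.fixture(scope="session")
def marker_fixture():
    """The packaged 156-row candidate-marker table."""
    return ld.load_marker_fixture()


@pytest.fixture(scope="session")
def small_study():
    """A deterministic simulated two-line study at default scale."""
    return ld.simulate_study(ld.SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """Deep, error-free study: fixed case-only variants must be recovered exactly."""
    return ld.simulate_study(ld.SimConfig(seed=7, depth_mean=20, error_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_snp_rate(counts):
    """Enumerate every non-reference event and divide the max by depth."""
    events = []
    if counts.ref_base == "-":
        events = [counts.base_count(b) for b in "ACGT"]
        if not any(events):
            events = [counts.count_ins]
    else:
        events = [counts.base_count(b) for b in "ACGT" if b != counts.ref_base]
        events.append(counts.count_del)
        if counts.count_ins:
            events.append(counts.count_ins)
    return max(events) / counts.depth if events else 0.0


def spliced_cds_oracle(model, reference):
    """Base-by-base walk of the CDS in genomic order, reverse-complemented on '-'."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seq = reference[model.contig]
    bases = []
    for s, e in sorted(model.cds_segments):
        for pos in range(s, e + 1):
            bases.append(seq[pos - 1])
    if model.strand == "-":
        bases = [comp[b] for b in reversed(bases)]
    return "".join(bases)


def cds_position_oracle(model):
    """{genomic pos: 1-based spliced CDS pos}, walking segments base-by-base."""
    coords = []
    for s, e in sorted(model.cds_segments):
        coords.extend(range(s, e + 1))
    if model.strand == "-":
        coords = coords[::-1]
    return {pos: i + 1 for i, pos in enumerate(coords)}
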