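import pytest

import glycopore as gp


@pytest.fixture(scope="session")
def library():
    return gp.builtin_library()


@pytest.fixture(scope="session")
def table_6sl(library):
    """40,000 untimed events from the 6SL-MPB model."""
    return gp.sample_events(library["6SL-MPB"], 40_000, seed=101, with_times=False)


@pytest.fixture(scope="session")
def table_3sl(library):
    """40,000 untimed events from the 3SL-MPB model."""
    return gp.sample_events(library["3SL-MPB"], 40_000, seed=102, with_times=False)


@pytest.fixture(scope="session")
def four_glycan_tables(library):
    """Four well-separated glycans, 40,000 events each (the canonical panel)."""
    names = ["3SL-MPB", "6SL-MPB", "6S2FL-MPB", "LNT-DPE-6SL"]
    return {
        n: gp.sample_events(library[n], 40_000, seed=200 + i, with_times=False)
        for i, n in enumerate(names)
    }
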