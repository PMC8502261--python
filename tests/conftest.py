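import pytest

import cnvcohort as cc


@pytest.fixture(scope="session")
def bundled():
    """All bundled inputs (cohort tables, sample sheet, reference files)."""
    return cc.load_bundled()


@pytest.fixture(scope="session")
def bundled_result():
    """Full pipeline result on the bundled cohort (as-published filter)."""
    return cc.reproduce_bundled()


@pytest.fixture(scope="session")
def cavc_calls(bundled):
    return [c for c in bundled["calls"] if c.sample_id.startswith("CAVC")]


@pytest.fixture(scope="session")
def sv_calls(bundled):
    return [c for c in bundled["calls"] if c.sample_id.startswith("SV")]


@pytest.fixture
def toy_build():
    return cc.GenomeBuild("toy", (
        cc.Chromosome("1", 10_000, 0, 10_000),
        cc.Chromosome("21", 46_709_983, 13_000_000, 46_700_000),
    ))
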