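import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lirscreen import fixture_forge


@pytest.fixture(scope="session")
def screen_corpus(tmp_path_factory):
    """End-to-end synthetic corpus, generated once per session."""
    out = tmp_path_factory.mktemp("corpus")
    return fixture_forge.make_screen_corpus(out, seed=7)


@pytest.fixture(scope="session")
def lir_fixture_complex():
    """One canonical-LIR predicted complex, shared by read-only tests."""
    return fixture_forge.make_peptide_pose(
        fixture_forge.FixtureSpec(label="can.LIR", seed=11)
    )
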