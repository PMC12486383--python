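import logging

import pytest

from synopsin import presets

logging.getLogger("synopsin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """Default scenario with sequences (shared; treat as read-only)."""
    return presets.paper_scenario(seed=11)


@pytest.fixture(scope="session")
def skeleton_bundle():
    """Default scenario, structure only (fast)."""
    return presets.paper_scenario(seed=11, with_sequences=False)
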