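import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from castkit.synth import CastParams, generate_cast_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic CAST genome with ground truth (seed 1)."""
    return generate_cast_genome(CastParams(seed=1))
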