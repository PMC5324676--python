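import numpy as np
import pytest

from amplistar import fixtures
from amplistar.sequences import decode, encode
from amplistar.synthetic import ReadErrorModel, _apply_errors


@pytest.fixture(scope="session")
def reference() -> str:
    return fixtures.fixture_reference()


@pytest.fixture(scope="session")
def table():
    return fixtures.fixture_table()


@pytest.fixture(scope="session")
def layout():
    return fixtures.fixture_layout()


def noisy_copies(template: str, n: int, model: ReadErrorModel, seed: int) -> list[str]:
    """n independent noisy reads of a template (insert only, no adornments)."""
    rng = np.random.default_rng(seed)
    codes = encode(template)
    return [decode(_apply_errors(codes, model, rng)) for _ in range(n)]
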