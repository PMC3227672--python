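import numpy as np
import pytest
from hypothesis import settings

from mirscreen.library import Construct, ConstructLibrary
from mirscreen.simulate import generate_construct_library

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library() -> ConstructLibrary:
    """12 constructs, 120 nt inserts, 20 nt flanks; used wherever real
    sequences matter."""
    return generate_construct_library(12, insert_len=120, flank_len=20, seed=11)


@pytest.fixture(scope="session")
def screen_library() -> ConstructLibrary:
    """40 constructs mirroring one screening pool."""
    return generate_construct_library(40, insert_len=120, flank_len=20, seed=7)


def toy_library(n: int, prefix: str = "c") -> ConstructLibrary:
    """Cheap library for counts-only simulations (sequences never read)."""
    ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    return ConstructLibrary(
        [Construct(cid, cid, "ACGTACGTACGTACGTACGT", "A" * 20, "C" * 20) for cid in ids]
    )
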