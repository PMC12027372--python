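import itertools

import numpy as np
import pytest

from edrec.design import (
    SequenceParts,
    annotations_frame,
    design_stemloop_library,
)
from edrec.simulate import EditingModel


@pytest.fixture(scope="session")
def parts():
    return SequenceParts()


@pytest.fixture(scope="session")
def default_model():
    return EditingModel()


@pytest.fixture(scope="session")
def tiny_pool():
    """Four loop variants (position 8 randomized), both orientations."""
    records = design_stemloop_library(window=(8, 8), seed=0)
    return records, annotations_frame(records)


@pytest.fixture(scope="session")
def all_loops():
    """All 1,024 possible 5-nt loops (RNA alphabet)."""
    return ["".join(c) for c in itertools.product("ACGU", repeat=5)]


def gnrna_bruteforce(loop: str) -> bool:
    """Independent statement of the GNRNA predicate for oracle checks."""
    return loop[0] == "G" and loop[2] in ("A", "G") and loop[4] == "A"
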