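import numpy as np
import pandas as pd
import pytest

import evomedia as em


@pytest.fixture(scope="session")
def aa_space():
    """The packaged amino-acid parameter space (20 optimizable genes)."""
    return em.builtin_space()


@pytest.fixture(scope="session")
def glutamine(aa_space):
    return next(s for s in aa_space.specs if s.name == "l-Glutamine")


@pytest.fixture
def demo_space():
    return em.make_demo_space(5)


class FakeRng:
    """Deterministic stand-in for numpy's Generator in operator unit tests."""

    def __init__(self, randoms=(), integers=()):
        self._randoms = list(randoms)
        self._integers = list(integers)

    def random(self, size=None):
        if size is None:
            return self._randoms.pop(0)
        return np.array([self._randoms.pop(0) for _ in range(size)])

    def integers(self, low, high=None, size=None, dtype=None):
        assert size is None
        return self._integers.pop(0)


@pytest.fixture
def fake_rng():
    return FakeRng


def make_assay_table(nets_by_treatment, background=500.0, individual_id=None):
    """Build a paired cells/cell-free assay table with given net RFU replicates."""
    rows = []
    for tid, nets in nets_by_treatment.items():
        for rep, net in enumerate(nets, start=1):
            common = {"well": f"A{rep}", "treatment_id": tid, "replicate": rep}
            if individual_id is not None:
                common["individual_id"] = individual_id
            rows.append(
                {"plate_id": "P1", "role": "cells", "rfu": background + net, **common}
            )
            rows.append(
                {"plate_id": "P2", "role": "cell_free", "rfu": background, **common}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def assay_builder():
    return make_assay_table
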