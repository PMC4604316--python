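import numpy as np
import pytest

from rhizopan import (
    CompartmentLabels,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)


@pytest.fixture
def small_labels() -> CompartmentLabels:
    """2 rhizosphere + 3 endosphere strains."""
    return CompartmentLabels(
        {
            "r1": RHIZOSPHERE,
            "r2": RHIZOSPHERE,
            "e1": ENDOSPHERE,
            "e2": ENDOSPHERE,
            "e3": ENDOSPHERE,
        }
    )


@pytest.fixture
def study_labels() -> CompartmentLabels:
    """Study-shaped 4 + 15 design."""
    mapping = {f"R{i:02d}": RHIZOSPHERE for i in range(1, 5)}
    mapping.update({f"E{i:02d}": ENDOSPHERE for i in range(1, 16)})
    return CompartmentLabels(mapping)


def make_matrix(strains, features, rows, kind="presence") -> PresenceMatrix:
    return PresenceMatrix.from_arrays(strains, features, np.array(rows),
                                      kind=kind)


@pytest.fixture
def matrix_factory():
    return make_matrix
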