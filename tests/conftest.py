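import numpy as np
import pandas as pd
import pytest

from qtlhotspot.io_formats import MarkerMatrix
from qtlhotspot.simulate import make_annotation_fixture


@pytest.fixture(scope="session")
def annotation_fixture():
    """The deterministic 13-gene region fixture (shared; construction is
    pure so sharing is safe)."""
    return make_annotation_fixture()


@pytest.fixture
def toy_matrix():
    """Six markers on one chromosome, four homozygous families."""
    markers = [f"M{i}" for i in range(1, 7)]
    mm = pd.DataFrame({
        "chrom": "Ca4",
        "cm": np.linspace(0.0, 0.25, 6),
        "bp": [100, 300, 500, 700, 900, 1100],
    }, index=pd.Index(markers, name="marker"))
    calls = pd.DataFrame(
        [list("AABBAA"),
         list("AABBAA"),
         list("AAAAAA"),
         list("BBAAAA")],
        index=["F1", "F2", "F3", "F4"], columns=markers,
    )
    return MarkerMatrix(calls=calls, marker_map=mm)
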