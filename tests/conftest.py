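import numpy as np
import pytest

from linkclust.io import ExpressionMatrix
from linkclust.synthetic import SyntheticSpec, make_expression, make_ontology


@pytest.fixture
def collinear3() -> ExpressionMatrix:
    """Three collinear 1-D points at 0, 1, 3 (hand-checkable densities)."""
    return ExpressionMatrix(["g0", "g1", "g2"], np.array([[0.0], [1.0], [3.0]]))


@pytest.fixture(scope="session")
def blobs_small():
    """Two far-separated tight blobs of 10 genes each, with labels."""
    spec = SyntheticSpec(n=20, d=3, k=2, separation=8.0, seed=7)
    return make_expression(spec)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study: expression, labels, ontology, annotations."""
    spec = SyntheticSpec(n=80, d=5, k=3, separation=6.0, seed=11)
    m, labels = make_expression(spec)
    ontology, mapping = make_ontology(spec, labels)
    return spec, m, labels, ontology, mapping
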