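import numpy as np
import pytest

from hemtree.node_model import NodeLogisticModel
from hemtree.tree_core import Node, SplitRule, TreeModel
from hemtree.synthetic_data import TreedGenerator, generate_cohort


@pytest.fixture(scope="session")
def toy_1d():
    """12 distinct values of one predictor, labels switching mid-range.

    With min_node_size=4 the admissible tree space has 8 members, small
    enough for exhaustive enumeration.
    """
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(1.0, 10.0, 12)).reshape(-1, 1)
    y = (np.arange(12) >= 6).astype(np.int8)
    y[5], y[6] = 1, 0  # overlap so the likelihood is non-degenerate
    return x, y


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def mcv_truth_generator():
    """Single MCV-split treed-logistic ground truth with strong node effects.

    Left of MCV 70 the outcome is mostly bTT with a positive Hb slope;
    right of it mostly IDA with a negative Hb slope (coefficients act on
    the raw scale: intercept, mcv, mch, hb, rdw).
    """
    left = Node(1, model=NodeLogisticModel(   # logit = -6.3 + 0.8*hb
        coefficients=[-6.3, 0.0, 0.0, 0.8, 0.0], prior_sd=20.0))
    right = Node(1, model=NodeLogisticModel(  # logit = -2.5
        coefficients=[-2.5, 0.0, 0.0, 0.0, 0.0], prior_sd=20.0))
    root = Node(0, SplitRule(0, 70.0), left, right)
    ranges = ((55.0, 85.0), (15.0, 30.0), (8.0, 14.0), (10.0, 22.0))
    return TreedGenerator(tree=TreeModel(root), ranges=ranges)
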