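import numpy as np
import pytest

from pathformer.cohort_io import GdaTable, Sample, SignalingCohort, canonical_order
from pathformer.synthetic import SimConfig, generate_cohort


def make_sample(sample_id, expression, label=0):
    return Sample(
        sample_id=sample_id,
        present_genes=frozenset(expression),
        expression=dict(expression),
        label=label,
    )


def set_importance(state, values):
    """Set the importance vector lambda = softplus(theta) to given per-gene values."""
    for gene, lam in values.items():
        state.theta.data[state.universe.h(gene)] = np.log(np.expm1(lam))


@pytest.fixture(scope="session")
def path_cohort():
    """3-gene path A-B-C, two samples, two classes."""
    universe = canonical_order(["A", "B", "C"])
    edges = frozenset({frozenset(("A", "B")), frozenset(("B", "C"))})
    samples = [
        make_sample("s1", {"A": 1.0, "B": 2.0, "C": 3.0}, label=0),
        make_sample("s2", {"A": 4.0, "B": 5.0, "C": 6.0}, label=1),
    ]
    return SignalingCohort(
        universe=universe, edges=edges, samples=samples, class_names=["ctrl", "dis"]
    )


@pytest.fixture(scope="session")
def path_gda():
    return GdaTable(scores={"A": 1.0, "B": 0.5, "C": 0.0})


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 40-gene, 2x12-sample cohort with 5 planted genes."""
    cfg = SimConfig(
        n_genes=40,
        n_samples_per_class=12,
        n_classes=2,
        mean_degree=6,
        n_planted=5,
        effect_size=1.5,
        seed=11,
    )
    cohort, gda, planted = generate_cohort(cfg)
    return cohort, gda, planted
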