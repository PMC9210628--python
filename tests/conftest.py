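import numpy as np
import pandas as pd
import pytest

from pathburden.registry import PathwayCollection, PathwaySet
from pathburden.simulate import (
    CohortSpec,
    EffectSpec,
    demo_pathway_collection,
    generate_study,
)


@pytest.fixture(scope="session")
def demo_coll():
    return demo_pathway_collection(seed=0)


@pytest.fixture(scope="session")
def small_coll():
    """Two small overlapping pathways with simple lengths."""
    lengths = {"A": 1000, "B": 2000, "C": 1500, "D": 500}
    return PathwayCollection(
        [
            PathwaySet("alpha", frozenset({"A", "B"}), lengths),
            PathwaySet("beta", frozenset({"B", "C", "D"}), lengths),
        ]
    )


@pytest.fixture(scope="session")
def small_study(demo_coll):
    """A modest two-cohort study with a burden effect, reused read-only."""
    eff = EffectSpec(or_per_doubling_tmb={"glucocorticoid": 1.5})
    return generate_study(
        demo_coll,
        [CohortSpec(250, "cohortA", seed=1), CohortSpec(250, "cohortB", seed=2)],
        eff,
        seed=99,
        tissues=(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


# TMM factors for the frozen negative-binomial fixture below, computed with
# the reference R implementation of the trimmed-mean method (edgeR
# calcNormFactors, method="TMM") on the identical matrix.
TMM_REFERENCE_FACTORS = [
    1.00393309, 0.97965421, 0.96609924, 0.94373001,
    1.02949215, 1.08644003, 0.93248758, 1.06925444,
]


def make_nb_counts():
    """Deterministic 300 x 8 NB count matrix with depth and composition
    differences (the first 30 genes are 3x up in the first 4 samples)."""
    rng = np.random.default_rng(20260926)
    g, s = 300, 8
    base = rng.lognormal(4, 1.5, g)
    depth = rng.uniform(0.5, 2.0, s)
    mu = np.outer(base, depth)
    mu[:30, :4] *= 3
    phi = 0.2
    counts = rng.poisson(rng.gamma(1 / phi, phi * mu)).astype(int)
    return pd.DataFrame(
        counts,
        index=[f"G{i:03d}" for i in range(g)],
        columns=[f"S{j}" for j in range(s)],
    )


@pytest.fixture(scope="session")
def nb_counts_with_reference():
    return make_nb_counts(), np.array(TMM_REFERENCE_FACTORS)
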