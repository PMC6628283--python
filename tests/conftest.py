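"""Shared fixtures: small hand-built systems and randomised system factories."""

import numpy as np
import pytest

import mamfis as m


@pytest.fixture
def staggered_system() -> m.FuzzySystem:
    """One input, one output, three staggered trapezoids and three rules.

    Input position controls which rules fire and how strongly, so crisp
    outputs sweep through genuinely mixed aggregates.
    """
    mfs_in = (
        m.MembershipFunction("low", "trapezoidal", 0, 0, 2, 5),
        m.MembershipFunction("mid", "triangular", 2, 5, 8),
        m.MembershipFunction("high", "trapezoidal", 5, 8, 10, 10),
    )
    mfs_out = (
        m.MembershipFunction("o1", "trapezoidal", 0, 0, 2, 4),
        m.MembershipFunction("o2", "trapezoidal", 2, 4, 6, 8),
        m.MembershipFunction("o3", "trapezoidal", 6, 8, 10, 10),
    )
    system = m.FuzzySystem(
        name="staggered",
        inputs=[m.FuzzyVariable("x", 0, 10, mfs_in)],
        outputs=[m.FuzzyVariable("z", 0, 10, mfs_out)],
        rules=[
            m.FuzzyRule((1,), (1,)),
            m.FuzzyRule((2,), (2,)),
            m.FuzzyRule((3,), (3,)),
        ],
        resolution=2001,
    )
    system.validate()
    return system


def random_system(rng: np.random.Generator, n_inputs: int = 2) -> m.FuzzySystem:
    """A valid random system built through the cluster->MF pipeline.

    Clustering random training columns guarantees Ruspini coverage, which a
    naive random-breakpoint generator would not.
    """
    n_rows = int(rng.integers(20, 60))
    variables = []
    for i in range(n_inputs + 1):
        values = rng.normal(0, 1, n_rows) * rng.uniform(0.5, 20)
        k = int(rng.integers(2, 5))
        cm = m.cluster_variable(values, k, name=f"v{i + 1}")
        variables.append(m.mfs_from_cluster_model(cm))
    inputs, output = variables[:-1], variables[-1]
    n_rules = int(rng.integers(2, 8))
    rules = [
        m.FuzzyRule(
            tuple(int(rng.integers(1, len(v.mfs) + 1)) for v in inputs),
            (int(rng.integers(1, len(output.mfs) + 1)),),
        )
        for _ in range(n_rules)
    ]
    system = m.FuzzySystem(
        name=f"rand{int(rng.integers(1e6))}",
        inputs=inputs,
        outputs=[output],
        rules=rules,
    )
    system.validate()
    return system


@pytest.fixture
def separable_toy():
    """Two-feature table where feature f1 low/high perfectly predicts class."""
    import pandas as pd

    rng = np.random.default_rng(7)
    n = 40
    cls = np.repeat([1.0, 2.0], n // 2)
    f1 = np.where(cls == 1, rng.uniform(0, 1, n), rng.uniform(4, 5, n))
    f2 = np.where(cls == 1, rng.uniform(10, 12, n), rng.uniform(20, 22, n))
    return pd.DataFrame({"f1": f1, "f2": f2, "class": cls})
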