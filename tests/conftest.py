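import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from paretohits.synthetic import SyntheticSpec, simulate_all

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A scaled-down synthetic benchmark shared across module tests."""
    return SyntheticSpec(
        n_genes=100,
        n_planted=3,
        kg_n_background_nodes=40,
        corpus_size=150,
        n_responders=15,
        n_nonresponders=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return simulate_all(small_spec)


def brute_force_front(points, directions):
    """O(n^2) pairwise-dominance Pareto front oracle (pure Python)."""
    signs = [1.0 if d == "maximize" else -1.0 for d in directions]
    pts = [[s * x for s, x in zip(signs, p)] for p in points]

    def dom(a, b):
        return all(x >= y for x, y in zip(a, b)) and any(
            x > y for x, y in zip(a, b)
        )

    return {
        i
        for i, p in enumerate(pts)
        if not any(dom(q, p) for j, q in enumerate(pts) if j != i)
    }


def brute_force_levels(points, directions):
    """Repeated brute-force front removal; returns per-point levels."""
    levels = [0] * len(points)
    remaining = list(range(len(points)))
    level = 0
    while remaining:
        level += 1
        front_local = brute_force_front([points[i] for i in remaining], directions)
        front = {remaining[i] for i in front_local}
        for i in front:
            levels[i] = level
        remaining = [i for i in remaining if i not in front]
    return levels
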