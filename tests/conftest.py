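import numpy as np
import pytest

from minset import (
    ConservationProblem,
    build_boundary,
    compute_targets,
)


def make_random_problem(
    seed: int,
    n_rows: int = 3,
    n_cols: int = 3,
    n_features: int = 2,
    proportion: float = 0.4,
    blm: float = 0.0,
) -> ConservationProblem:
    """Random grid problem: lognormal costs, uniform feature amounts."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    cost = np.exp(rng.normal(0, 1, n))
    amounts = rng.uniform(0.0, 1.0, (n, n_features))
    pairs, lengths, perim = build_boundary(n_rows, n_cols)
    return ConservationProblem(
        unit_ids=np.arange(1, n + 1),
        cost=cost,
        amounts=amounts,
        targets=compute_targets(amounts, proportion),
        boundary_pairs=pairs,
        boundary_lengths=lengths,
        total_perimeter=perim,
        blm=blm,
        target_proportion=proportion,
    )


@pytest.fixture
def random_problem_factory():
    return make_random_problem


@pytest.fixture
def small_problem():
    """3x3 grid, 2 features, 40% targets, no boundary penalty."""
    return make_random_problem(seed=42)
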