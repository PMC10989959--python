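import numpy as np
import pandas as pd
import pytest

import netperturb as npb


@pytest.fixture(scope="session")
def default_study():
    """Reference synthetic study (default config, seed 1)."""
    return npb.simulate_study(npb.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_perturbation(default_study):
    """(tumor perturbation, normal perturbation, benchmark) for the study."""
    return npb.compute_perturbation(
        default_study.tumor_expr, default_study.normal_expr, default_study.network
    )


@pytest.fixture(scope="session")
def discovery_run(default_study):
    """Full discovery pipeline on the reference study (250 consensus reps)."""
    return npb.run_discovery(
        {"seed": 1, "simulate": {"seed": 1}, "n_reps": 250, "k_p": 1500, "k_sd": 1500}
    )


@pytest.fixture
def toy_expr():
    """3 genes x 2 samples, hand-checkable."""
    return pd.DataFrame(
        [[5.0, 2.0], [1.0, 2.0], [3.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def triangle_net():
    return npb.network_from_edges(
        [("A", "B", 0.9), ("A", "C", 0.9), ("B", "C", 0.9)], min_confidence=0.5
    )


def random_instance(rng, n_genes=20, n_edges=30, n_samples=10):
    """Random expression matrix + network over its genes."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    expr = pd.DataFrame(
        rng.normal(5.0, 2.0, size=(n_genes, n_samples)),
        index=genes,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    pairs = set()
    while len(pairs) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        pairs.add((genes[min(a, b)], genes[max(a, b)]))
    net = npb.network_from_edges(
        [(a, b, 1.0) for a, b in sorted(pairs)], min_confidence=0.5
    )
    return expr, net
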