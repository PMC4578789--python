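import numpy as np
import pandas as pd
import pytest

from mkdos import SimulationConfig, annotate_gene_table, simulate_counts_table


@pytest.fixture(scope="session")
def neutral_genome() -> pd.DataFrame:
    """Annotated 2,000-gene table simulated under strict neutrality."""
    table, _ = simulate_counts_table(
        SimulationConfig(n_genes=2000, adaptive_fraction=0.0, seed=0)
    )
    return annotate_gene_table(table)


@pytest.fixture(scope="session")
def mixed_genome() -> pd.DataFrame:
    """Annotated table with 10% strongly adaptive genes, with truth flags."""
    table, truths = simulate_counts_table(
        SimulationConfig(
            n_genes=2000, adaptive_fraction=0.1, adaptive_boost=10.0, seed=1
        )
    )
    annotated = annotate_gene_table(table)
    annotated["true_adaptive"] = [t.adaptive for t in truths]
    return annotated


def random_mk_table(rng: np.random.Generator, max_total: int = 60):
    """Random nonnegative 2x2 table with bounded total, as cell counts."""
    total = int(rng.integers(0, max_total + 1))
    cuts = np.sort(rng.integers(0, total + 1, size=3))
    a = int(cuts[0])
    b = int(cuts[1] - cuts[0])
    c = int(cuts[2] - cuts[1])
    d = int(total - cuts[2])
    return a, b, c, d
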