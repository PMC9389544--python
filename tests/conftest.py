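import numpy as np
import pandas as pd
import pytest

from metabosubtype.simulate import (
    MetabolomeSimConfig,
    SubtypeSimConfig,
    make_gene_sets,
    simulate_expression_cohort,
    simulate_metabolome_cohort,
)


@pytest.fixture(scope="session")
def expression_cohort():
    """Default 400-sample expression cohort with planted subtypes (seed 7)."""
    cfg = SubtypeSimConfig(seed=7)
    expr, clinical, truth = simulate_expression_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def gene_sets(expression_cohort):
    cfg, *_ = expression_cohort
    return make_gene_sets(cfg)


@pytest.fixture(scope="session")
def metabolome_cohort():
    """Default 112+112 metabolome with 50 up / 100 down planted DEMs (seed 1)."""
    cfg = MetabolomeSimConfig(seed=1)
    matrix, clinical, truth = simulate_metabolome_cohort(cfg)
    return cfg, matrix, clinical, truth


@pytest.fixture
def tiny_metabolome():
    """Hand-built 3x4 positive matrix with two groups."""
    values = pd.DataFrame(
        [[10.0, 12.0, 20.0, 24.0], [5.0, 5.5, 5.2, 5.1], [100.0, 90.0, 110.0, 95.0]],
        index=["m1", "m2", "m3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    from metabosubtype.datatypes import MetaboliteAbundanceMatrix

    return MetaboliteAbundanceMatrix(
        values, group=pd.Series(["GC", "GC", "healthy", "healthy"], index=values.columns)
    )
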