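import numpy as np
import pandas as pd
import pytest

from pairrisk import ExpressionMatrix, SimScenario, simulate_cohort


def small_scenario(**overrides):
    """Desk-scale scenario used across tests; overrides tweak one knob."""
    base = dict(n_tumor=120, n_normal=40, n_lncrna=40, n_immune_gene=30,
                n_de_up=14, n_de_down=2, n_causal_pairs=3,
                causal_betas=(1.0, -1.0, 0.8), rng_seed=11)
    base.update(overrides)
    return SimScenario(**base)


@pytest.fixture(scope="session")
def cohort():
    """One simulated cohort shared by read-only tests."""
    return simulate_cohort(small_scenario())


@pytest.fixture
def tiny_expr():
    """3 genes x 5 samples, 3 tumor + 2 normal, handcrafted values."""
    values = pd.DataFrame(
        [[5.0, 6.0, 7.0, 1.0, 2.0],
         [1.0, 1.5, 2.0, 4.0, 5.0],
         [3.0, 3.0, 3.0, 3.0, 3.0]],
        index=["G1", "G2", "G3"],
        columns=["T1", "T2", "T3", "N1", "N2"])
    group = pd.Series(["tumor"] * 3 + ["normal"] * 2, index=values.columns)
    return ExpressionMatrix(values, group)


def make_expr(values, sample_ids=None, gene_ids=None, group="tumor"):
    values = np.asarray(values, float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    if isinstance(group, str):
        group = pd.Series(group, index=samples)
    else:
        group = pd.Series(list(group), index=samples)
    return ExpressionMatrix(df, group)
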