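import numpy as np
import pandas as pd
import pytest

from scfate import ExpressionMatrix, GenePanel, SyntheticConfig, generate_cells


@pytest.fixture(scope="session")
def panel() -> GenePanel:
    return GenePanel.default()


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: 42 HSC, 7 CMP, 15 PreME, 20 PreMeg."""
    return generate_cells(SyntheticConfig.default(seed=11))


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 12, size=(50, 70))
    vals[rng.random((50, 70)) < 0.3] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"cell{i:03d}" for i in range(50)],
            columns=[f"g{j:03d}" for j in range(70)],
        )
    )


def flat_config(genes, n=20, pi=1.0, mu=5.0, sigma=1.0, seed=0, **kw):
    """Single-population config with uniform parameters and no phase or
    batch structure, for targeted generator checks."""
    pops = kw.pop("populations", ["HSC"])
    counts = kw.pop("cells_per_population", [n] * len(pops))
    cats = {g: "other" for g in genes} if not isinstance(genes, dict) else genes
    cfg = SyntheticConfig(
        populations=pops,
        cells_per_population=counts,
        gene_categories=cats,
        pi={p: {g: pi for g in cats} for p in pops},
        mu={p: {g: mu for g in cats} for p in pops},
        sigma={p: {g: sigma for g in cats} for p in pops},
        phase_fractions={p: {"G0G1": 1.0, "SG2M": 0.0} for p in pops},
        phase_effect=0.0,
        seed=seed,
        **kw,
    )
    cfg.validate()
    return cfg
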