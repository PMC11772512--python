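import numpy as np
import pandas as pd
import pytest

from targetmr.sumstats import SUMSTAT_COLUMNS, SummaryStatSet


def make_frame(rows):
    """Build a summary-stat frame from (snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


def make_stats(rows, trait_id="trait", trait_type="quantitative", region=None):
    return SummaryStatSet(trait_id, trait_type, make_frame(rows), region)


@pytest.fixture(scope="session")
def h4_region():
    """A strongly-powered shared-causal-variant region used across tests."""
    from targetmr.simulate import ScenarioConfig, simulate_region

    cfg = ScenarioConfig(
        "H4", seed=11, n_snps=200, eqtl_var_explained=0.05, causal_effect=1.0
    )
    return simulate_region(cfg, gene_id="G01")


@pytest.fixture(scope="session")
def benchmark20():
    from targetmr.simulate import simulate_benchmark

    return simulate_benchmark(seed=5)
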