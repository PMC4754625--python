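"""Shared fixtures: small synthetic panels and cohorts, generated at test time."""

import numpy as np
import pandas as pd
import pytest

from bcprs.data_model_io import PANEL_COLUMNS, SNPPanel
from bcprs.synthetic_cohort import (SimulationConfig, make_panel,
                                    simulate_cohort, simulate_family_history)


def panel_from_arrays(eaf, beta_overall, beta_erpos=None, beta_erneg=None,
                      region_id=None) -> SNPPanel:
    """Build a panel directly from arrays (for hand-crafted examples)."""
    k = len(eaf)
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(k)],
        "chrom": ["1"] * k,
        "pos": np.arange(1, k + 1) * 1000,
        "effect_allele": ["A"] * k,
        "other_allele": ["G"] * k,
        "eaf": eaf,
        "beta_overall": beta_overall,
        "beta_erpos": beta_erpos if beta_erpos is not None else beta_overall,
        "beta_erneg": beta_erneg if beta_erneg is not None else beta_overall,
        "region_id": region_id if region_id is not None
        else [f"region{i}" for i in range(k)],
    })
    return SNPPanel(df[PANEL_COLUMNS])


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_snps=8, n_cases=800, n_controls=800, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return make_panel(small_cfg)


@pytest.fixture(scope="session")
def small_data(small_cfg, small_panel):
    """(genotypes, cohort) with family history filled, 800 cases / 800 controls."""
    genotypes, cohort = simulate_cohort(small_panel, small_cfg)
    cohort = simulate_family_history(cohort, small_cfg)
    return genotypes, cohort
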