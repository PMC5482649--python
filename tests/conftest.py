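import numpy as np
import pytest

from burdenscan.simulate import (
    FailureRates,
    PlantedSignal,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort at reduced scale, shared across read-only tests."""
    cfg = SimulationConfig(
        n_case=120, n_control=360, n_genes=30, common_snv_count=400,
        x_snv_count=120, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def failure_cohort():
    """Cohort with every QC failure mode injected, for recovery tests."""
    cfg = SimulationConfig(
        n_case=150, n_control=450, n_genes=25, common_snv_count=500,
        x_snv_count=150, seed=13,
        failure_rates=FailureRates(
            missingness_outlier=0.01,
            heterozygosity_outlier=0.008,
            duplicate_pair=0.008,
            sex_mismatch=0.01,
            hwe_violating_site=0.02,
            repeat_proximal_site=0.03,
            low_gq_genotype=0.02,
            allele_imbalanced_het=0.02,
        ),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Study-scale cohort with one planted 16/7 weight-1 gene."""
    cfg = SimulationConfig(
        n_case=513, n_control=1569, n_genes=120, common_snv_count=300,
        x_snv_count=100, seed=29,
        planted_signals=[PlantedSignal(
            gene="G00011", variant_class=3, mode="exact_counts",
            case_carriers=16, control_carriers=7,
        )],
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
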