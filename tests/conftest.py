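import numpy as np
import pandas as pd
import pytest

from qtlallele.association import ScanSettings, two_stage_scan
from qtlallele.simulate import SimulationConfig, simulate_population
from qtlallele.snpldb import (
    build_blocks,
    qc_filter,
    similarity_matrix,
    structure_covariates,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_accessions=150,
        n_chromosomes=6,
        snps_per_chromosome=40,
        n_true_qtls=4,
        heritability_target=0.75,
        master_seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_markers(small_population):
    genotypes, _, _ = small_population
    filtered, _ = qc_filter(genotypes)
    markers = build_blocks(filtered)
    return filtered, markers


@pytest.fixture(scope="session")
def small_scan(small_population, small_markers):
    _, phenotypes, truth = small_population
    filtered, markers = small_markers
    cov = structure_covariates(similarity_matrix(markers), 10)
    result = two_stage_scan(
        markers,
        phenotypes,
        filtered.accessions,
        cov,
        ScanSettings(heritability_cap=truth.realized_h2),
    )
    return result, markers, filtered


def make_plot_table(effects_by_accession, env_effects, ge=None, resid=None, n_rep=2):
    """Balanced plot table from explicit effect arrays (testing helper)."""
    n_acc = len(effects_by_accession)
    n_env = len(env_effects)
    rows = []
    for j in range(n_env):
        for rep in range(n_rep):
            for i in range(n_acc):
                v = effects_by_accession[i] + env_effects[j]
                if ge is not None:
                    v += ge[i, j]
                if resid is not None:
                    v += resid[i, j, rep]
                rows.append(
                    {
                        "accession": f"A{i:03d}",
                        "environment": f"E{j}",
                        "replicate": rep + 1,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)
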