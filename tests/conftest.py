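import numpy as np
import pytest

from hrmhap import datasets, melt_clustering, melt_model, synthetic_data

TEMPS = 65.0 + 0.2 * np.arange(151)


def sigmoid_curve(tm, width=0.7, amplitude=1.0, drift=(0.05, -0.002), noise=0.0, rng=None):
    """Synthetic raw melt curve: drift + two-state sigmoid (+ noise)."""
    f = drift[0] + drift[1] * (TEMPS - TEMPS[0]) + amplitude / (
        1.0 + np.exp((TEMPS - tm) / width)
    )
    if noise > 0:
        f = f + (rng or np.random.default_rng(0)).normal(0, noise, TEMPS.shape)
    return melt_model.MeltCurve(TEMPS, f)


def amp_curve(plateau=1000.0, baseline=20.0, midpoint=22.0):
    cycles = np.arange(1, 41, dtype=float)
    return melt_model.AmplificationCurve(
        cycles, baseline + plateau / (1.0 + np.exp(-(cycles - midpoint) / 2.5))
    )


@pytest.fixture(scope="session")
def population_table():
    return datasets.load_population_table()


@pytest.fixture(scope="session")
def wild_locus_s():
    return datasets.load_wild_locus("atpI-atpH")


@pytest.fixture(scope="session")
def wild_locus_u():
    return datasets.load_wild_locus("ndhA")


@pytest.fixture(scope="session")
def wild_haplotypes():
    return datasets.load_wild_haplotypes()


@pytest.fixture(scope="session")
def trial_matrices():
    return datasets.load_discrimination_trials()


def run_population_screen(table, hapset, seed=1, split_rate=0.0, config_kwargs=None):
    """Simulate one locus screen and cluster it per population."""
    config = synthetic_data.SimConfig(
        seed=seed, duplicate_split_rate=split_rate, **(config_kwargs or {})
    )
    records, truth = synthetic_data.simulate_population_screen(
        table, hapset, synthetic_data.SnpClassModel(), config
    )
    features = {r.well.key: melt_model.normalize_melt(r.melt) for r in records}
    grouping = {r.well.key: r.well.population_id for r in records}
    assignments = melt_clustering.cluster_by_group(features, grouping)
    return records, truth, features, assignments


@pytest.fixture(scope="session")
def screened_run(population_table, wild_locus_u):
    """One default-noise wild-population screen (ndhA), shared across tests."""
    return run_population_screen(population_table, wild_locus_u, seed=1)
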