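import numpy as np
import pandas as pd
import pytest

import fluorosel as fs
from fluorosel.ojip import PLOT_KEYS

N_ENSEMBLE_SEEDS = 25


@pytest.fixture(scope="session")
def paper_config():
    return fs.default_paper_config()


@pytest.fixture(scope="session")
def paper_trial(paper_config):
    design, effects = paper_config
    return fs.generate_trial(design, effects, seed=1)


@pytest.fixture(scope="session")
def paper_jip(paper_trial):
    return fs.jip_table(paper_trial.transients, preset="jip56")


@pytest.fixture(scope="session")
def paper_table(paper_trial, paper_jip):
    _, plot = paper_jip
    return paper_trial.agro.merge(plot, on=PLOT_KEYS)


@pytest.fixture(scope="session")
def ensemble(paper_config):
    """Independent replicate trials of the default study configuration."""
    design, effects = paper_config
    out = []
    for seed in range(N_ENSEMBLE_SEEDS):
        trial = fs.generate_trial(design, effects, seed=seed)
        plant, plot = fs.jip_table(trial.transients, preset="jip56")
        table = trial.agro.merge(plot, on=PLOT_KEYS)
        out.append({"trial": trial, "plant": plant, "table": table})
    return out


def make_balanced_table(
    n_genotypes=4, n_years=2, n_reps=2, seed=0,
    sigma_g=1.0, sigma_gxe=0.5, sigma_e=1.0, year_means=None, blocks=True,
):
    """Random balanced genotype x year x rep table with known effects."""
    rng = np.random.default_rng(seed)
    g = sigma_g * rng.standard_normal(n_genotypes)
    gxe = sigma_gxe * rng.standard_normal((n_genotypes, n_years))
    if year_means is None:
        year_means = 10.0 + np.arange(n_years, dtype=float)
    rows = []
    for i in range(n_genotypes):
        for j in range(n_years):
            for r in range(n_reps):
                row = dict(genotype=f"H{i + 1}", year=2017 + j, rep=r + 1,
                           y=year_means[j] + g[i] + gxe[i, j]
                             + sigma_e * rng.standard_normal())
                if blocks:
                    row["block"] = (i + r) % n_reps + 1
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_table_factory():
    return make_balanced_table
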