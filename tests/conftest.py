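import numpy as np
import pytest

from riverpacs import (
    PredictiveModel,
    cluster_reference_sites,
    compute_group_frequencies,
    run_scenarios,
    select_best_models,
)
from riverpacs import synthetic
from riverpacs.io import load_paper_tables

PREDICTORS = ["water_temperature", "discharge", "altitude", "x", "y"]


def build_pipeline(seed: int, n_cells: int = 2000, n_taxa: int = 40, n_sites: int = 300):
    """Full synthetic pipeline: landscape, niches, model, scenario cube."""
    rng = np.random.default_rng(seed)
    landscape = synthetic.generate_landscape(n_cells=n_cells, n_basins=9, seed=rng)
    niches = synthetic.generate_niches(landscape, n_taxa=n_taxa, seed=rng)
    sites, occ = synthetic.generate_reference_dataset(landscape, niches, n_sites=n_sites, seed=rng)
    keep = occ.sum(axis=1) > 0
    occ, sites = occ[keep], sites[keep]
    groups = cluster_reference_sites(occ, 6, min_group_size=10)
    freq = compute_group_frequencies(occ, groups)
    models = select_best_models(sites, groups, n_models=5, predictors=PREDICTORS, max_subset_size=3)
    pm = PredictiveModel(groups=groups, models=models, frequencies=freq)
    cube = run_scenarios(landscape.cells, pm)
    return landscape, niches, pm, cube


@pytest.fixture(scope="session")
def pipeline():
    return build_pipeline(seed=0)


@pytest.fixture(scope="session")
def paper_tables():
    return load_paper_tables()


@pytest.fixture(scope="session")
def small_landscape():
    return synthetic.generate_landscape(n_cells=400, n_basins=4, seed=11)
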