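import numpy as np
import pytest

from optopore import CellModel, PoreSpec, SimParams, random_pores

#: Printed calibration relations the analysis reproduces.
FLUENCE_RESEALING = (106.3, 2.7, -80.6)      # t = a*exp(f/b) + c, growth
LOADING_VS_TIME = (46.89, 251.87, -48.68)    # % = a*exp(t/b) + c, growth
LOADING_VS_MW = (23.5, 20.3, 4.5)            # % = a*exp(-M/b) + c, decay

FLUENCES = np.array([0.064, 0.32, 0.64, 0.96, 1.28, 1.6])
MOL_WEIGHTS = np.array([5.0, 10.0, 40.0, 70.0, 100.0])


@pytest.fixture(scope="session")
def small_cell() -> CellModel:
    """Multi-pore cell at reduced domain size for fast MC tests."""
    return CellModel(cell_radius=1.0,
                     pores=tuple(random_pores(10, 0.4, seed=7)),
                     domain_radius=2.5)


@pytest.fixture(scope="session")
def one_pore_cell() -> CellModel:
    return CellModel(cell_radius=1.0,
                     pores=(PoreSpec((0.0, 0.0, 1.0), 0.4),),
                     domain_radius=2.5)


@pytest.fixture()
def fast_sim() -> SimParams:
    return SimParams(n_particles=1000, open_time=30.0, n_replicates=4, seed=11)
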