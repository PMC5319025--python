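import numpy as np
import pytest
from dataclasses import replace

from mircrosstalk import (
    PopulationConfig,
    background_correct,
    bin_and_summarize,
    gate_positive,
    generate_population,
)
from mircrosstalk.phenotypes import reference_params


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def cotransfection_base():
    """Model base for synthetic cotransfection runs: a large miRNA pool
    (k_s = 40) places the titration threshold well inside the plasmid-load
    distribution."""
    return replace(reference_params(), k_s=40.0)


@pytest.fixture(scope="session")
def small_populations(cotransfection_base):
    """One regulated (N=4/N=4) and one unregulated (N=0/N=0) population,
    small enough for unit tests; shared across the session."""
    kw = dict(n_cells=6000, n_replicates=3, n_control=3000, g_unit=0.5)
    reg = generate_population(
        PopulationConfig(n_mre_cherry=4, n_mre_cerulean=4, seed=101, **kw),
        cotransfection_base)
    ref = generate_population(
        PopulationConfig(n_mre_cherry=0, n_mre_cerulean=0, seed=102, **kw),
        cotransfection_base)
    return reg, ref


@pytest.fixture(scope="session")
def binned_pair(small_populations):
    reg_tab, ref_tab = small_populations
    reg = bin_and_summarize(gate_positive(background_correct(reg_tab)),
                            n_bins=12, min_cells=40)
    ref = bin_and_summarize(gate_positive(background_correct(ref_tab)),
                            edges=reg.edges, min_cells=40)
    return reg, ref
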