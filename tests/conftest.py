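import numpy as np
import pandas as pd
import pytest

from lipdiff import (
    AnalysisConfig,
    LipDifferentialModel,
    SampleDesign,
    SimulationParams,
    simulate_lip_study,
)
from lipdiff.io import IonTable

TOY_PROTEIN = "MKGGGRAAAKPPPW"


@pytest.fixture(scope="session")
def toy_protein() -> str:
    return TOY_PROTEIN


@pytest.fixture(scope="session")
def small_design() -> SampleDesign:
    return SampleDesign.from_groups({"AU": 10, "AI": 7})


def make_ion_table(rows, design):
    """rows: list of (protein, peptide, ion, {sample: intensity})."""
    recs = []
    for prot, pep, ion, vals in rows:
        rec = {"protein": prot, "peptide": pep, "ion": ion}
        for s in design.sample_ids:
            rec[s] = vals.get(s, np.nan)
        recs.append(rec)
    return IonTable(pd.DataFrame(recs), design)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic study: 200 proteins, 15% planted with |log2| = 2
    effects on 2-4 peptides, 10 vs 7 design, CV 0.20."""
    return simulate_lip_study(params=SimulationParams(seed=2024))


@pytest.fixture(scope="session")
def default_fit(default_sim):
    cfg = AnalysisConfig.for_region("CA1", rng_seed=2024)
    return LipDifferentialModel.from_simulation(default_sim, cfg).fit()
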