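import numpy as np
import pandas as pd
import pytest

from protmed import SimConfig, SummaryTable, simulate_study
from protmed.sumstats import COLUMNS


def make_table(trait_id, rows, trait_type="continuous"):
    """Build a SummaryTable from a list of dicts, filling dialect defaults."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "variant_id": f"rs{i}", "chrom": "1", "pos": 1000 + i * 1000,
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.1, "se": 0.01, "pval": 1e-4, "n": 10000.0,
            "n_case": np.nan, "n_control": np.nan,
        }
        rec.update(row)
        records.append(rec)
    df = pd.DataFrame(records, columns=COLUMNS)
    return SummaryTable(trait_id, trait_type, df)


@pytest.fixture
def mk_table():
    return make_table


@pytest.fixture(scope="session")
def small_study():
    """A compact linked study with one planted mediator (protein P000)."""
    cfg = SimConfig(
        n_proteins=6, n_exposure_qtls=12,
        frac_adiposity_assoc=0.5, frac_outcome_assoc=0.2, seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
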