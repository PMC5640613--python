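import numpy as np
import pandas as pd
import pytest

from clonedriver import SMALL_CONFIG, annotate_cohort, simulate_cohort


def make_cohort(rows):
    """Build a canonical cohort DataFrame from (gene, patient, classification,
    vaf, purity, impact_raw) tuples, with optional ccf/damage overrides."""
    df = pd.DataFrame(
        rows, columns=["gene", "patient", "classification", "vaf", "purity", "impact_raw"]
    )
    df["copy_number"] = 2.0
    df["cnv_ccf"] = np.nan
    df["ccf"] = np.nan
    df["damage"] = np.nan
    return df[
        ["gene", "patient", "classification", "vaf", "purity", "copy_number",
         "cnv_ccf", "impact_raw", "ccf", "damage"]
    ]


@pytest.fixture(scope="session")
def small_sim():
    """One annotated small spiked cohort shared across tests."""
    cohort, truth, ctx = simulate_cohort(SMALL_CONFIG, seed=7)
    return annotate_cohort(cohort), truth, ctx


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from clonedriver import write_fixture_suite

    outdir = tmp_path_factory.mktemp("fixtures")
    write_fixture_suite(outdir, seed=0)
    return outdir
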