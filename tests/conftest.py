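"""Shared fixtures: tiny on-disk cohorts and a fitted demonstration model."""

import warnings

import pytest

import ustscreen as u


TINY_PANEL_CSV = """mirna,enrichment_class
miR-215,gi_enriched
miR-145,gi_enriched
miR-30e-3p,ubiquitous
"""

TINY_COHORT_CSV = """subject_id,group,organ_system,pathology_type
S1,control,none,none
S2,gi_cancer,gi,cancer
"""

TINY_CQ_CSV = """subject_id,mirna,replicate,cq
S1,miR-215,1,30.1
S1,miR-215,2,30.3
S1,miR-215,3,30.2
S1,miR-145,1,29.0
S1,miR-145,2,29.1
S1,miR-145,3,28.9
S1,miR-30e-3p,1,26.0
S1,miR-30e-3p,2,26.1
S1,miR-30e-3p,3,25.9
S2,miR-215,1,28.0
S2,miR-215,2,28.2
S2,miR-215,3,28.1
S2,miR-145,1,29.2
S2,miR-145,2,29.0
S2,miR-145,3,29.1
S2,miR-30e-3p,1,26.2
S2,miR-30e-3p,2,26.0
S2,miR-30e-3p,3,26.1
"""


@pytest.fixture
def tiny_files(tmp_path):
    """Write the 2-subject x 3-miRNA x 3-replicate toy cohort to disk."""
    paths = {
        "cq": tmp_path / "cq.csv",
        "panel": tmp_path / "panel.csv",
        "cohort": tmp_path / "cohort.csv",
    }
    paths["cq"].write_text(TINY_CQ_CSV)
    paths["panel"].write_text(TINY_PANEL_CSV)
    paths["cohort"].write_text(TINY_COHORT_CSV)
    return paths


@pytest.fixture
def tiny_dataset(tiny_files):
    return u.read_cq_table(tiny_files["cq"], tiny_files["panel"], tiny_files["cohort"])


@pytest.fixture(scope="session")
def demo_dataset():
    """One aggregated draw of the demonstration scenario (seed 7)."""
    ds = u.simulate_cohort(u.demo_scenario(seed=7))
    return u.aggregate_replicates(ds)


@pytest.fixture(scope="session")
def fitted_ust(demo_dataset):
    """UST model fitted on the demonstration cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return u.fit_ust(demo_dataset)
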