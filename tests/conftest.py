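import matplotlib
import pandas as pd
import pytest

matplotlib.use("Agg")

from lfqdiff import generate_design, run_synthetic_study


@pytest.fixture(scope="session")
def design10():
    """The standard paired design: 2 bio x 5 tech per condition."""
    return generate_design(2, 5, "A-172")


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study run through all three workflows."""
    return run_synthetic_study(
        seed=11, n_proteins=400, workflows=("A", "B", "C"))


def make_evidence(rows, **defaults):
    """Build a minimal evidence table, filling unspecified columns."""
    base = dict(
        protein_id="P0", gene="G0", run_id="control_b1_t1",
        condition="control", bio_rep=1, tech_rep=1, spectral_count=1,
        summed_intensity=1.0, n_observed_peptides=1, score=5.0,
        passed_fdr_filter=True, is_decoy=False, protein_length=100,
        n_observable_peptides=10,
    )
    base.update(defaults)
    if not rows:
        return pd.DataFrame(columns=list(base))
    return pd.DataFrame([{**base, **row} for row in rows])
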