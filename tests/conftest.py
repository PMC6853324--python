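import numpy as np
import pandas as pd
import pytest

from cd4cvl.cohort import CohortTable


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Three patients: a normal trajectory, a baseline-only patient, and a
    patient with second-line visits and a high baseline CD4."""
    visits = pd.DataFrame(
        {
            "patient_id": ["A", "A", "A", "B", "C", "C", "C", "C", "C"],
            "time_on_art": [0.0, 0.5, 1.0, 0.0, 0.0, 0.5, 1.0, 1.5, 2.0],
            "cd4": [100.0, 150.0, np.nan, 80.0, 520.0, 540.0, 560.0, 580.0, 600.0],
            "viral_load": [50000.0, np.nan, 400.0, 120000.0, 900.0, 50.0, 50.0, 50.0, 50.0],
            "first_line": [True, True, True, True, True, True, True, False, False],
        }
    )
    baselines = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "sex": [1.0, 0.0, np.nan],
            "age": [34.0, 41.0, 29.0],
            "baseline_cd4": [100.0, 80.0, 520.0],
            "baseline_log_vl": [4.7, 5.1, 2.95],
            "in_care": [1, 0, 1],
        }
    )
    return CohortTable(visits, baselines)


@pytest.fixture(scope="session")
def small_slope_fit():
    """A quick, complete-data gaussian slope fit shared by reporting and
    inference tests (module-level work; keep it small)."""
    from cd4cvl import inference, models, simulate

    cfg = simulate.SyntheticConfig(
        n_patients=80,
        missing_vl=0.0,
        missing_cd4=0.0,
        missing_baseline=0.0,
        dropout=0.0,
        seed=42,
    )
    cohort, truth = simulate.generate_cohort(cfg)
    spec = models.ModelSpec(outcome="slope", cvl_adjusted=True)
    design, _, info = inference.prepare_design(cohort, spec)
    fit = inference.fit(
        spec, design, None, inference.McmcConfig(n_chains=2, burn_in=400, n_iter=600, seed=7)
    )
    return {"cohort": cohort, "truth": truth, "spec": spec, "design": design,
            "info": info, "fit": fit}
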