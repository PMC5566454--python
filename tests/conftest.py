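import numpy as np
import pandas as pd
import pytest

from triomix import SimulationConfig, generate_cohort
from triomix.io import SampleSheet


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale cohort: fast to simulate, enough signal to recover."""
    defaults = dict(
        n_patients=12,
        n_probes=4000,
        n_genes=400,
        n_proteins=100,
        n_de_genes=60,
        n_dmrs=10,
        n_diff_proteins=20,
        n_concordant=5,
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def null_config(**overrides) -> SimulationConfig:
    """Complete-null configuration: every planted effect size is zero."""
    return small_config(
        de_log2fc=0.0,
        dmr_delta_beta=0.0,
        protein_effect_log2=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(null_config(seed=2))


def make_sheet(n_patients: int, cohort: str = "discovery") -> SampleSheet:
    rows = []
    for i in range(1, n_patients + 1):
        pid = f"P{i:03d}"
        rows.append((f"{pid}_I", pid, "intact", cohort))
        rows.append((f"{pid}_D", pid, "degraded", cohort))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "status", "cohort"])
    )


def paired_matrix(diffs: np.ndarray, intact_base: float = 0.0) -> tuple[pd.DataFrame, SampleSheet]:
    """Build a features-x-samples matrix realising the given per-patient
    degraded-minus-intact differences exactly."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_feat, n_pat = diffs.shape
    sheet = make_sheet(n_pat)
    cols = {}
    for j in range(n_pat):
        pid = f"P{j + 1:03d}"
        cols[f"{pid}_I"] = np.full(n_feat, intact_base)
        cols[f"{pid}_D"] = intact_base + diffs[:, j]
    values = pd.DataFrame(cols, index=[f"f{i}" for i in range(n_feat)])
    return values[sheet.sample_ids], sheet
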