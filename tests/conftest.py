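import numpy as np
import pandas as pd
import pytest

from silacturnover.io import PEPTIDE_COLUMNS


def _pep_rows(protein, times, peptide_ratios, subject="D01",
              group="control_diabetic", intensity=1e6):
    """Peptide rows for one protein: same peptide ratios at each time."""
    rows = []
    for t in times:
        for j, r in enumerate(peptide_ratios):
            rows.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "time_h": t,
                    "protein_id": protein,
                    "peptide_id": f"{protein}_pep{j}",
                    "ratio_hl": r,
                    "intensity": intensity * (j + 1),
                    "run_id": f"{subject}_t{t:g}",
                }
            )
    return rows


# Peptide triples with exactly controlled across-peptide CV
LOW_CV = (0.4, 0.5, 0.6)        # median 0.5, CV 20%
CV_60 = (0.2, 0.5, 0.8)         # median 0.5, CV 60%  -> excluded
CV_50 = (0.25, 0.5, 0.75)       # median 0.5, CV 50%  -> boundary, retained


@pytest.fixture(scope="session")
def filter_fixture():
    """20-protein cohort with hand-enumerated filter outcomes.

    Returns (peptide table, expected dict) where the expectations list the
    (protein, time) measurements dropped by the 50% measurement-CV filter,
    the protein series passing the 24 h + >=1 other time coverage rule, and
    the proteins whose kinetic fit is reliable (valid k, estimate CV <= 50%).
    """
    rows = []
    all_times = (4.0, 7.5, 24.0)
    # T00-T04: full coverage, low CV -> retained everywhere
    for i in range(5):
        rows += _pep_rows(f"T{i:02d}", all_times, LOW_CV)
    # T05-T07: no 24 h -> excluded by coverage
    for i in range(5, 8):
        rows += _pep_rows(f"T{i:02d}", (4.0, 7.5), LOW_CV)
    # T08-T09: 24 h only -> excluded by coverage
    for i in range(8, 10):
        rows += _pep_rows(f"T{i:02d}", (24.0,), LOW_CV)
    # T10-T11: 24 h + one other -> retained
    for i in range(10, 12):
        rows += _pep_rows(f"T{i:02d}", (4.0, 24.0), LOW_CV)
    # T12-T13: CV 60% at 4 h (measurement dropped), still covered
    for i in range(12, 14):
        rows += _pep_rows(f"T{i:02d}", (4.0,), CV_60)
        rows += _pep_rows(f"T{i:02d}", (7.5, 24.0), LOW_CV)
    # T14: CV 60% at 24 h -> 24 h dropped -> series excluded by coverage
    rows += _pep_rows("T14", (24.0,), CV_60)
    rows += _pep_rows("T14", (4.0, 7.5), LOW_CV)
    # T15: CV exactly 50% everywhere -> retained (strict inequality)
    rows += _pep_rows("T15", all_times, CV_50)
    # T16-T17: single peptide (CV 0) -> retained
    for i in range(16, 18):
        rows += _pep_rows(f"T{i:02d}", all_times, (0.5,))
    # T18: near-zero flat ratios -> k tiny, estimate CV >> 50% -> unreliable
    rows += _pep_rows("T18", all_times, (0.001,))
    # T19: all-zero ratios -> k = 0 -> invalid fit
    rows += _pep_rows("T19", all_times, (0.0,))

    peptides = pd.DataFrame(rows)[PEPTIDE_COLUMNS]
    expected = {
        "cv_dropped": {("T12", 4.0), ("T13", 4.0), ("T14", 24.0)},
        "covered": {
            "T00", "T01", "T02", "T03", "T04",
            "T10", "T11", "T12", "T13",
            "T15", "T16", "T17", "T18", "T19",
        },
        "reliable": {
            "T00", "T01", "T02", "T03", "T04",
            "T10", "T11", "T12", "T13",
            "T15", "T16", "T17",
        },
        "invalid": {"T19"},
    }
    return peptides, expected


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete two-group cohort with ground truth."""
    from silacturnover.simulate import SyntheticConfig, simulate_cohort

    cfg = SyntheticConfig(n_proteins=150, seed=123, force_fail_24h_frac=0.05)
    peptides, truth = simulate_cohort(cfg)
    return peptides, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
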