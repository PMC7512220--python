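import warnings

import pytest

import swathms as sm


def quantify(cohort, **kwargs):
    """Fragment table -> averaged protein x sample matrix (warnings silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = sm.rollup_protein_intensity(cohort.fragments, cohort.runs, **kwargs)
        return sm.average_replicates(sm.total_sum_normalize(raw), cohort.runs)


@pytest.fixture(scope="session")
def planted_cohort():
    """Desk-scale cohort with the study's 11/9 design and a 9-of-11 subgroup."""
    cfg = sm.CohortConfig(
        n_proteins=150,
        n_de_proteins=25,
        peptides_per_protein=(3, 12),
        fragments_per_peptide=(4, 8),
        seed=11,
    )
    return cfg, sm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_averaged(planted_cohort):
    cfg, cohort = planted_cohort
    return cfg, cohort, quantify(cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Same design, no planted effects."""
    cfg = sm.CohortConfig(
        n_proteins=120,
        n_de_proteins=0,
        peptides_per_protein=(3, 10),
        fragments_per_peptide=(4, 7),
        seed=23,
    )
    return cfg, sm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_averaged(null_cohort):
    cfg, cohort = null_cohort
    return cfg, cohort, quantify(cohort)
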