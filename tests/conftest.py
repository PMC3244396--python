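"""Shared fixtures: simulated cohorts at the default study conditions.

Session scope keeps the expensive EM fits to one evaluation for the whole
run; every fixture is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from lcgwas import em_fit, simulate_cohort
from lcgwas.defaults import default_cohort_spec


@pytest.fixture(scope="session")
def printed_cohort():
    """1000 cases at the default class structure, no genotypes."""
    spec = default_cohort_spec(n_null_snps=0, with_planted_snps=False, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def printed_fit(printed_cohort):
    """3-class multi-start EM fit to the default-condition indicators."""
    return em_fit(printed_cohort.indicators, K=3, n_starts=50, seed=42)


@pytest.fixture(scope="session")
def snp_cohort():
    """Cohort with the three planted recessive effects plus 2000 null SNPs."""
    spec = default_cohort_spec(n_null_snps=2000, seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def snp_fit(snp_cohort):
    return em_fit(snp_cohort.indicators, K=3, n_starts=50, seed=7)


def truth_to_canonical(fit, cohort):
    """Map generator class indices to fitted canonical class indices.

    Classes are matched by majority vote of the modal assignment against the
    generative truth labels.
    """
    from lcgwas import modal_assignment

    assign = modal_assignment(fit.posteriors)
    truth = cohort.truth.true_class
    mapping = {}
    for t in np.unique(truth):
        vals, counts = np.unique(assign[truth == t], return_counts=True)
        mapping[int(t)] = int(vals[np.argmax(counts)])
    return mapping
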