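"""Shared fixtures and independent reference implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedsoil.simulate import CohortDesign, SimulatedCohort, generate, write_fixture


def naive_ssgsea_es(values: dict[str, float], members: set[str],
                    alpha: float = 0.25) -> float:
    """Literal, loop-based running-sum enrichment score.

    Kept deliberately independent of the package implementation: explicit
    sort, explicit 1-based walk down the ranked list.
    """
    order = sorted(values, key=lambda g: (-values[g], g))
    n = len(order)
    n_in = sum(1 for g in order if g in members)
    assert 0 < n_in < n
    total_in_weight = sum(
        (n - i + 1) ** alpha
        for i, g in enumerate(order, start=1)
        if g in members
    )
    es = 0.0
    running_in = 0.0
    running_out = 0
    for i, g in enumerate(order, start=1):
        if g in members:
            running_in += (n - i + 1) ** alpha
        else:
            running_out += 1
        es += running_in / total_in_weight - running_out / (n - n_in)
    return es


def small_design(seed: int = 0, **overrides) -> CohortDesign:
    """A scaled-down cohort for fast tests (same structure as the default)."""
    kwargs = dict(
        n_genes=800,
        module_sizes={"emt_angio": 40, "immune": 40,
                      "metabolism_cellcycle": 40, "ln_fibrosis": 9},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@pytest.fixture(scope="session")
def default_cohort() -> SimulatedCohort:
    return generate(CohortDesign(seed=7))


@pytest.fixture(scope="session")
def small_cohort() -> SimulatedCohort:
    return generate(small_design(seed=11))


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    write_fixture(small_cohort, outdir)
    return outdir


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
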