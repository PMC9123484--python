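"""Shared fixtures: grids, synthetic cohorts (generated at test time)."""

from __future__ import annotations

import dataclasses

import pytest

from perifield import Eye, build_grid, default_rpgr_config, generate_cohort, table1_fixture


@pytest.fixture(scope="session")
def od_grid():
    return build_grid(Eye.OD)


@pytest.fixture(scope="session")
def os_grid():
    return build_grid(Eye.OS)


@pytest.fixture(scope="session")
def default_config():
    return default_rpgr_config(seed=1)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Default 10-subject cohort: (exams, cohort frame)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """200-subject recovery cohort with a fixed seed."""
    cfg = dataclasses.replace(default_config, n_subjects=200, seed=7)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()
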