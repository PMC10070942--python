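"""Shared fixtures: small synthetic embryos and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from morphodyn import synthetic as sy


@pytest.fixture(scope="session")
def small_spec() -> sy.EmbryoSpec:
    """Desk-scale eggshell for fast rendering (~20k interior voxels)."""
    return sy.EmbryoSpec(
        eggshell_semi_axes=(11.5, 7.5, 7.5),
        voxel_spacing=(0.5, 0.5, 0.5),
        n_frames=80,
    )


@pytest.fixture(scope="session")
def default_tree():
    spec = sy.EmbryoSpec(n_frames=140)
    prog = sy.default_program()
    return sy.generate_lineage(prog, spec, seed=7), prog, spec


@pytest.fixture(scope="session")
def small_cohort() -> list[sy.SyntheticEmbryo]:
    """Six-embryo analytic cohort for cross-module integration tests."""
    cfg = sy.CohortConfig(n_embryos=6)
    return sy.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def recovery_cohort() -> list[sy.SyntheticEmbryo]:
    """32-embryo analytic cohort at the default study conditions."""
    cfg = sy.CohortConfig(n_embryos=32)
    return sy.simulate_cohort(cfg, seed=5)


def tracks_and_trees(cohort):
    return (
        {e.embryo_id: e.tracks for e in cohort},
        {e.embryo_id: e.tree for e in cohort},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (no cross-test state)."""
    return np.random.default_rng(1234)
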