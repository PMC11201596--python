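"""Shared fixtures: small synthetic cohorts with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import netfingerprint as nf


@pytest.fixture(scope="session")
def planted_cohort():
    """A compact cohort with one strong planted edge of each sign.

    120 subjects, 16 nodes, 80 frames, effect large enough that both edges
    are reliably detectable; used by CPM/anatomy tests that need signal.
    """
    cfg = nf.SimulationConfig(
        n_subjects=120,
        n_nodes=16,
        frames_per_block=20,
        n_blocks_per_condition=4,
        planted_pos_edges=((0, 1),),
        planted_neg_edges=((2, 3),),
        effect_size=0.08,
        base_connectivity=0.2,
        conditions=("punishment",),
        seed=11,
    )
    measures, covariates, series, truth = nf.simulate_cohort(cfg)
    mats = np.asarray(
        [nf.connectivity_matrix(series["punishment"][i]).values
         for i in range(cfg.n_subjects)]
    )
    return cfg, measures, covariates, mats, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted structure (pure noise edges)."""
    cfg = nf.SimulationConfig(
        n_subjects=80,
        n_nodes=12,
        frames_per_block=20,
        n_blocks_per_condition=3,
        conditions=("punishment",),
        seed=23,
    )
    measures, covariates, series, truth = nf.simulate_cohort(cfg)
    mats = np.asarray(
        [nf.connectivity_matrix(series["punishment"][i]).values
         for i in range(cfg.n_subjects)]
    )
    return cfg, measures, covariates, mats, truth
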