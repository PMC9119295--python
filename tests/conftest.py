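"""Shared fixtures: small, fast synthetic cohorts fitted once per session."""

from __future__ import annotations

import numpy as np
import pytest

import eigenembryo as ee

# reduced-size rendering used throughout the suite: the smallest canvas the
# generator accepts, with the embryo filling most of it
SMALL = dict(image_side=64, embryo_radius_range=(20, 26))


def fit_cohort(cfg: ee.CohortConfig):
    """Simulate + preprocess + fit; returns (records, meta, model, labels)."""
    records, meta = ee.simulate_cohort(cfg)
    model = ee.fit_pca(ee.build_matrix(records))
    return records, meta, model, labels_of(meta)


def labels_of(meta) -> np.ndarray:
    return meta["hcg"].to_numpy().astype(int)


@pytest.fixture(scope="session")
def moderate_cohort():
    """60+60 cohort with a paper-strength grainy<->hCG association."""
    cfg = ee.CohortConfig(n_positive=60, n_negative=60,
                          p_grainy_given_pos=0.65, p_grainy_given_neg=0.38,
                          seed=11, **SMALL)
    return fit_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """60+60 cohort in which graininess is independent of hCG."""
    cfg = ee.CohortConfig(n_positive=60, n_negative=60,
                          p_grainy_given_pos=0.5, p_grainy_given_neg=0.5,
                          seed=123, **SMALL)
    return fit_cohort(cfg)


@pytest.fixture(scope="session")
def paper_mirror_meta():
    """Metadata of a 129+105 cohort with exact per-stratum counts.

    The fragmentation/graininess cross-tab is deterministic: all 110
    non-grainy embryos carry >=20% fragmentation and none of the 124
    grainy ones do.
    """
    cfg = ee.paper_scale_config(seed=5, **SMALL)
    _, meta = ee.simulate_cohort(cfg)
    return meta
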