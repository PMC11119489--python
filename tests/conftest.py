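import dataclasses

import numpy as np
import pytest

import sxt_celltyper as sxt
from sxt_celltyper.synthetic import DEFAULT_SEED


def small_cohort_config(n_alpha=2, n_beta=2, vesicles=120.0, voxel_size=40.0):
    """A scaled-down cohort (small cells, few vesicles) for fast voxel tests."""
    cfg = sxt.default_config(voxel_size=voxel_size)
    cfg.alpha = dataclasses.replace(
        cfg.alpha, n_cells=n_alpha, cell_volume=(220.0, 30.0),
        vesicle_count=(vesicles, vesicles * 0.1),
    )
    cfg.beta = dataclasses.replace(
        cfg.beta, n_cells=n_beta, cell_volume=(300.0, 40.0),
        vesicle_count=(vesicles, vesicles * 0.1),
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_cohort_config()


@pytest.fixture(scope="session")
def small_voxel_cohort(small_config):
    """Four small voxel phantoms with ground truth (a few seconds)."""
    return sxt.generate_cohort(small_config, seed=404)


@pytest.fixture(scope="session")
def default_feature_cohort():
    """The full default synthetic cohort in fast feature-table mode."""
    cfg = sxt.default_config()
    return sxt.generate_vesicle_features(cfg, seed=DEFAULT_SEED)


def match_detections_to_truth(vesicles, truth, voxel_size):
    """Greedy center-proximity matching of segmented components to ground truth.

    A detection matches a true vesicle when its centroid lies within the true
    radius of the true center.  Returns (precision, recall).
    """
    from scipy.spatial import cKDTree

    if not vesicles:
        return 0.0, 0.0
    centers = np.array([v.center() for v in vesicles])
    tree = cKDTree(truth.centers)
    dist, idx = tree.query(centers)
    matched = dist < (truth.diameters[idx] / 2.0) / voxel_size
    precision = float(matched.mean())
    recall = len(set(idx[matched])) / len(truth.diameters)
    return precision, recall
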