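import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import sxt_celltyper as sxt
from sxt_celltyper.extraction import (
    MODE_BIN_WIDTH,
    SegmentedVesicle,
    _check_record_invariants,
    vesicle_table,
)
from sxt_celltyper.volumes import TomogramVolume

from conftest import match_detections_to_truth


# ---------------------------------------------------------------------------
# equivalent diameter
# ---------------------------------------------------------------------------


def test_equivalent_diameter_closed_form():
    assert sxt.equivalent_diameter(1, 35.0) == pytest.approx(35.0 * (6 / np.pi) ** (1 / 3))
    # volume consistency: d^3 * pi/6 == n * voxel^3
    d = sxt.equivalent_diameter(123, 40.0)
    assert d**3 * np.pi / 6 == pytest.approx(123 * 40.0**3)


def test_equivalent_diameter_monotone_and_validated():
    d = sxt.equivalent_diameter(np.arange(1, 50), 35.0)
    assert np.all(np.diff(d) > 0)
    with pytest.raises(ValueError):
        sxt.equivalent_diameter(0, 35.0)


# ---------------------------------------------------------------------------
# 11-parameter LAC statistics
# ---------------------------------------------------------------------------


def brute_force_stats(values):
    """Independent reference for the 11 LAC parameters (scipy/numpy route)."""
    x = np.asarray(values, float)
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    degenerate = len(x) < 3 or sd == 0
    from collections import Counter

    counts = Counter(int(np.floor(v / MODE_BIN_WIDTH)) for v in x)
    best = max(counts.values())
    mode_bin = min(b for b, c in counts.items() if c == best)
    return {
        "lac_min": x.min(),
        "lac_q25": q25,
        "lac_mean": x.mean(),
        "lac_q75": q75,
        "lac_max": x.max(),
        "lac_mode": (mode_bin + 0.5) * MODE_BIN_WIDTH,
        "lac_median": med,
        "lac_sd": sd,
        "lac_skew": 0.0 if degenerate else sps.skew(x, bias=True),
        "lac_kurtosis": 0.0 if degenerate else sps.kurtosis(x, fisher=True, bias=True),
        "lac_iqr": q75 - q25,
    }


def test_constant_input_is_degenerate():
    out = sxt.vesicle_lac_stats([0.30] * 8)
    for k in ("lac_min", "lac_q25", "lac_mean", "lac_q75", "lac_max", "lac_median"):
        assert out[k] == pytest.approx(0.30)
    # the binned-mode rule reports the centre of the occupied 0.005-wide bin
    assert abs(out["lac_mode"] - 0.30) <= MODE_BIN_WIDTH
    assert out["lac_sd"] == 0 and out["lac_iqr"] == 0
    assert out["lac_skew"] == 0 and out["lac_kurtosis"] == 0
    assert out["degenerate"]


def test_five_value_example_against_oracle():
    vals = [0.30, 0.32, 0.34, 0.36, 0.38]
    out = sxt.vesicle_lac_stats(vals)
    ref = brute_force_stats(vals)
    assert out["lac_mean"] == pytest.approx(0.34)
    for k, v in ref.items():
        assert out[k] == pytest.approx(v, rel=1e-12, abs=1e-12), k


@pytest.mark.parametrize("n", [1, 2, 3, 7, 30, 100])
def test_random_inputs_match_oracle(n):
    rng = np.random.default_rng(n)
    for _ in range(10):
        vals = rng.uniform(0.1, 0.6, n)
        out = sxt.vesicle_lac_stats(vals)
        ref = brute_force_stats(vals)
        for k, v in ref.items():
            assert out[k] == pytest.approx(v, rel=1e-12, abs=1e-12), k


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False, width=32), min_size=1, max_size=60))
def test_quantile_chain_and_iqr_identity(values):
    out = sxt.vesicle_lac_stats(values)
    assert out["lac_min"] <= out["lac_q25"] + 1e-12
    assert out["lac_q25"] <= out["lac_median"] + 1e-12
    assert out["lac_median"] <= out["lac_q75"] + 1e-12
    assert out["lac_q75"] <= out["lac_max"] + 1e-12
    assert out["lac_iqr"] == out["lac_q75"] - out["lac_q25"]
    assert out["lac_min"] - MODE_BIN_WIDTH <= out["lac_mode"] <= out["lac_max"] + MODE_BIN_WIDTH
    with pytest.raises(ValueError):
        sxt.vesicle_lac_stats([])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def sphere_volume(shape, centers_radii_lacs, cytosol=0.24, voxel_size=35.0):
    """Hand-built test volume: spheres on a uniform cytosol background."""
    lac = np.full(shape, cytosol, dtype=np.float32)
    labels = np.ones(shape, dtype=np.uint8)
    idx = np.indices(shape)
    for (c, r, v) in centers_radii_lacs:
        dist = np.sqrt(sum((idx[i] - c[i]) ** 2 for i in range(3))) * voxel_size
        lac[dist <= r] = v
    return TomogramVolume(lac=lac, voxel_size=voxel_size, labels=labels, cell_id="toy")


def test_single_sphere_on_threshold_background_yields_one_component():
    # 200 nm sphere at 0.37 on 0.24 cytosol; the glucagon window's lower
    # bound sits exactly at the background level and must not flood the cell
    vol = sphere_volume((40, 40, 40), [((20, 20, 20), 100.0, 0.37)])
    labels, ves = sxt.segment_vesicles(vol, lac_window=(0.24, 0.50))
    assert len(ves) == 1
    assert labels.max() == 1
    d = sxt.equivalent_diameter(ves[0].n_voxels, vol.voxel_size)
    assert d == pytest.approx(200.0, abs=vol.voxel_size)


def test_fused_cluster_over_500nm_is_excluded():
    # a chain of three fused cores whose union exceeds the volume of a
    # 500 nm sphere is excluded as one oversized component, even though each
    # core alone would have been retained
    chain = [((20, 20, 10 + 7 * i), 200.0, 0.37) for i in range(3)]
    vol = sphere_volume((40, 40, 40), chain, cytosol=0.15)
    _, ves = sxt.segment_vesicles(vol, lac_window=(0.24, 0.50))
    assert ves == []
    single = sphere_volume((40, 40, 40), chain[:1], cytosol=0.15)
    _, ves_single = sxt.segment_vesicles(single, lac_window=(0.24, 0.50))
    assert len(ves_single) == 1


def test_sub_100nm_component_is_excluded():
    vol = sphere_volume((30, 30, 30), [((15, 15, 15), 40.0, 0.37)], cytosol=0.15)
    _, ves = sxt.segment_vesicles(vol)
    assert ves == []


def test_empty_cell_mask_errors_and_no_candidates_is_empty():
    vol = sphere_volume((20, 20, 20), [], cytosol=0.15)
    _, ves = sxt.segment_vesicles(vol)  # nothing in window -> empty, no error
    assert ves == []
    vol.labels[:] = 0
    with pytest.raises(ValueError):
        sxt.segment_vesicles(vol)


def test_nucleus_voxels_are_excluded_from_segmentation():
    vol = sphere_volume((30, 30, 30), [((15, 15, 15), 150.0, 0.37)], cytosol=0.15)
    vol.labels[vol.lac > 0.3] = 2  # mark the sphere as nucleus
    _, ves = sxt.segment_vesicles(vol)
    assert ves == []


def test_detection_recall_precision_on_phantom_cohort(small_voxel_cohort):
    """Segmented components match ground-truth vesicles by center proximity."""
    for vol, truth in small_voxel_cohort:
        _, ves = sxt.segment_vesicles(vol)
        precision, recall = match_detections_to_truth(ves, truth, vol.voxel_size)
        assert precision >= 0.95
        assert recall >= 0.95


def test_rasterized_diameter_within_one_voxel(small_voxel_cohort):
    vol, truth = small_voxel_cohort[0]
    _, ves = sxt.segment_vesicles(vol)
    from scipy.spatial import cKDTree

    tree = cKDTree(truth.centers)
    for v in ves:
        d_meas = sxt.equivalent_diameter(v.n_voxels, vol.voxel_size)
        _, i = tree.query(v.center())
        assert abs(d_meas - truth.diameters[i]) <= 1.5 * vol.voxel_size


def test_size_filters_hold_on_all_extracted_records(small_voxel_cohort):
    extractor = sxt.VesicleExtractor()
    table = extractor.transform([vol for vol, _ in small_voxel_cohort])
    assert (table.diameter >= 100.0).all() and (table.diameter <= 500.0).all()
    _check_record_invariants(table)  # quantile chain + iqr on every record


# ---------------------------------------------------------------------------
# cell metrics
# ---------------------------------------------------------------------------


def make_masked_volume(n_cell, n_nucleus, voxel_size=35.0):
    side = int(np.ceil((n_cell) ** (1 / 3))) + 2
    labels = np.zeros((side, side, side), np.uint8)
    flat = labels.reshape(-1)
    flat[:n_cell] = 1
    flat[:n_nucleus] = 2
    lac = np.full(labels.shape, 0.24, np.float32)
    return TomogramVolume(lac=lac, voxel_size=voxel_size, labels=labels, cell_id="m")


def test_nuclear_occupancy_matches_volume_ratio():
    # a nucleus a tenth of the cell -> occupancy 9.9%
    vol = make_masked_volume(n_cell=1000, n_nucleus=99)
    m = sxt.cell_metrics(vol, pd.DataFrame(columns=["n_voxels", "diameter", "lac_mean"]))
    assert m.nuclear_occupancy == pytest.approx(9.9)
    assert m.cytosol_volume == pytest.approx(m.cell_volume - m.nucleus_volume)


def test_occupancy_limit_and_error():
    # nucleus = cell minus one voxel -> occupancy approaches the 100% limit
    vol = make_masked_volume(n_cell=1000, n_nucleus=999)
    m = sxt.cell_metrics(vol, pd.DataFrame(columns=["n_voxels", "diameter", "lac_mean"]))
    assert m.nuclear_occupancy == pytest.approx(99.9)
    # a nucleus consuming the whole cell is rejected at construction
    with pytest.raises(ValueError):
        make_masked_volume(n_cell=1000, n_nucleus=1000)


def test_phantom_volumes_match_ground_truth(small_voxel_cohort):
    """Mask-derived volumes agree with analytic ground truth (rasterization)."""
    for vol, truth in small_voxel_cohort:
        labels, ves = sxt.segment_vesicles(vol)
        m = sxt.cell_metrics(vol, vesicle_table(vol, ves), labels)
        # one voxel layer over the sphere surface bounds the rasterization error
        r_nm = (3 * truth.cell_volume / (4 * np.pi)) ** (1 / 3) * 1000
        layer = 4 * np.pi * r_nm**2 * vol.voxel_size * 1e-9  # um3
        assert abs(m.cell_volume - truth.cell_volume) < layer
        assert abs(m.nucleus_volume - truth.nucleus_volume) < layer
        # true vesicles just above the 100 nm floor may rasterize below it
        assert 0.95 * len(truth.diameters) <= m.vesicle_count <= len(truth.diameters)
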