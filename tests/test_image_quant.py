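"""Segmentation, gating and contribution arithmetic on known images."""

import numpy as np
import pandas as pd
import pytest

from leachresp import image_quant as iq
from leachresp.simulate import CellGroupSpec, FovParams, simulate_fov_set

from conftest import quantify_fovs


def _mg(px, channel="dapi", **kw):
    kw.setdefault("fov_id", "f0")
    kw.setdefault("sample_id", "S")
    return iq.Micrograph(np.asarray(px), channel, **kw)


# ---------------------------------------------------------------------------
# segmentation


def test_segment_blank_image_yields_no_cells():
    labels = iq.segment_cells(_mg(np.zeros((32, 32), np.uint8)))
    assert labels.max() == 0


def test_segment_two_disks_two_labels():
    img = np.zeros((40, 40), np.uint8)
    img[5:10, 5:10] = 200
    img[25:32, 25:32] = 180
    labels = iq.segment_cells(_mg(img))
    assert labels.max() == 2


def test_segment_min_area_drops_specks():
    img = np.zeros((30, 30), np.uint8)
    img[2, 2] = 255  # single pixel
    img[10:16, 10:16] = 255
    labels = iq.segment_cells(_mg(img), min_area_px=5)
    assert labels.max() == 1
    assert labels[2, 2] == 0


def test_segment_recovers_planted_cell_count():
    params = FovParams(noise_sd=2.0, n_cells=40, shape=(192, 192))
    fovs, truth = simulate_fov_set(params, n_fov=2, probes=["EUB338"], seed=3)
    for fov, (_, sub) in zip(
        fovs["EUB338"], truth.groupby("fov_id", sort=True)
    ):
        labels = iq.segment_cells(fov["dapi"])
        assert labels.max() == len(sub)


# ---------------------------------------------------------------------------
# mean grey value


def test_mgv_uniform_and_two_pixel_cells():
    labels = np.array([[1, 1, 0], [0, 2, 2]])
    img = np.array([[7, 7, 9], [9, 10, 20]], float)
    assert iq.mean_grey_value(labels, img, 1) == pytest.approx(7.0)
    assert iq.mean_grey_value(labels, img, 2) == pytest.approx(15.0)
    with pytest.raises(KeyError):
        iq.mean_grey_value(labels, img, 5)


def test_mgv_equals_pixel_loop_oracle_on_random_images():
    rng = np.random.default_rng(0)
    for _ in range(5):
        labels = rng.integers(0, 4, size=(20, 20))
        img = rng.integers(0, 255, size=(20, 20)).astype(float)
        for cid in np.unique(labels[labels > 0]):
            total, count = 0.0, 0
            for i in range(20):
                for j in range(20):
                    if labels[i, j] == cid:
                        total += img[i, j]
                        count += 1
            assert iq.mean_grey_value(labels, img, cid) == total / count


# ---------------------------------------------------------------------------
# gating


def _gated_fixture():
    """One 3-cell FOV: bright, dim and background-level BONCAT signals."""
    labels = np.zeros((30, 30), np.int32)
    labels[2:6, 2:6] = 1
    labels[10:14, 10:14] = 2
    labels[20:24, 20:24] = 3
    dapi = np.where(labels > 0, 200, 10).astype(np.uint8)
    boncat = np.full((30, 30), 10, np.uint8)
    boncat[labels == 1] = 150
    boncat[labels == 2] = 60
    # cell 3 stays at background level
    fish = np.full((30, 30), 10, np.uint8)
    fish[labels == 1] = 120
    return labels, _mg(dapi), _mg(boncat, "boncat"), _mg(fish, "fish", probe_id="P")


def test_gate_background_level_cell_is_boncat_negative():
    labels, dapi, boncat, fish = _gated_fixture()
    cells = iq.gate_cells(labels, dapi, boncat, fish)
    by_id = cells.set_index("cell_id")
    assert bool(by_id.loc[1, "boncat_pos"]) and bool(by_id.loc[2, "boncat_pos"])
    assert not by_id.loc[3, "boncat_pos"]
    assert bool(by_id.loc[1, "fish_pos"]) and not by_id.loc[2, "fish_pos"]


def test_gate_zero_threshold_makes_all_cells_positive():
    labels, dapi, boncat, fish = _gated_fixture()
    cells = iq.gate_cells(
        labels, dapi, boncat, fish,
        boncat_threshold_policy=iq.FixedThreshold(0.0),
    )
    assert cells["boncat_pos"].all()


def test_boncat_positive_implies_dapi_positive(two_group_fovs):
    fovs, _ = two_group_fovs
    for probe in fovs:
        cells = quantify_fovs(fovs[probe])
        assert (cells.loc[cells["boncat_pos"], "dapi_pos"]).all()


# ---------------------------------------------------------------------------
# sample- and group-level summaries


def _cells(mgvs, fish_flags, boncat_flags=None):
    n = len(mgvs)
    boncat_flags = [True] * n if boncat_flags is None else boncat_flags
    return pd.DataFrame(
        {
            "cell_id": range(1, n + 1),
            "mgv_boncat": mgvs,
            "dapi_pos": [True] * n,
            "boncat_pos": boncat_flags,
            "fish_pos": fish_flags,
        }
    )


def test_sample_activity_examples_and_linearity():
    cells = _cells([10, 20], [False, False])
    assert iq.sample_activity(cells, 2) == pytest.approx(15.0)
    assert iq.sample_activity(_cells([], []), 3) == 0.0
    doubled = cells.assign(mgv_boncat=cells["mgv_boncat"] * 2)
    assert iq.sample_activity(doubled, 2) == pytest.approx(30.0)
    with pytest.raises(ValueError):
        iq.sample_activity(cells, 0)


def test_group_activity_contribution_examples():
    cells = _cells([10, 20, 30], [True, True, False])
    assert iq.group_activity_contribution(cells) == pytest.approx(0.5)
    assert iq.group_activity_contribution(
        _cells([5, 5], [True, True])
    ) == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        iq.group_activity_contribution(_cells([5], [True], [False]))


def test_group_abundance_contribution_examples():
    assert iq.group_abundance_contribution(
        _cells([1, 1, 1, 1], [False] * 4)
    ) == 0.0
    assert iq.group_abundance_contribution(
        _cells([1, 1], [True, True])
    ) == 1.0
    assert iq.group_abundance_contribution(
        _cells([1] * 5, [True, True, False, False, False])
    ) == pytest.approx(0.4)


def test_activity_ratio_three_to_one_recovered(two_group_fovs):
    """Equal cell numbers, MGV ratio 3:1 -> contributions 0.75/0.25."""
    fovs, _ = two_group_fovs
    c1 = iq.group_activity_contribution(quantify_fovs(fovs["P1"]))
    c2 = iq.group_activity_contribution(quantify_fovs(fovs["P2"]))
    assert c1 == pytest.approx(0.75, abs=0.02)
    assert c2 == pytest.approx(0.25, abs=0.02)


# ---------------------------------------------------------------------------
# nested probe resolution and the abundance/activity comparison


def _per_probe_table(values):
    rows = []
    for probe, (act, ab) in values.items():
        rows.append(
            {"sample_id": "S", "probe_id": probe,
             "contribution_activity": act, "contribution_abundance": ab}
        )
    return pd.DataFrame(rows)


def test_resolve_nested_subtracts_children():
    panel = iq.default_probe_panel()
    table = _per_probe_table(
        {
            "GAM42a": (0.5, 0.4), "ALT1413": (0.2, 0.1),
            "Alf968": (0.3, 0.35), "ROS537": (0.3, 0.35),
            "CF319a": (0.1, 0.15),
        }
    )
    out = iq.resolve_nested_groups(table, panel).set_index("group")
    assert out.loc["Other Gammaproteobacteria", "contribution_activity"] == pytest.approx(0.3)
    assert out.loc["Alteromonadales", "contribution_activity"] == pytest.approx(0.2)
    # child equals parent -> derived category collapses to zero
    assert out.loc["Other Alphaproteobacteria", "contribution_activity"] == pytest.approx(0.0)
    assert out["contribution_activity"].sum() == pytest.approx(1.0, abs=1e-9)
    assert out["contribution_abundance"].sum() == pytest.approx(1.0, abs=1e-9)


def test_resolve_nested_clips_inconsistent_child(caplog):
    panel = iq.default_probe_panel()
    table = _per_probe_table(
        {
            "GAM42a": (0.2, 0.2), "ALT1413": (0.4, 0.4),  # child > parent
            "Alf968": (0.3, 0.3), "ROS537": (0.1, 0.1),
            "CF319a": (0.1, 0.1),
        }
    )
    out = iq.resolve_nested_groups(table, panel).set_index("group")
    assert out.loc["Other Gammaproteobacteria", "contribution_activity"] >= 0.0
    assert out["contribution_activity"].sum() == pytest.approx(1.0, abs=1e-9)


def test_full_panel_contributions_close_on_synthetic_sample():
    params = FovParams(n_cells=60)
    fovs, _ = simulate_fov_set(params, n_fov=2, seed=4)
    rows = []
    for probe, fov_list in fovs.items():
        cells = quantify_fovs(fov_list)
        rows.append(
            {
                "sample_id": "S1", "probe_id": probe,
                "contribution_activity": iq.group_activity_contribution(cells),
                "contribution_abundance": iq.group_abundance_contribution(cells),
            }
        )
    out = iq.resolve_nested_groups(pd.DataFrame(rows), iq.default_probe_panel())
    sums = out.groupby("sample_id")[
        ["contribution_activity", "contribution_abundance"]
    ].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_abundance_vs_activity_deviation_sign():
    table = pd.DataFrame(
        {
            "sample_id": ["S", "S"],
            "group": ["equal", "inactive"],
            "contribution_abundance": [0.3, 0.3],
            "contribution_activity": [0.3, 0.0],
        }
    )
    out = iq.abundance_vs_activity(table).set_index("group")
    assert out.loc["equal", "deviation"] == pytest.approx(0.0)
    assert out.loc["inactive", "deviation"] == pytest.approx(-0.3)


def test_boncat_density_per_fov_and_scaling():
    cells = _cells([1] * 60, [False] * 60)
    out = iq.boncat_positive_density(cells, 12)
    assert out["per_fov"] == pytest.approx(5.0)
    scaled = iq.boncat_positive_density(
        cells, 12, volume_mL=2.0, filter_area=100.0, fov_area=0.5
    )
    assert scaled["per_mL"] == pytest.approx(5.0 * 200 / 2.0)
    with pytest.raises(ValueError):
        iq.boncat_positive_density(cells, 12, volume_mL=-1, filter_area=1, fov_area=1)


def test_probe_panel_rejects_cycles_and_unknown_probes():
    with pytest.raises(ValueError):
        iq.ProbePanel(targets={"A": "x", "B": "y"}, nesting={"A": "B", "B": "A"},
                      universal="A")
    with pytest.raises(ValueError):
        iq.ProbePanel(targets={"A": "x"}, nesting={"A": "Z"}, universal="A")
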