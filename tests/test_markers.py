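import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combodex import datasets
from combodex.markers import (
    MarkerPanel,
    QPCRMeasurement,
    QuadrantCounts,
    fold_change,
    pearson_r,
    percent_change,
    read_marker_table,
    read_qpcr_table,
    relative_quantity,
    total_apoptosis,
)

groups = st.lists(st.floats(0.1, 100.0), min_size=2, max_size=6)


class TestFoldAndPercentChange:
    def test_identical_groups(self):
        assert fold_change([2, 2, 2], [2, 2, 2]) == pytest.approx(1.0)
        assert percent_change([2, 2, 2], [2, 2, 2]) == pytest.approx(0.0)

    def test_packaged_marker_values(self):
        # ROS combination group: 2.8-fold; caspase-3: 3.6-fold;
        # MDA +120 %; GSH -40 % -- all versus control
        assert fold_change([datasets.ROS_FOLD["Q+GEM"]], [1.0]) == pytest.approx(2.8)
        assert fold_change([datasets.CASPASE3_FOLD["Q+GEM"]], [1.0]) == pytest.approx(3.6)
        mda = datasets.OXIDATIVE_PANEL_PERCENT["MDA"]
        assert percent_change([mda["Q+GEM"]], [mda["control"]]) == pytest.approx(120.0)
        gsh = datasets.OXIDATIVE_PANEL_PERCENT["GSH"]
        assert percent_change([gsh["Q+GEM"]], [gsh["control"]]) == pytest.approx(-40.0)

    def test_zero_or_empty_control_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            fold_change([], [1.0])

    @given(groups, groups)
    @settings(max_examples=50, deadline=None)
    def test_scale_consistency(self, treated, control):
        assert percent_change(treated, control) == pytest.approx(
            (fold_change(treated, control) - 1.0) * 100.0, abs=1e-12)


class TestQuadrants:
    @pytest.mark.parametrize("q, total", [
        ((0, 0, 100, 0), 0.0),
        ((5, 20, 50.8, 24.2), 44.2),     # combination-like quadrants
        ((0, 44.2, 55.8, 0), 44.2),
    ])
    def test_total_apoptosis_is_q2_plus_q4(self, q, total):
        assert total_apoptosis(QuadrantCounts(*q)) == pytest.approx(total)

    def test_quadrants_must_sum_to_100(self):
        with pytest.raises(ValueError):
            QuadrantCounts(10, 10, 10, 10)

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_total_never_exceeds_100(self, q2, q4):
        rest = 100.0 - q2 - q4
        if rest < 0:
            return
        q = QuadrantCounts(0.0, q2, rest, q4)
        assert 0.0 <= total_apoptosis(q) <= 100.0


def qpcr(group, ct_t, ct_r, target="HIF1A", n=3):
    return [QPCRMeasurement(group, target, ct_t, ct_r) for _ in range(n)]


class TestRelativeQuantity:
    def test_all_ct_equal_gives_unity(self):
        assert relative_quantity(qpcr("control", 24, 16),
                                 qpcr("treated", 24, 16)) == pytest.approx(1.0)

    def test_ddct_minus_one_doubles(self):
        assert relative_quantity(qpcr("control", 24, 16),
                                 qpcr("treated", 23, 16)) == pytest.approx(2.0)

    def test_fold_point_two_from_constructed_ct(self):
        # Ct shift of +log2(5) encodes the 80 % decrease (fold 0.2)
        treated = qpcr("treated", 24 + math.log2(5), 16)
        assert relative_quantity(qpcr("control", 24, 16),
                                 treated) == pytest.approx(0.2)

    def test_packaged_ct_tables_recover_printed_folds(self):
        ms = datasets.paper_qpcr_measurements()
        for gene, folds in datasets.QPCR_FOLDS.items():
            control = [m for m in ms if m.target == gene and m.group == "control"]
            for group, fold in folds.items():
                treated = [m for m in ms if m.target == gene and m.group == group]
                assert relative_quantity(control, treated) == pytest.approx(fold)

    def test_mismatched_targets_rejected(self):
        with pytest.raises(ValueError):
            relative_quantity(qpcr("control", 24, 16, target="VEGF"),
                              qpcr("treated", 24, 16, target="BAX"))

    def test_reference_shift_invariance_within_groups(self):
        base = relative_quantity(qpcr("control", 24, 16), qpcr("t", 22, 15))
        shifted = relative_quantity(qpcr("control", 24, 16 + 3),
                                    qpcr("t", 22, 15 + 3))
        # the same constant added to ct_reference within each group
        # shifts both dCts equally, leaving ddCt and RQ unchanged
        assert shifted == pytest.approx(base)


class TestPearsonR:
    def test_perfect_linear_relations(self):
        assert pearson_r([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_packaged_ros_apoptosis_matches_covariance_oracle(self):
        x = [1.0, 1.6, 2.4, 2.8]
        y = [2.8, 24.6, 38.4, 44.2]
        # independent oracle: explicit covariance formula
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        oracle = sxy / math.sqrt(sxx * syy)
        assert pearson_r(x, y) == pytest.approx(oracle, rel=1e-12)
        assert pearson_r(x, y) == pytest.approx(0.9789946645628866, rel=1e-12)

    def test_affine_invariance(self):
        x = [1.0, 1.6, 2.4, 2.8]
        y = [2.8, 24.6, 38.4, 44.2]
        assert pearson_r([3 * v + 7 for v in x], y) == pytest.approx(
            pearson_r(x, y), rel=1e-12)

    @pytest.mark.parametrize("x, y", [
        ([1, 2], [3, 4]),
        ([1, 1, 1], [2, 3, 4]),
    ])
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson_r(x, y)


class TestMarkerTables:
    def test_marker_csv_round_trip(self, tmp_path):
        path = tmp_path / "markers.csv"
        path.write_text(
            "marker,units,group,replicate,value\n"
            "ROS,fold_of_control,control,1,1.0\n"
            "ROS,fold_of_control,control,2,1.1\n"
            "ROS,fold_of_control,combo,1,2.8\n"
        )
        (panel,) = read_marker_table(path)
        assert panel.marker == "ROS"
        assert panel.groups["combo"] == [2.8]

    def test_qpcr_csv_round_trip(self, tmp_path):
        path = tmp_path / "qpcr.csv"
        path.write_text(
            "group,target,replicate,ct_target,ct_reference\n"
            "control,HIF1A,1,24.0,16.0\n"
            "treated,HIF1A,1,26.32,16.0\n"
        )
        ms = read_qpcr_table(path)
        assert len(ms) == 2
        assert ms[1].ct_target == pytest.approx(26.32)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            MarkerPanel(marker="ROS", units="fold_of_control",
                        groups={"control": []})
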