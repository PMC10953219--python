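import numpy as np
import pandas as pd
import pytest

from genefam.expression import (delta_delta_ct, heat_matrix, na_k_ratio, rwc,
                                significance_mark)
from genefam.synthetic import CtDesign, simulate_ct_table


def manual_ct(rows):
    return pd.DataFrame(rows, columns=["gene", "cultivar", "tissue", "stress",
                                       "level", "is_control", "replicate", "ct"])


def _row(gene, level, is_control, rep, ct):
    return (gene, "cv", "leaf", "drought", level, is_control, rep, ct)


class TestDeltaDeltaCt:
    def test_hand_arithmetic_example(self):
        rows = []
        for i, ct in enumerate([20.0, 20.2, 19.8]):
            rows.append(_row("g", "ctrl", True, i + 1, ct))
        for i, ct in enumerate([18.0, 18.2, 17.8]):
            rows.append(_row("g", "trt", False, i + 1, ct))
        for level, flag in (("ctrl", True), ("trt", False)):
            for rep in (1, 2, 3):
                rows.append(_row("ref", level, flag, rep, 15.0))
        res = delta_delta_ct(manual_ct(rows), "ref")
        trt = res[res.level == "trt"].iloc[0]
        assert trt.delta_delta_ct == pytest.approx(-2.0)
        assert trt.fold_change == pytest.approx(4.0)
        assert trt.direction == "up"

    def test_control_fold_change_is_exactly_one(self):
        designs = [CtDesign("drought", ["100", "60"], "100")]
        ct = simulate_ct_table(designs, {"g": {("drought", "60"): 3.0}},
                               noise_sd=0.0, seed=0)
        res = delta_delta_ct(ct, "Actin7")
        ctrl = res[res.level == "100"].iloc[0]
        assert ctrl.fold_change == 1.0 and ctrl.direction == "unchanged"

    def test_one_cycle_shift_doubles(self):
        designs = [CtDesign("drought", ["100", "60"], "100")]
        ct = simulate_ct_table(designs, {"g": {("drought", "60"): 2.0}},
                               noise_sd=0.0, seed=0)
        res = delta_delta_ct(ct, "Actin7")
        assert res[res.level == "60"].iloc[0].fold_change == pytest.approx(2.0)

    def test_reference_gene_as_target_is_always_one(self):
        # a second gene with Ct identical to the reference behaves as a
        # re-labelled reference and must give FC 1 everywhere
        rows = []
        for level, flag in (("ctrl", True), ("trt", False)):
            for rep in (1, 2, 3):
                rows.append(_row("ref", level, flag, rep, 15.0))
                rows.append(_row("ref2", level, flag, rep, 15.0))
        res = delta_delta_ct(manual_ct(rows), "ref")
        assert (res.fold_change == 1.0).all()

    def test_missing_reference_is_error(self):
        rows = [_row("g", "ctrl", True, 1, 20.0)]
        with pytest.raises(ValueError, match="reference"):
            delta_delta_ct(manual_ct(rows), "ref")

    def test_missing_control_is_error(self):
        rows = [_row("g", "trt", False, 1, 20.0),
                _row("ref", "trt", False, 1, 15.0)]
        with pytest.raises(ValueError, match="control"):
            delta_delta_ct(manual_ct(rows), "ref")

    def test_swap_roles_inverts_fold_change(self):
        designs = [CtDesign("drought", ["100", "60"], "100")]
        ct = simulate_ct_table(designs, {"g": {("drought", "60"): 3.0}},
                               noise_sd=0.0, seed=0)
        fc = delta_delta_ct(ct, "Actin7")
        fc60 = fc[fc.level == "60"].iloc[0].fold_change
        swapped = ct.copy()
        swapped["is_control"] = swapped["level"] == "60"
        fc2 = delta_delta_ct(swapped, "Actin7")
        fc100 = fc2[fc2.level == "100"].iloc[0].fold_change
        assert fc60 * fc100 == pytest.approx(1.0)


class TestSignificance:
    def test_identical_groups_give_p_one(self):
        rows = []
        for level, flag in (("ctrl", True), ("trt", False)):
            for rep in (1, 2, 3):
                rows.append(_row("g", level, flag, rep, 20.0))
                rows.append(_row("ref", level, flag, rep, 15.0))
        res = delta_delta_ct(manual_ct(rows), "ref")
        assert res[res.level == "trt"].iloc[0].p_value == 1.0

    def test_label_swap_symmetry(self):
        designs = [CtDesign("drought", ["100", "60"], "100")]
        ct = simulate_ct_table(designs, {"g": {("drought", "60"): 2.5}},
                               noise_sd=0.3, seed=5)
        p1 = delta_delta_ct(ct, "Actin7")
        swapped = ct.copy()
        swapped["is_control"] = swapped["level"] == "60"
        p2 = delta_delta_ct(swapped, "Actin7")
        a = p1[p1.level == "60"].iloc[0].p_value
        b = p2[p2.level == "100"].iloc[0].p_value
        assert a == pytest.approx(b)

    def test_planted_shift_detected_with_high_power(self):
        # ddCt = -3 (FC = 8) with sd 0.1 and n = 3: p < 0.05 nearly always
        designs = [CtDesign("drought", ["100", "60"], "100")]
        hits = 0
        for seed in range(100):
            ct = simulate_ct_table(designs, {"g": {("drought", "60"): 8.0}},
                                   noise_sd=0.1, n_reps=3, seed=seed)
            res = delta_delta_ct(ct, "Actin7")
            if res[res.level == "60"].iloc[0].p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_marks(self):
        assert significance_mark(0.001) == "**"
        assert significance_mark(0.03) == "*"
        assert significance_mark(0.5) == "ns"
        assert significance_mark(float("nan")) == "na"


class TestPhysiology:
    def test_rwc_bounds_and_midpoint(self):
        assert rwc(3, 1, 3) == 100.0
        assert rwc(1, 1, 3) == 0.0
        assert rwc(2, 1, 3) == 50.0

    def test_rwc_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            rwc(4, 1, 3)  # fresh above turgid

    def test_na_k_examples_and_reciprocal(self):
        assert na_k_ratio(10, 10) == 1.0
        assert na_k_ratio(20, 10) == 2.0
        assert na_k_ratio(3, 7) * na_k_ratio(7, 3) == pytest.approx(1.0)

    def test_na_k_zero_rejected(self):
        with pytest.raises(ValueError):
            na_k_ratio(10, 0)


def fc_frame(fcs):
    rows = []
    for gene, by_cond in fcs.items():
        for cond, fc in by_cond.items():
            rows.append({"gene": gene, "cultivar": "cv", "tissue": "leaf",
                         "stress": "s", "level": cond, "fold_change": fc})
    return pd.DataFrame(rows)


class TestHeatMatrix:
    def test_all_ones_give_zero_matrix(self):
        df = fc_frame({"g1": {"a": 1.0, "b": 1.0}, "g2": {"a": 1.0, "b": 1.0}})
        mat, groups = heat_matrix(df, 2)
        assert (mat.to_numpy() == 0).all()

    def test_identical_profiles_share_a_group(self):
        df = fc_frame({"g1": {"a": 2.0, "b": 0.5}, "g2": {"a": 2.0, "b": 0.5},
                       "g3": {"a": 0.1, "b": 9.0}})
        _, groups = heat_matrix(df, 2)
        assert groups["g1"] == groups["g2"] != groups["g3"]

    def test_two_block_structure_recovered(self):
        up = {"a": 8.0, "b": 8.0}
        down = {"a": 0.125, "b": 0.125}
        df = fc_frame({"u1": up, "u2": {"a": 7.0, "b": 9.0},
                       "d1": down, "d2": {"a": 0.11, "b": 0.14}})
        _, groups = heat_matrix(df, 2)
        assert groups["u1"] == groups["u2"]
        assert groups["d1"] == groups["d2"]
        assert groups["u1"] != groups["d1"]

    def test_nonpositive_fold_change_rejected(self):
        df = fc_frame({"g1": {"a": 0.0, "b": 1.0}})
        with pytest.raises(ValueError):
            heat_matrix(df, 1)
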