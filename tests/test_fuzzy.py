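"""Fuzzy stage: membership, modifier areas, thresholds, labels, decision."""

import numpy as np
import pytest

from sinquad import (
    DEFAULT_MF_NON_SYN,
    DEFAULT_MF_SYN,
    ClassConfig,
    ModifierAreas,
    TrapezoidMF,
    classify_fuzzy,
    default_class_configs,
    derive_thresholds,
    linguistic_label,
    load_class_configs,
    membership,
    modifier_area,
)
from sinquad.fuzzy import (
    LABEL_ALMOST,
    LABEL_CLEARLY,
    LABEL_NOT_MEMBER,
    LABEL_UNCLEAR,
    round_half_up,
)


class TestTrapezoidMF:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            TrapezoidMF(10, 5, 20, 30)

    def test_outside_support_is_zero(self):
        assert membership(DEFAULT_MF_NON_SYN, 10.0) == 0.0
        assert membership(DEFAULT_MF_SYN, 150.0) == 0.0

    def test_plateau_is_one(self):
        assert membership(DEFAULT_MF_SYN, 45.0) == 1.0
        assert membership(DEFAULT_MF_NON_SYN, 150.0) == 1.0

    def test_shoulder_midpoint_is_half(self):
        mf = TrapezoidMF(0, 40, 60, 100)
        assert membership(mf, 20.0) == pytest.approx(0.5)
        assert membership(mf, 80.0) == pytest.approx(0.5)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            membership(DEFAULT_MF_SYN, -1.0)
        with pytest.raises(ValueError):
            membership(DEFAULT_MF_SYN, 180.5)

    def test_bounded_and_unimodal(self):
        mf = TrapezoidMF(10, 40, 70, 120)
        grid = np.linspace(0, 180, 721)
        vals = [membership(mf, a) for a in grid]
        assert all(0.0 <= v <= 1.0 for v in vals)
        peak = int(np.argmax(vals))
        assert all(x <= y + 1e-12 for x, y in zip(vals[:peak], vals[1:peak + 1]))
        assert all(x >= y - 1e-12 for x, y in zip(vals[peak:], vals[peak + 1:]))

    def test_area_closed_form_vs_riemann(self):
        for mf in (DEFAULT_MF_SYN, DEFAULT_MF_NON_SYN, TrapezoidMF(10, 40, 70, 120)):
            grid = np.linspace(0.0, 180.0, 360001)
            vals = np.array([membership(mf, a) for a in grid])
            riemann = float(np.trapezoid(vals, grid))
            assert riemann == pytest.approx(mf.area(), rel=1e-6)


class TestModifierAreas:
    def test_printed_values_exact(self):
        assert modifier_area(115.6, 1) == 28.9
        assert modifier_area(115.6, 2) == 57.8
        assert modifier_area(90.0, 1) == 22.5
        assert modifier_area(90.0, 2) == 45.0

    def test_branch_continuity(self):
        for width in (115.6, 90.0, 57.3):
            assert modifier_area(width, 2.0) == pytest.approx(width / 2.0)
            lo = modifier_area(width, 2.0 - 1e-9)
            hi = modifier_area(width, 2.0 + 1e-9)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            modifier_area(0.0, 1.0)
        with pytest.raises(ValueError):
            modifier_area(90.0, -0.1)

    def test_modifier_areas_container(self):
        areas = ModifierAreas.at(115.6, 2.0)
        assert areas.s_t == pytest.approx(57.8)
        assert areas.s_m_true == pytest.approx(57.8)


class TestThresholds:
    def test_width_115_6(self):
        t = derive_thresholds(115.6)
        assert (t.not_member, t.almost, t.clearly) == (0.29, 0.58, 0.76)
        assert t.unclear_upper == 0.58

    def test_width_90(self):
        t = derive_thresholds(90.0)
        assert (t.not_member, t.almost, t.clearly) == (0.23, 0.45, 0.67)

    def test_dilation_is_rounded_square_root(self):
        assert round_half_up(np.sqrt(0.58)) == 0.76
        assert round_half_up(np.sqrt(0.45)) == 0.67

    def test_round_half_up(self):
        assert round_half_up(0.225) == 0.23  # not banker's 0.22
        assert round_half_up(0.289) == 0.29

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            derive_thresholds(0.0)


class TestLinguisticLabels:
    def test_labels_against_k0_syn_thresholds(self):
        t = derive_thresholds(115.6)
        assert linguistic_label(0.8, t) == LABEL_CLEARLY
        assert linguistic_label(0.60, t) == LABEL_ALMOST
        assert linguistic_label(0.38, t) == LABEL_UNCLEAR
        assert linguistic_label(0.0, t) == LABEL_NOT_MEMBER
        assert linguistic_label(0.29, t) == LABEL_NOT_MEMBER  # boundary inclusive


class TestClassifyFuzzy:
    def test_plateau_cases(self):
        cfg = default_class_configs()["K0"]
        r = classify_fuzzy(45.0, cfg)
        assert (r.mu_syn, r.mu_non_syn) == (1.0, 0.0)
        assert r.decision == "syndesmophyte"
        r = classify_fuzzy(170.0, cfg)
        assert (r.mu_syn, r.mu_non_syn) == (0.0, 1.0)
        assert r.decision == "healthy"

    def test_overlap_complementarity(self):
        cfg = default_class_configs()["K0"]
        for a in np.linspace(0.0, 180.0, 361):
            r = classify_fuzzy(float(a), cfg)
            assert r.mu_syn + r.mu_non_syn == pytest.approx(1.0, abs=1e-12)

    def test_tie_falls_back_to_healthy_with_flag(self):
        cfg = default_class_configs()["K0"]
        r = classify_fuzzy(102.8, cfg)  # exact shoulder crossing
        assert r.tie
        assert r.decision == "healthy"

    def test_result_serialization(self):
        cfg = default_class_configs()["K0"]
        doc = classify_fuzzy(100.0, cfg).to_dict()
        assert set(doc) >= {"mu_syn", "mu_non_syn", "mu_syn_display",
                            "label_syn", "decision"}
        assert doc["mu_syn_display"] == f"{round_half_up(doc['mu_syn']):.2f}"


class TestClassConfig:
    def test_defaults_cover_all_classes(self):
        configs = default_class_configs()
        assert set(configs) == {"K0", "K1", "K2", "K3", "K4", "K5"}
        k0 = configs["K0"]
        assert k0.support_width_syn == pytest.approx(115.6)
        assert k0.support_width_non_syn == pytest.approx(90.0)
        assert (k0.thresholds_syn.not_member, k0.thresholds_syn.almost,
                k0.thresholds_syn.clearly) == (0.29, 0.58, 0.76)

    def test_unknown_class_id_rejected(self):
        with pytest.raises(ValueError):
            ClassConfig(class_id="K9")

    def test_load_from_yaml(self, tmp_path):
        path = tmp_path / "classes.yaml"
        path.write_text(
            "K1:\n  syn: [0, 0, 80, 110]\n  non_syn: [80, 110, 180, 180]\n"
        )
        configs = load_class_configs(path)
        assert configs["K1"].mf_syn.b_right == 80.0
        assert configs["K0"].mf_syn.b_right == 90.0  # default untouched

    def test_load_rejects_unknown_class(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("K9:\n  syn: [0, 0, 80, 110]\n")
        with pytest.raises(ValueError):
            load_class_configs(path)
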