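"""Compound fixture, fetal clearance closed forms, partitioning and scale-up."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gestpbpk as g
from gestpbpk.compound import FetalParameters, load_tissue_composition
from gestpbpk.errors import ConfigError, DomainError


class TestEscitalopramFixture:
    def test_reference_values(self, escitalopram):
        c = escitalopram
        assert c.logp == 1.34
        assert c.pka == 9.5
        assert c.blood_to_plasma == 2.0
        assert c.fu_plasma == 0.44
        assert c.f_absorbed == 1.0
        assert c.k_absorption == 0.19
        assert c.fu_gut == 1.0
        assert c.q_gut == 5.69
        assert c.kp_scalar == 0.92
        assert c.clint_by_isoform == {"CYP2C19": 0.774, "CYP2D6": 0.505, "CYP3A4": 0.0155}
        assert c.cl_renal_adult == 4.0
        assert c.cl_pdm == c.cl_pdf == 0.80902
        assert c.molecular_weight == 324.39

    def test_fraction_bounds_enforced(self, escitalopram):
        with pytest.raises(DomainError):
            escitalopram.with_updates(fu_plasma=0.0)
        with pytest.raises(DomainError):
            escitalopram.with_updates(f_absorbed=1.2)


class TestFetalClearances:
    def test_term_swallowing_clearance(self):
        assert g.fetal_swallowing_clearance(750.0, 3.7) == pytest.approx(0.00844, abs=1e-5)

    def test_no_swallowing(self):
        assert g.fetal_swallowing_clearance(0.0, 3.7) == 0.0

    def test_swallowing_hand_example(self):
        assert g.fetal_swallowing_clearance(500.0, 2.5) == pytest.approx(0.00833, abs=5e-6)

    def test_term_fetal_renal_clearance(self):
        assert g.fetal_renal_clearance(4.0, 4.92, 121.0, 3.7) == pytest.approx(0.044, abs=5e-4)

    def test_renal_equal_gfr_unit_weight(self):
        assert g.fetal_renal_clearance(4.0, 121.0, 121.0, 1.0) == pytest.approx(4.0)

    def test_renal_linear_in_adult_clearance(self):
        assert g.fetal_renal_clearance(2.0, 4.92, 121.0, 3.7) == pytest.approx(0.022, abs=5e-4)

    @given(vol=st.floats(0, 2000), w=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_swallowing_matches_independent_arithmetic(self, vol, w):
        # independent route: convert to L/h first, then per-kg
        expected = (vol / 1000.0 / 24.0) / w
        assert g.fetal_swallowing_clearance(vol, w) == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(DomainError):
            g.fetal_swallowing_clearance(750.0, 0.0)
        with pytest.raises(DomainError):
            g.fetal_renal_clearance(4.0, 4.92, 121.0, 0.0)

    def test_fetal_parameters_carry_derived_values(self):
        fp = FetalParameters()
        assert fp.cl_swallowing == pytest.approx(0.00844, abs=1e-5)
        assert fp.cl_renal_fetal == pytest.approx(0.044, abs=5e-4)


class TestPartitioning:
    def test_zero_scalar_zeroes_all_kp(self, escitalopram):
        kps = g.predict_kp(escitalopram.with_updates(kp_scalar=0.0))
        assert all(v == 0.0 for v in kps.values())

    def test_linear_in_scalar(self, escitalopram):
        k1 = g.predict_kp(escitalopram)
        k2 = g.predict_kp(escitalopram.with_updates(kp_scalar=2 * escitalopram.kp_scalar))
        for t in k1:
            assert k2[t] == pytest.approx(2 * k1[t], rel=1e-12)

    def test_vss_near_reference(self, escitalopram, phys0):
        kps = g.predict_kp(escitalopram)
        vss = g.predict_vss(kps, phys0, escitalopram)
        assert vss == pytest.approx(13.513, rel=0.25)

    def test_vss_unit_partitioning(self, escitalopram, phys0):
        # Kp == 1 everywhere and B/P == 1 -> total body water-like Vss = BW/BW
        unit = escitalopram.with_updates(blood_to_plasma=1.0, fu_plasma=1.0)
        kps = {t: 1.0 for t in phys0.tissue_volumes if t != "plasma"}
        vols = sum(phys0.tissue_volumes.values()) + phys0.erythrocyte_volume
        vss = g.predict_vss(kps, phys0, unit)
        assert vss == pytest.approx(vols / phys0.body_weight, rel=1e-9)

    def test_vss_zero_kp_is_blood_only(self, escitalopram, phys0):
        kps = {t: 0.0 for t in phys0.tissue_volumes if t != "plasma"}
        vss = g.predict_vss(kps, phys0, escitalopram)
        expected = (
            phys0.plasma_volume
            + ((2.0 - 0.6) / 0.4) * phys0.erythrocyte_volume  # KpuBC * fu at hct 0.4
        ) / phys0.body_weight
        assert vss == pytest.approx(expected, rel=1e-6)

    def test_vss_increasing_in_each_kp(self, escitalopram, phys0):
        kps = g.predict_kp(escitalopram)
        base = g.predict_vss(kps, phys0, escitalopram)
        for t in kps:
            bumped = dict(kps)
            bumped[t] += 1.0
            assert g.predict_vss(bumped, phys0, escitalopram) > base

    def test_missing_tissue_rejected(self, escitalopram, phys0):
        kps = g.predict_kp(escitalopram)
        kps.pop("muscle")
        with pytest.raises(ConfigError):
            g.predict_vss(kps, phys0, escitalopram)

    def test_acid_rejected(self, escitalopram):
        with pytest.raises(DomainError):
            g.predict_kp(escitalopram.with_updates(pka=4.0))


class TestLiverScaleUp:
    def test_zero_multipliers_zero_clearance(self, escitalopram, phys0):
        zero = {iso: 0.0 for iso in escitalopram.clint_by_isoform}
        assert g.whole_liver_intrinsic_clearance(escitalopram, phys0, zero) == 0.0

    def test_isoform_contribution_ordering(self, escitalopram, phys0):
        def only(iso):
            mult = {i: 0.0 for i in escitalopram.clint_by_isoform}
            mult[iso] = 1.0
            return g.whole_liver_intrinsic_clearance(escitalopram, phys0, mult)

        assert only("CYP2C19") > only("CYP2D6") > only("CYP3A4") > 0

    def test_additive_across_isoforms(self, escitalopram, phys0):
        total = g.whole_liver_intrinsic_clearance(escitalopram, phys0)
        parts = 0.0
        for iso in escitalopram.clint_by_isoform:
            mult = {i: float(i == iso) for i in escitalopram.clint_by_isoform}
            parts += g.whole_liver_intrinsic_clearance(escitalopram, phys0, mult)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_gestational_induction_ratio(self, escitalopram):
        clu0 = g.whole_liver_intrinsic_clearance(escitalopram, g.build_physiology(0.0))
        clu35 = g.whole_liver_intrinsic_clearance(escitalopram, g.build_physiology(35.0))
        assert clu35 / clu0 == pytest.approx(1.53, abs=0.01)

    def test_linear_in_clint(self, escitalopram, phys0):
        doubled = escitalopram.with_updates(
            clint_by_isoform={k: 2 * v for k, v in escitalopram.clint_by_isoform.items()}
        )
        assert g.whole_liver_intrinsic_clearance(doubled, phys0) == pytest.approx(
            2 * g.whole_liver_intrinsic_clearance(escitalopram, phys0), rel=1e-12
        )

    def test_negative_multiplier_rejected(self, escitalopram, phys0):
        with pytest.raises(DomainError):
            g.whole_liver_intrinsic_clearance(escitalopram, phys0, {"CYP2C19": -1.0})
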