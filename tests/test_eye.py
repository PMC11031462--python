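"""Scenario assembly, REF solving, and the magnification-change formula."""

import numpy as np
import pytest

from piolcalc.design import ScheduleParams, synth_design_table
from piolcalc.errors import GeometryError
from piolcalc.eye import (
    EyeBiometry,
    Gap,
    ScenarioConfig,
    build_system,
    delta_m_finite_object,
    resubstitute_ref,
    scan_power_range,
    solve_ref,
)
from piolcalc.paraxial import RefractiveSurface, ThinLens


class TestBiometry:
    def test_acd_and_keratometric_power_identities(self):
        eye = EyeBiometry(rc_a=7.5, rc_p=6.4, cct=0.54, aqd=3.0, lt=4.0)
        assert eye.acd == pytest.approx(3.54, abs=1e-12)
        assert eye.pc == pytest.approx(337.5 / 7.5, abs=1e-12)

    def test_non_positive_lengths_rejected(self):
        with pytest.raises(GeometryError):
            EyeBiometry(rc_a=7.5, rc_p=6.4, cct=-0.1, aqd=3.0, lt=4.0)


class TestBuildSystem:
    def test_scenario_a_gap_bookkeeping(self, table1_mean_eye, design_table):
        piol = design_table[17.0]
        cfg = ScenarioConfig("A")
        elements = build_system(table1_mean_eye, piol, cfg, "post")
        gaps = [e for e in elements if isinstance(e, Gap)]
        # cornea gap, aqueous gap, lens gap
        assert gaps[1].distance == pytest.approx(
            table1_mean_eye.aqd - cfg.vault - piol.thickness, abs=1e-12
        )

    def test_scenario_d_has_two_refracting_elements(self, table1_mean_eye):
        elements = build_system(table1_mean_eye, -10.0, ScenarioConfig("D"), "post")
        refracting = [e for e in elements if not isinstance(e, Gap)]
        assert len(refracting) == 2

    def test_scenarios_a_and_b_share_the_piol_block(self, table1_mean_eye, design_table):
        piol = design_table[-10.0]
        sys_a = build_system(table1_mean_eye, piol, ScenarioConfig("A"), "post")
        sys_b = build_system(table1_mean_eye, piol, ScenarioConfig("B"), "post")
        assert sys_a[-3:] == sys_b[-3:]

    def test_thick_scenarios_require_a_design(self, table1_mean_eye):
        with pytest.raises(TypeError):
            build_system(table1_mean_eye, -10.0, ScenarioConfig("A"), "post")

    def test_impossible_geometry_raises(self, design_table):
        eye = EyeBiometry(rc_a=7.7, rc_p=6.5, cct=0.5, aqd=0.9, lt=4.0)
        with pytest.raises(GeometryError):
            build_system(eye, design_table[17.0], ScenarioConfig("A", vault=0.4), "post")


class TestSolveRef:
    def test_zero_power_thin_piol_changes_nothing(self, table1_mean_eye):
        res = solve_ref(table1_mean_eye, 0.0, ScenarioConfig("D"))
        assert res.ref == pytest.approx(0.0, abs=1e-12)
        assert res.delta_m == pytest.approx(0.0, abs=1e-12)

    def test_slpos_is_acd_minus_vault(self, table1_mean_eye, design_table):
        cfg = ScenarioConfig("A", vault=0.4)
        res = solve_ref(table1_mean_eye, design_table[-10.0], cfg)
        assert res.slpos == pytest.approx(table1_mean_eye.acd - 0.4, abs=1e-12)

    @pytest.mark.parametrize("scenario", ["A", "B", "C", "D"])
    @pytest.mark.parametrize("power", [-17.0, -5.5, 3.0, 17.0])
    def test_ref_resubstitution_self_consistency(
        self, table1_mean_eye, design_table, scenario, power
    ):
        """REF pushed forward through the preoperative system reproduces V_SLPOS."""
        cfg = ScenarioConfig(scenario)
        piol = design_table[power] if scenario in "AB" else power
        res = solve_ref(table1_mean_eye, piol, cfg)
        v = resubstitute_ref(table1_mean_eye, cfg, res.ref)
        assert v.value == pytest.approx(res.v_slpos.value, abs=1e-9)

    def test_resubstitution_on_random_eyes(self, random_eyes, design_table):
        cfg = ScenarioConfig("A")
        piol = design_table[12.5]
        for eye in random_eyes:
            res = solve_ref(eye, piol, cfg)
            v = resubstitute_ref(eye, cfg, res.ref)
            assert abs(v.value - res.v_slpos.value) < 1e-9

    def test_sign_convention(self, table1_mean_eye, design_table):
        """Minus lenses correct myopia (REF < 0, magnification gain); plus
        lenses correct hyperopia (REF > 0, magnification loss)."""
        cfg = ScenarioConfig("A")
        neg = solve_ref(table1_mean_eye, design_table[-10.0], cfg)
        pos = solve_ref(table1_mean_eye, design_table[10.0], cfg)
        assert neg.ref < 0 < pos.ref
        assert neg.delta_m > 0 > pos.delta_m


class TestDeltaM:
    @pytest.mark.parametrize("scenario", ["A", "B", "C", "D"])
    def test_symbolic_cancellation_matches_finite_object_limit(
        self, table1_mean_eye, design_table, scenario
    ):
        cfg = ScenarioConfig(scenario)
        for power in (-17.0, -3.0, 3.0, 17.0):
            piol = design_table[power] if scenario in "AB" else power
            exact = solve_ref(table1_mean_eye, piol, cfg).delta_m
            limit = delta_m_finite_object(table1_mean_eye, piol, cfg, 1.0e6)
            # compared on the dimensionless magnification-ratio scale
            assert exact / 100.0 == pytest.approx(limit / 100.0, abs=1e-6)

    def test_delta_m_vanishes_linearly_with_thin_piol_power(self, table1_mean_eye):
        cfg = ScenarioConfig("D")
        powers = (0.5, 0.05, 0.005)
        dms = [solve_ref(table1_mean_eye, p, cfg).delta_m for p in powers]
        # dM ~ slope * PIOLP near zero (slope about -1.2 %/dpt)
        slopes = [dm / p for dm, p in zip(dms, powers)]
        assert all(abs(a) > abs(b) for a, b in zip(dms, dms[1:]))
        assert slopes[0] == pytest.approx(slopes[-1], rel=1e-2)
        assert abs(dms[-1]) < 0.01


class TestScanPowerRange:
    def test_monotone_in_power_for_random_eyes(self, random_eyes, design_table):
        """REF strictly increasing and dM strictly decreasing in PIOLP."""
        cfg = ScenarioConfig("A")
        for eye in random_eyes:
            results = scan_power_range(eye, design_table, cfg)
            refs = [r.ref for r in results]
            dms = [r.delta_m for r in results]
            assert all(a < b for a, b in zip(refs, refs[1:]))
            assert all(a > b for a, b in zip(dms, dms[1:]))

    def test_thin_cornea_is_a_mild_simplification(self, clinical_eye, design_table):
        """Scenario B deviates from A by well under 0.1 dpt at every step."""
        cfg = dict(vault=0.4, vd=14.0)
        ra = scan_power_range(clinical_eye, design_table, ScenarioConfig("A", **cfg))
        rb = scan_power_range(clinical_eye, design_table, ScenarioConfig("B", **cfg))
        diffs = [abs(a.ref - b.ref) for a, b in zip(ra, rb)]
        assert max(diffs) < 0.1

    def test_thin_piol_error_grows_with_positive_power(self, clinical_eye, design_table):
        cfg = dict(vault=0.4, vd=14.0)
        ra = scan_power_range(clinical_eye, design_table, ScenarioConfig("A", **cfg))
        rc = scan_power_range(clinical_eye, design_table, ScenarioConfig("C", **cfg))
        diffs = np.array([a.ref - c.ref for a, c in zip(ra, rc)])
        pos = diffs[29:]
        assert np.all(np.diff(pos) > 0)  # grows with PIOLP on the plus side
        assert abs(diffs[-1]) == np.max(np.abs(diffs))

    def test_scenario_collapse_in_the_thin_lens_limit(self, table1_mean_eye):
        """With a vanishing thickness schedule the thick-PIOL scenarios agree
        with their thin-lens counterparts for every power step."""
        params = ScheduleParams(t_negative=1e-6, t_pos_low=1e-6, t_pos_high=1e-6)
        thin_table = synth_design_table(params)
        for thick_sc, thin_sc in (("A", "C"), ("B", "D")):
            r_thick = scan_power_range(table1_mean_eye, thin_table, ScenarioConfig(thick_sc))
            r_thin = scan_power_range(table1_mean_eye, thin_table, ScenarioConfig(thin_sc))
            for a, c in zip(r_thick, r_thin):
                assert a.ref == pytest.approx(c.ref, abs=1e-3)
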