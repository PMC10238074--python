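import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retnav.calibration import fit_voltage_map
from retnav.core_io import LaserParams
from retnav.lesion_planner import (
    LesionPlan,
    compile_schedule,
    coverage_report,
    plan_focal,
    plan_patch,
    quadrant_layout,
)

LASER = LaserParams(6.0, 200.0, 1, 0.0)


def brute_force_patch_sites(treatment, exclusion, spot_um, overlap, pitch):
    """Independent enumeration of the raster keep-rule, pixel by pixel."""
    radius = spot_um / 2.0
    step = (1 - overlap) * spot_um
    rows, cols = np.nonzero(treatment)
    if len(rows) == 0:
        return []
    y0, y1 = (rows.min() + 0.5) * pitch, (rows.max() + 0.5) * pitch
    x0, x1 = (cols.min() + 0.5) * pitch, (cols.max() + 0.5) * pitch
    sites = []
    y = y0 + radius
    while y <= y1 - radius + 1e-9:
        x = x0 + radius
        while x <= x1 - radius + 1e-9:
            ok = True
            for r in range(treatment.shape[0]):
                for c in range(treatment.shape[1]):
                    cy, cx = (r + 0.5) * pitch, (c + 0.5) * pitch
                    if (cy - y) ** 2 + (cx - x) ** 2 <= radius**2:
                        if not treatment[r, c]:
                            ok = False
                        if exclusion is not None and exclusion[r, c]:
                            ok = False
            # pixels beyond the image border with centres inside the disc
            if y - radius < 0 or x - radius < 0:
                ok = False
            if ok:
                sites.append((x, y))
            x += step
        y += step
    return sites


def _rect_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestPlanFocal:
    def test_quadrant_preset_has_12_sites_3_per_quadrant(self):
        sites = quadrant_layout((500.0, 500.0))
        assert len(sites) == 12
        sites = np.asarray(sites)
        d = sites - [500.0, 500.0]
        quadrants = {
            "temporal": (d[:, 0] > 0) & (d[:, 1] == 0),
            "nasal": (d[:, 0] < 0) & (d[:, 1] == 0),
            "superior": (d[:, 1] > 0) & (d[:, 0] == 0),
            "inferior": (d[:, 1] < 0) & (d[:, 0] == 0),
        }
        for name, sel in quadrants.items():
            assert sel.sum() == 3, name

    def test_site_on_vessel_rejected(self):
        treat = np.ones((20, 20), dtype=bool)
        vessels = np.zeros((20, 20), dtype=bool)
        vessels[10, :] = True
        with pytest.raises(ValueError, match="exclusion"):
            plan_focal([(5.0, 10.5)], LASER, treat, vessels, pitch=1.0)

    def test_empty_site_list_valid(self):
        plan = plan_focal([], LASER)
        assert plan.n_sites == 0


class TestPlanPatch:
    def test_overlap_half_gives_half_diameter_pitch(self):
        treat = _rect_mask((60, 60), 5, 55, 5, 55)
        plan = plan_patch(treat, None, LASER, spot_diameter=20.0, overlap=0.5, pitch=1.0)
        pos = plan.positions()
        xs = np.unique(np.round(pos[:, 0], 6))
        assert np.allclose(np.diff(xs), 10.0)
        assert plan.provenance["pitch_um"] == pytest.approx(10.0)

    def test_zero_overlap_pitch_equals_diameter(self):
        treat = _rect_mask((60, 60), 0, 60, 0, 60)
        plan = plan_patch(treat, None, LASER, spot_diameter=20.0, overlap=0.0, pitch=1.0)
        xs = np.unique(np.round(plan.positions()[:, 0], 6))
        assert np.allclose(np.diff(xs), 20.0)

    def test_matches_brute_force_oracle_rectangle(self):
        # 400 x 200 um rectangle, 50 um spot, 50% overlap, 10 um pixels
        treat = _rect_mask((30, 50), 3, 23, 4, 44)
        plan = plan_patch(treat, None, LASER, spot_diameter=50.0, overlap=0.5, pitch=10.0)
        oracle = brute_force_patch_sites(treat, None, 50.0, 0.5, 10.0)
        got = sorted((round(x, 6), round(y, 6)) for x, y in plan.positions())
        want = sorted((round(x, 6), round(y, 6)) for x, y in oracle)
        assert got == want
        assert len(got) > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = (24, 24)
        treat = np.zeros(shape, dtype=bool)
        r0, c0 = rng.integers(0, 8, 2)
        r1, c1 = rng.integers(14, 24, 2)
        treat[r0:r1, c0:c1] = True
        # random blob exclusions
        excl = np.zeros(shape, dtype=bool)
        for _ in range(rng.integers(0, 4)):
            rr, cc = rng.integers(0, 24, 2)
            excl[max(rr - 1, 0) : rr + 2, max(cc - 1, 0) : cc + 2] = True
        spot = float(rng.choice([30.0, 50.0]))
        overlap = float(rng.choice([0.0, 0.5]))
        plan = plan_patch(treat, excl, LASER, spot_diameter=spot, overlap=overlap, pitch=10.0)
        oracle = brute_force_patch_sites(treat, excl, spot, overlap, 10.0)
        got = sorted((round(x, 6), round(y, 6)) for x, y in plan.positions())
        want = sorted((round(x, 6), round(y, 6)) for x, y in oracle)
        assert got == want

    def test_exclusion_equals_treatment_empty_plan(self):
        treat = _rect_mask((30, 30), 5, 25, 5, 25)
        plan = plan_patch(treat, treat.copy(), LASER, spot_diameter=20.0, pitch=1.0)
        assert plan.n_sites == 0

    def test_spot_larger_than_mask_empty_plan(self):
        treat = _rect_mask((30, 30), 10, 15, 10, 15)
        plan = plan_patch(treat, None, LASER, spot_diameter=200.0, pitch=1.0)
        assert plan.n_sites == 0

    def test_no_site_intersects_exclusion(self):
        rng = np.random.default_rng(9)
        treat = _rect_mask((40, 40), 2, 38, 2, 38)
        excl = rng.random((40, 40)) > 0.92
        plan = plan_patch(treat, excl, LASER, spot_diameter=12.0, overlap=0.5, pitch=2.0)
        radius = 6.0
        er, ec = np.nonzero(excl)
        e_xy = np.stack([(ec + 0.5) * 2.0, (er + 0.5) * 2.0], axis=-1)
        for x, y in plan.positions():
            d = np.linalg.norm(e_xy - [x, y], axis=1)
            assert d.min() > radius

    @given(spot=st.sampled_from([16.0, 24.0, 32.0, 48.0]))
    @settings(max_examples=4)
    def test_site_count_monotone_in_spot_diameter(self, spot):
        treat = _rect_mask((40, 40), 4, 36, 4, 36)
        n_small = plan_patch(treat, None, LASER, spot_diameter=spot, overlap=0.0,
                             pitch=2.0).n_sites
        n_big = plan_patch(treat, None, LASER, spot_diameter=spot + 8.0, overlap=0.0,
                           pitch=2.0).n_sites
        assert n_big <= n_small

    def test_site_count_monotone_in_exclusion_area(self, rng):
        treat = _rect_mask((40, 40), 2, 38, 2, 38)
        excl_small = rng.random((40, 40)) > 0.97
        excl_big = excl_small | (rng.random((40, 40)) > 0.97)
        n_none = plan_patch(treat, None, LASER, spot_diameter=10.0, pitch=2.0).n_sites
        n_small = plan_patch(treat, excl_small, LASER, spot_diameter=10.0, pitch=2.0).n_sites
        n_big = plan_patch(treat, excl_big, LASER, spot_diameter=10.0, pitch=2.0).n_sites
        assert n_big <= n_small <= n_none


class TestCompileSchedule:
    def _identity_model(self, extent=1000.0):
        v = np.stack(np.meshgrid(np.linspace(0, extent, 5), np.linspace(0, extent, 5)),
                     -1).reshape(-1, 2)
        return fit_voltage_map(v, v.copy(), degree=1)

    def test_pulse_train_timing(self):
        model = self._identity_model()
        laser = LaserParams(6.0, 200.0, 4, 50.0)
        plan = plan_focal([(100.0, 100.0), (300.0, 300.0)], laser)
        sched = compile_schedule(plan, model)
        assert len(sched) == 8
        for site in (0, 1):
            onsets = sched[sched.site == site].onset_ms.to_numpy()
            np.testing.assert_allclose(np.diff(onsets), 250.0)
        assert sched.duration_ms.sum() == pytest.approx(1600.0)

    def test_single_repeat_one_row_per_site(self):
        model = self._identity_model()
        plan = plan_focal([(50.0, 60.0), (70.0, 80.0), (90.0, 10.0)], LASER)
        sched = compile_schedule(plan, model)
        assert len(sched) == 3

    def test_identity_calibration_voltages_equal_positions(self):
        model = self._identity_model()
        plan = plan_focal([(123.0, 456.0)], LASER)
        sched = compile_schedule(plan, model)
        assert sched.vx[0] == pytest.approx(123.0, abs=1e-3)
        assert sched.vy[0] == pytest.approx(456.0, abs=1e-3)

    def test_site_outside_calibration_image_rejected(self):
        model = self._identity_model(extent=100.0)
        plan = plan_focal([(5000.0, 5000.0)], LASER)
        with pytest.raises(ValueError, match="outside the calibration"):
            compile_schedule(plan, model)

    def test_energy_bookkeeping_exact(self):
        model = self._identity_model()
        laser = LaserParams(7.0, 150.0, 3, 20.0)
        plan = plan_focal([(10.0 * i, 20.0 * i) for i in range(1, 6)], laser)
        sched = compile_schedule(plan, model)
        total = (sched.power_mw * sched.duration_ms).sum()
        assert total == pytest.approx(5 * 3 * 7.0 * 150.0)


class TestCoverage:
    def test_interior_coverage_complete_at_half_overlap(self):
        treat = _rect_mask((60, 60), 5, 55, 5, 55)
        plan = plan_patch(treat, None, LASER, spot_diameter=20.0, overlap=0.5, pitch=1.0)
        frac, gap = coverage_report(plan, _rect_mask((60, 60), 20, 40, 20, 40), pitch=1.0)
        assert frac == 1.0

    def test_empty_plan_zero_coverage(self):
        treat = _rect_mask((20, 20), 2, 18, 2, 18)
        plan = LesionPlan(sites=[], spot_diameter=10.0)
        frac, gap = coverage_report(plan, treat, pitch=1.0)
        assert frac == 0.0
        assert gap.sum() == treat.sum()

    def test_single_site_coverage_matches_disc_area(self):
        treat = np.ones((100, 100), dtype=bool)
        plan = LesionPlan(sites=[((50.0, 50.0), LASER)], spot_diameter=40.0)
        frac, _ = coverage_report(plan, treat, pitch=1.0)
        expected = np.pi * 20.0**2 / 100.0**2
        assert frac == pytest.approx(expected, rel=0.02)
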