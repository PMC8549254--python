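import numpy as np
import pytest

from cmrsv.geometry_core import (
    ED,
    EPICARDIAL,
    ES,
    InputError,
    LandmarkSet,
    Slice,
    SlicePhase,
)
from cmrsv.regional_sv import (
    basal_epicardial_area,
    compute_avpd,
    decompose,
    radial_slice_areas,
    sv_long,
    sv_radial,
)
from cmrsv.synthetic_data import PhantomSpec, generate_phantom
from conftest import circle_contour, simple_landmarks, stack_of_squares


class TestAVPD:
    def test_uniform_translation_along_axis(self):
        stack = stack_of_squares([10.0] * 8, avpd=15.3)
        res = compute_avpd(stack)
        assert res.mean_mm == pytest.approx(15.3, rel=1e-12)
        assert all(v == pytest.approx(15.3) for v in res.per_landmark_mm.values())

    def test_zero_motion(self):
        stack = stack_of_squares([10.0] * 8, avpd=0.0)
        assert compute_avpd(stack).mean_mm == pytest.approx(0.0, abs=1e-12)

    def test_in_plane_motion_projects_to_zero(self):
        stack = stack_of_squares([10.0] * 8)
        lm = stack.landmarks
        es = {k: v + np.array([5.0, -3.0, 0.0]) for k, v in lm.ed.items()}
        stack.landmarks = LandmarkSet(ed=lm.ed, es=es, apex_ed=lm.apex_ed)
        assert compute_avpd(stack).mean_mm == pytest.approx(0.0, abs=1e-12)

    def test_mean_is_arithmetic_mean(self):
        stack = stack_of_squares([10.0] * 8)
        lm = stack.landmarks
        shifts = dict(zip(lm.ed, [4.0, 6.0, 8.0, 10.0, 12.0, 14.0]))
        es = {k: v + np.array([0.0, 0.0, -shifts[k]]) for k, v in lm.ed.items()}
        stack.landmarks = LandmarkSet(ed=lm.ed, es=es, apex_ed=lm.apex_ed)
        res = compute_avpd(stack)
        assert res.mean_mm == pytest.approx(np.mean(list(shifts.values())))


class TestBasalArea:
    def _stack(self, areas, spacing, avpd):
        # epicardial areas (cm^2) via the square builder's 1.3^2 scale factor
        return stack_of_squares(
            [a / 1.69 for a in areas], spacing=spacing, avpd=avpd
        )

    def test_two_in_band_slices_averaged(self):
        # slices at depths 5 and 15 mm, band [0, 16]
        stack = self._stack([50.0, 52.0, 40.0], spacing=10.0, avpd=16.0)
        res = basal_epicardial_area(stack, compute_avpd(stack))
        assert res.area_cm2 == pytest.approx(51.0, rel=1e-9)
        assert res.flag is None

    def test_three_in_band_takes_two_largest(self):
        stack = self._stack([30.0, 40.0, 50.0, 20.0], spacing=10.0, avpd=26.0)
        res = basal_epicardial_area(stack, compute_avpd(stack))
        assert res.area_cm2 == pytest.approx(45.0, rel=1e-9)

    def test_single_in_band_flagged(self):
        stack = self._stack([34.0, 40.0], spacing=10.0, avpd=6.0)
        res = basal_epicardial_area(stack, compute_avpd(stack))
        assert res.area_cm2 == pytest.approx(34.0, rel=1e-9)
        assert res.flag == "single_in_band"

    def test_none_in_band_falls_back_to_most_basal(self):
        stack = self._stack([34.0, 40.0], spacing=10.0, avpd=2.0)
        res = basal_epicardial_area(stack, compute_avpd(stack))
        assert res.area_cm2 == pytest.approx(34.0, rel=1e-9)
        assert res.flag == "fallback_most_basal"


class TestSVLong:
    def test_arithmetic(self):
        # AVPD 10 mm x 50 cm^2 over SV 100 ml -> 50 ml, 50%
        stack = stack_of_squares([50.0 / 1.69] * 4, spacing=10.0, avpd=10.0)
        avpd = compute_avpd(stack)
        basal = basal_epicardial_area(stack, avpd)
        ml, pct = sv_long(stack, avpd, basal, total_sv_ml=100.0)
        assert ml == pytest.approx(10.0 * 50.0 * 0.1, rel=1e-9)
        assert pct == pytest.approx(50.0, rel=1e-9)

    def test_zero_avpd_gives_zero(self):
        stack = stack_of_squares([30.0] * 4, avpd=0.0)
        ml, pct = sv_long(stack, total_sv_ml=80.0)
        assert ml == pytest.approx(0.0, abs=1e-12)
        assert pct == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_sv_percentage_undefined(self):
        stack = stack_of_squares([30.0] * 4, avpd=10.0)
        ml, pct = sv_long(stack, total_sv_ml=0.0)
        assert ml > 0
        assert np.isnan(pct)

    def test_linear_in_avpd_on_cylinder(self):
        mls = []
        for avpd in (4.0, 8.0, 16.0):
            spec = PhantomSpec(n_slices=20, avpd_mm=avpd, lateral_inward_mm=0.0,
                               septal_inward_mm=0.0, seed=1)
            stack, _ = generate_phantom(spec)
            ml, _ = sv_long(stack, total_sv_ml=1.0)
            mls.append(ml)
        assert mls[1] / mls[0] == pytest.approx(2.0, rel=1e-9)
        assert mls[2] / mls[0] == pytest.approx(4.0, rel=1e-9)


def _radial_slice(r=30.0, n=360, sept_shift=0.0, lat_shift=0.0, span=120.0):
    """Slice with ED circle and ES contour displaced inward on the septal
    (around 180 deg) and free-wall arcs; positive shift = toward the centre."""
    phi = 2 * np.pi * np.arange(n) / n
    a = np.abs((phi - np.pi + np.pi) % (2 * np.pi) - np.pi)
    half = np.radians(span / 2.0)
    delta = np.where(a <= half, sept_shift, lat_shift)
    ed_r = np.full(n, r)
    es_r = r - delta
    z = 0.0

    def ring(radii, phase):
        pts = np.column_stack(
            [radii * np.cos(phi), radii * np.sin(phi), np.full(n, z)]
        )
        from cmrsv.geometry_core import PlanarContour

        return PlanarContour(pts, EPICARDIAL, phase)

    def at(radius, deg):
        t = np.radians(deg)
        return np.array([radius * np.cos(t), radius * np.sin(t), z])

    ed = SlicePhase(
        epicardial=ring(ed_r, ED),
        insertion_anterior=at(r, 240.0),
        insertion_inferior=at(r, 120.0),
    )
    es = SlicePhase(
        epicardial=ring(es_r, ES),
        insertion_anterior=at(r - delta[240 * n // 360], 240.0),
        insertion_inferior=at(r - delta[120 * n // 360], 120.0),
    )
    return Slice(index=0, origin=np.zeros(3), normal=np.array([0.0, 0.0, -1.0]),
                 ed=ed, es=es)


class TestRadialSliceAreas:
    def test_septal_inward_positive_lateral_zero(self):
        res = radial_slice_areas(_radial_slice(sept_shift=2.0, lat_shift=0.0))
        assert res.septal_mm2 > 0
        # free wall is stationary; only the step-boundary sliver (one vertex
        # wide) can leak into the lateral term
        assert res.lateral_mm2 == pytest.approx(0.0, abs=1.0)

    def test_septal_toward_rv_negative(self):
        res = radial_slice_areas(_radial_slice(sept_shift=-2.0, lat_shift=0.0))
        assert res.septal_mm2 < 0

    def test_concentric_annulus_split_by_arc_angle(self):
        r, d = 30.0, 1.0
        res = radial_slice_areas(_radial_slice(sept_shift=d, lat_shift=d))
        total_true = 2 * np.pi * r * d - np.pi * d**2
        total = res.septal_mm2 + res.lateral_mm2
        assert total == pytest.approx(total_true, rel=2e-3)
        # the septum spans 120 of 360 degrees
        assert res.septal_mm2 / total == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_missing_insertions_raise(self):
        slc = _radial_slice()
        slc.es.insertion_anterior = None
        with pytest.raises(InputError, match="insertion"):
            radial_slice_areas(slc)


class TestSVRadial:
    def test_lateral_only_phantom(self):
        spec = PhantomSpec(n_slices=20, avpd_mm=8.0, lateral_inward_mm=4.0,
                           septal_inward_mm=0.0, seed=3)
        stack, truth = generate_phantom(spec)
        res = sv_radial(stack)
        assert res.sept_ml == pytest.approx(0.0, abs=0.5)
        assert res.lat_ml == pytest.approx(truth.lat_ml, rel=0.05)

    def test_zero_septal_displacement_zero_contribution(self):
        spec = PhantomSpec(n_slices=20, avpd_mm=8.0, lateral_inward_mm=0.0,
                           septal_inward_mm=0.0, seed=3)
        stack, _ = generate_phantom(spec)
        res = sv_radial(stack)
        assert res.sept_ml == pytest.approx(0.0, abs=0.1)

    def test_mixed_phantom_matches_truth(self):
        spec = PhantomSpec(n_slices=20, avpd_mm=10.0, lateral_inward_mm=5.0,
                           septal_inward_mm=-3.0, seed=4)
        stack, truth = generate_phantom(spec)
        res = sv_radial(stack)
        # 5% covers the basal truncation when the ES AV plane falls inside a
        # slice (the stated recovery tolerance of the method)
        assert res.sept_ml == pytest.approx(truth.sept_ml, rel=0.05)
        assert res.lat_ml == pytest.approx(truth.lat_ml, rel=0.05)

    def test_septal_antisymmetry(self):
        # Swept annular areas are antisymmetric only to first order in the
        # displacement: inward sweeps (2*R*d - d^2)/2 per radian, outward
        # (2*R*d + d^2)/2, so the magnitudes differ by ~d/R (6% here).
        results = []
        for sept in (2.0, -2.0):
            spec = PhantomSpec(n_slices=20, avpd_mm=10.0, lateral_inward_mm=0.0,
                               septal_inward_mm=sept, seed=9)
            stack, _ = generate_phantom(spec)
            results.append(sv_radial(stack).sept_ml)
        assert results[0] > 0 > results[1]
        assert results[0] == pytest.approx(-results[1], rel=0.10)


class TestDecompose:
    def test_control_like_sums_near_100(self, control_phantom):
        stack, _ = control_phantom
        res = decompose(stack)
        total = res.sv_long_pct + res.sv_lat_pct + res.sv_sept_pct
        assert 90.0 <= total <= 110.0
        assert res.residual_pct == pytest.approx(100.0 - total, rel=1e-9)

    def test_patient_like_negative_septum_augmented_lateral(self, control_phantom):
        _, _ = control_phantom
        control = decompose(control_phantom[0])
        spec = PhantomSpec(n_slices=20, avpd_mm=8.3, lateral_inward_mm=5.0,
                           septal_inward_mm=-2.0, seed=12)
        stack, _ = generate_phantom(spec)
        patient = decompose(stack)
        assert patient.sv_sept_pct < 0
        assert patient.sv_lat_pct > control.sv_lat_pct

    def test_rigid_ventricle_flagged(self):
        spec = PhantomSpec(n_slices=20, avpd_mm=0.0, lateral_inward_mm=0.0,
                           septal_inward_mm=0.0, seed=2)
        stack, _ = generate_phantom(spec)
        res = decompose(stack)
        assert res.volumetrics.sv_ml == pytest.approx(0.0, abs=1e-6)
        assert res.sv_long_ml == pytest.approx(0.0, abs=1e-9)
        assert res.sv_sept_ml == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(res.sv_long_pct) and np.isnan(res.residual_pct)
        assert any("percentages undefined" in f for f in res.flags)

    def test_percentages_consistent_with_ml(self, control_phantom):
        stack, _ = control_phantom
        res = decompose(stack)
        sv = res.volumetrics.sv_ml
        assert res.sv_long_pct == pytest.approx(100 * res.sv_long_ml / sv)
        assert res.sv_lat_pct == pytest.approx(100 * res.sv_lat_ml / sv)
        assert res.sv_sept_pct == pytest.approx(100 * res.sv_sept_ml / sv)

    def test_conservation_on_independent_motion(self):
        for seed, avpd, lat, sept in [(1, 12.0, 3.0, 2.0), (2, 8.0, 5.0, -2.0)]:
            spec = PhantomSpec(n_slices=20, avpd_mm=avpd, lateral_inward_mm=lat,
                               septal_inward_mm=sept, seed=seed)
            stack, _ = generate_phantom(spec)
            res = decompose(stack)
            assert -10.0 <= res.residual_pct <= 10.0
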