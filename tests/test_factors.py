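"""Correction-factor tests: kvert, kprof, kimp, kgap, r80, dose conversion,
and positional Type B propagation through the factors."""

import numpy as np
import pytest

from pmbdose.dap import SensitiveRegion, dap_per_area_supersampled
from pmbdose.factors import (CorrectionFactor, ScoredDoseSet,
                             compute_dose_conversion, compute_kgap,
                             compute_kimp, compute_kprof, compute_kvert,
                             find_r80, percent_deviation_from_unity,
                             positional_type_b_on_factor)
from pmbdose.maps import DoseMap2D
from pmbdose.positioning import PositioningModel
from pmbdose.synthetic import (DepthDoseCurve, MinibeamFieldSpec,
                               generate_minibeam_map)


def _uniform_maps(value=3.0, n=2):
    return [DoseMap2D(np.full((500, 500), value), 0.1) for _ in range(n)]


def _gradient_map(g, n=500, s=0.1):
    c = (np.arange(n) - (n - 1) / 2.0) * s
    return DoseMap2D(np.tile(np.clip(1.0 + g * c, 0, None)[:, None],
                             (1, n)), s)


# ---------------------------------------------------------------------------
# kvert / kprof
# ---------------------------------------------------------------------------

def test_kvert_on_uniform_maps_is_unity():
    f = compute_kvert(_uniform_maps(), radius=7.8)
    assert f.value == pytest.approx(1.0, rel=1e-12)
    assert f.type_a == 0.0


def test_kvert_of_the_default_gradient_matches_the_closed_form(mono_map):
    # disc average of a linear vertical gradient is its center value, so
    # kvert = (1 + g*(-11)) / (1 + g*0) = 0.9637 for g = 0.0033 /mm
    f = compute_kvert([mono_map, mono_map], radius=7.8, name="kvert_roos")
    assert f.value == pytest.approx(1.0 - 0.0363, abs=5e-4)
    assert f.type_a == 0.0


def test_kvert_type_a_tracks_the_film_noise():
    def maps(noise, seeds):
        spec = MinibeamFieldSpec(noise_sd=noise)
        return [generate_minibeam_map(spec, seed=s, pixel_spacing=0.2)
                for s in seeds]

    noisy = compute_kvert(maps(0.2, range(6)), radius=7.8)
    quiet = compute_kvert(maps(0.02, range(6, 12)), radius=7.8)
    assert noisy.type_a > 0
    assert quiet.type_a < noisy.type_a


def test_kprof_on_uniform_maps_is_unity():
    assert compute_kprof(_uniform_maps()).value == pytest.approx(1.0,
                                                                 rel=1e-12)


def test_kprof_is_close_to_unity_on_the_minibeam_field(mono_map):
    f = compute_kprof([mono_map, mono_map])
    assert 0.97 <= f.value <= 1.03


def test_kprof_sign_follows_the_field_curvature_and_the_oracle():
    # radially symmetric Gaussian centered on the aperture: the wider disc
    # averages in lower dose, so kprof = DAP(8.0)/DAP(7.8) < 1
    s = 0.1
    n = 600
    c = (np.arange(n) - (n - 1) / 2.0) * s
    r2 = c[None, :] ** 2 + c[:, None] ** 2
    m = DoseMap2D(np.exp(-r2 / (2 * 10.0 ** 2)), s)
    f = compute_kprof([m, m], center=(0.0, 0.0))
    assert f.value < 1.0
    oracle = (dap_per_area_supersampled(m, SensitiveRegion((0, 0), 8.0))
              / dap_per_area_supersampled(m, SensitiveRegion((0, 0), 7.8)))
    assert f.value == pytest.approx(oracle, rel=1e-4)


def test_film_factors_require_repeated_measurements():
    with pytest.raises(ValueError, match="at least 2"):
        compute_kvert(_uniform_maps(n=1), radius=7.8)


# ---------------------------------------------------------------------------
# kimp / kgap
# ---------------------------------------------------------------------------

def test_kimp_and_kgap_are_the_configuration_dose_ratios():
    s = ScoredDoseSet(d_full=1.0000, d_pure=1.0013, d_compensated=0.99970,
                      u_full=0.04, u_pure=0.04, u_compensated=0.04)
    kimp = compute_kimp(s)
    assert kimp.value == pytest.approx(1.0013, rel=1e-12)
    assert kimp.type_a == pytest.approx(0.0566, abs=5e-4)
    s2 = ScoredDoseSet(d_full=1.0, d_pure=1.0, d_compensated=0.9984)
    assert compute_kimp(s2).value == 1.0
    assert compute_kgap(s2).value == pytest.approx(0.9984, rel=1e-12)


def test_kimp_kgap_telescoping_identity():
    s = ScoredDoseSet(d_full=0.9731, d_pure=1.0212, d_compensated=0.9876)
    prod = compute_kimp(s).value * compute_kgap(s).value
    assert prod == pytest.approx(s.d_compensated / s.d_full, rel=1e-14)


def test_scored_doses_must_be_positive():
    with pytest.raises(ValueError, match="> 0"):
        ScoredDoseSet(d_full=0.0, d_pure=1.0, d_compensated=1.0)


# ---------------------------------------------------------------------------
# r80 and dose conversion
# ---------------------------------------------------------------------------

def test_r80_of_a_linear_distal_edge():
    z = np.linspace(0.0, 20.0, 201)
    dose = np.where(z <= 10.0, z / 10.0, (20.0 - z) / 10.0)
    curve = DepthDoseCurve(z, dose)
    assert find_r80(curve) == pytest.approx(12.0, abs=1e-9)
    scaled = DepthDoseCurve(z, 7.3 * dose)
    assert find_r80(scaled) == pytest.approx(12.0, abs=1e-9)


def test_r80_of_a_gaussian_distal_edge_matches_the_analytic_crossing():
    sigma = 4.0
    z = np.arange(0.0, 60.0, 0.01)
    dose = np.where(z <= 30.0, 0.2 + 0.8 * z / 30.0,
                    np.exp(-0.5 * ((z - 30.0) / sigma) ** 2))
    curve = DepthDoseCurve(z, dose)
    expected = 30.0 + sigma * np.sqrt(-2.0 * np.log(0.8))
    assert find_r80(curve) == pytest.approx(expected, abs=0.01)


def test_r80_requires_a_distal_crossing():
    z = np.linspace(0.0, 10.0, 50)
    with pytest.raises(ValueError, match="truncated"):
        find_r80(DepthDoseCurve(z, np.linspace(0.5, 1.0, 50)))


def test_dose_conversion_of_identical_curves_is_unity():
    z = np.arange(0.0, 90.0, 0.1)
    dose = np.where(z <= 75.0, 0.3 + z / 100.0,
                    np.exp(-0.5 * ((z - 75.0) / 1.2) ** 2) * 1.05)
    w = DepthDoseCurve(z, dose, "water")
    g = DepthDoseCurve(z.copy(), dose.copy(), "graphite")
    f = compute_dose_conversion(w, g, ref_depth=20.0)
    assert f.value == pytest.approx(1.0, rel=1e-9)


def test_dose_conversion_is_invariant_to_affine_rescaling():
    # graphite = water with depths scaled by a and doses by b: PDD
    # normalization removes b, r80 matching removes a
    from pmbdose.synthetic import generate_depth_dose
    w = generate_depth_dose(76.0)
    a, b = 1.0 / 1.8, 3.7
    g = DepthDoseCurve(w.depths * a, w.dose * b, "graphite")
    f = compute_dose_conversion(w, g, ref_depth=20.0)
    assert f.value == pytest.approx(1.0, rel=1e-6)


def test_dose_conversion_with_a_dose_tilt_matches_a_dense_oracle():
    from pmbdose.synthetic import generate_depth_dose
    w = generate_depth_dose(76.0, step_mm=0.1)
    a, c = 1.0 / 1.8, 0.004
    tilt = 1.0 + c * w.depths
    g = DepthDoseCurve(w.depths * a, w.dose * tilt, "graphite")
    f = compute_dose_conversion(w, g, ref_depth=20.0)

    # independent dense oracle with plain linear interpolation
    wd = w.dose / w.dose.max()
    gd = (w.dose * tilt) / (w.dose * tilt).max()
    zz = np.linspace(0.0, w.depths[-1], 200001)
    wn = np.interp(zz, w.depths, wd)

    # distal crossings on the dense grids
    def r80(z, d):
        imax = np.argmax(d)
        j = imax + np.argmax(d[imax:] < 0.8 * d.max())
        return z[j]
    scale = r80(zz, wn) / r80(zz * a, np.interp(zz, w.depths, gd))
    val = (np.interp(20.0, zz, wn)
           / np.interp(20.0, zz * a * scale, np.interp(zz, w.depths, gd)))
    assert f.value == pytest.approx(val, rel=1e-3)


def test_dose_conversion_rejects_out_of_range_reference():
    z = np.arange(0.0, 50.0, 0.5)
    dose = np.where(z <= 40.0, 0.5 + z / 100.0,
                    np.exp(-0.5 * ((z - 40.0) / 1.0) ** 2))
    w = DepthDoseCurve(z, dose, "water")
    with pytest.raises(ValueError, match="ref_depth"):
        compute_dose_conversion(w, w, ref_depth=80.0)


# ---------------------------------------------------------------------------
# positional Type B on factors
# ---------------------------------------------------------------------------

def test_positional_type_b_is_zero_on_uniform_maps():
    res = positional_type_b_on_factor(_uniform_maps(), "kvert",
                                      n_samples=20_000, seed=3, radius=8.0)
    assert res.combined == pytest.approx(0.0, abs=1e-10)


def test_positional_type_b_matches_the_delta_method_on_a_gradient():
    g = 0.004
    m = _gradient_map(g)
    res = positional_type_b_on_factor([m], "kvert", n_samples=1_000_000,
                                      seed=4, radius=8.0)
    # kvert ratio R(dy) = (1 + g*(-11+dy)) / (1 + g*dy); horizontal is flat
    dR = 11.0 * g * g          # |dR/d(dy)| at 0
    r0 = (1.0 - 11.0 * g)
    expected = 0.5 * dR / r0 * 100.0
    assert res.horizontal == pytest.approx(0.0, abs=1e-8)
    assert res.vertical == pytest.approx(expected, rel=0.03)


def test_percent_deviation_from_unity_reads_off_the_correction():
    assert percent_deviation_from_unity(0.9640) == pytest.approx(3.6)
    assert percent_deviation_from_unity(1.02) == pytest.approx(2.0)


def test_correction_factor_serialization_round_trips_bit_exactly():
    f = CorrectionFactor("kvert_roos", 0.963712345678, 0.37123, 1.5512,
                         note="fixture")
    g = CorrectionFactor.from_dict(f.to_dict())
    assert g == f
    import json
    h = CorrectionFactor.from_dict(json.loads(json.dumps(f.to_dict())))
    assert h.value == f.value and h.type_a == f.type_a
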