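"""Generator tests: minibeam maps, depth-dose curves, calorimeter traces."""

import numpy as np
import pytest
from scipy.integrate import quad

from pmbdose.synthetic import (CalorimeterTrace, MinibeamFieldSpec,
                               generate_calorimeter_trace,
                               generate_depth_dose, generate_minibeam_map,
                               minibeam_dose)
from pmbdose.factors import find_r80


# ---------------------------------------------------------------------------
# minibeam field maps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("override, fragment", [
    (dict(n_slits=0), "n_slits"),
    (dict(slit_width=5.0), "slit_width < pitch"),
    (dict(n_slits=20), "field extent"),
    (dict(blur_sigma=0.0), "blur_sigma"),
    (dict(valley_fraction=1.0), "valley_fraction"),
    (dict(valley_fraction=-0.1), "valley_fraction"),
])
def test_spec_invariants_rejected_with_named_constraint(override, fragment):
    with pytest.raises(ValueError, match=fragment):
        MinibeamFieldSpec(**override)


def test_single_stripe_mass_is_conserved_by_blurring():
    # Gaussian convolution preserves the top-hat mass: the map integral is
    # peak_dose * slit_width * effective slit length (cosine-smoothed ends
    # contribute half their 2 mm span each).
    spec = MinibeamFieldSpec(n_slits=1, valley_fraction=0.0,
                             vertical_gradient=0.0, noise_sd=0.0,
                             peak_dose=10.0)
    m = generate_minibeam_map(spec, pixel_spacing=0.05)
    expected = 10.0 * 0.4 * (50.0 - 2.0)
    assert m.integral() == pytest.approx(expected, rel=1e-3)
    # the marginal over y is a single blurred top-hat: unimodal, centered
    profile = m.values.sum(axis=0)
    assert abs(m.x_coords[np.argmax(profile)]) <= m.pixel_spacing


def test_default_field_has_15_peaks_at_the_slit_centers(mono_map):
    row = mono_map.values[np.argmin(np.abs(mono_map.y_coords)), :]
    interior = (row[1:-1] > row[:-2]) & (row[1:-1] >= row[2:])
    peaks_x = mono_map.x_coords[1:-1][interior]
    # exclude the flat valley plateau at the field edges
    peaks_x = peaks_x[np.abs(peaks_x) < 30.0]
    # cluster plateau-induced duplicates within one pixel
    peaks_x = peaks_x[np.concatenate(([True], np.diff(peaks_x) > 0.5))]
    assert len(peaks_x) == 15
    assert np.allclose(peaks_x, np.arange(-28, 29, 4),
                       atol=mono_map.pixel_spacing)


def test_pvdr_matches_dense_profile_oracle(mono_spec, mono_map):
    # independent oracle: numerically convolve the slit top-hat with the
    # blur Gaussian by quadrature (no erf identity) on the central profile
    sigma = mono_spec.blur_sigma
    v = mono_spec.valley_fraction

    def profile(x):
        tot = 0.0
        for c in mono_spec.slit_centers:
            val, _ = quad(lambda u: np.exp(-0.5 * ((x - u) / sigma) ** 2)
                          / (sigma * np.sqrt(2 * np.pi)),
                          c - 0.2, c + 0.2)
            tot += val
        return v + (1 - v) * tot

    pvdr_oracle = profile(0.0) / profile(2.0)

    row = mono_map.values[np.argmin(np.abs(mono_map.y_coords)), :]
    x = mono_map.x_coords
    peak = row[np.abs(x) < 0.5].max()
    valley = row[np.abs(x - 2.0) < 0.5].min()
    assert peak / valley == pytest.approx(pvdr_oracle, rel=0.01)


def test_map_integral_matches_supersampled_generating_function(mono_spec):
    spec = mono_spec
    m = generate_minibeam_map(spec, pixel_spacing=0.3)
    # 10x supersampled evaluation of the analytic generating function
    s = m.pixel_spacing / 10.0
    n = int(round(72.0 / s))
    xs = (np.arange(n) - (n - 1) / 2.0) * s
    fine = minibeam_dose(spec, xs[None, :], xs[:, None])
    assert m.integral() == pytest.approx(float(fine.sum()) * s * s, rel=5e-3)


def test_generator_is_deterministic_per_seed():
    spec = MinibeamFieldSpec(noise_sd=0.05)
    a = generate_minibeam_map(spec, seed=7, pixel_spacing=0.5)
    b = generate_minibeam_map(spec, seed=7, pixel_spacing=0.5)
    c = generate_minibeam_map(spec, seed=8, pixel_spacing=0.5)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_noise_is_clipped_at_zero_and_needs_a_seed():
    spec = MinibeamFieldSpec(noise_sd=5.0)
    m = generate_minibeam_map(spec, seed=3, pixel_spacing=0.5)
    assert m.values.min() == 0.0
    with pytest.raises(ValueError, match="seed"):
        generate_minibeam_map(spec, pixel_spacing=0.5)


def test_padding_adds_zero_dose_margin(mono_spec):
    m = generate_minibeam_map(mono_spec, pixel_spacing=0.5, pad_mm=10.0)
    xmin, xmax, ymin, ymax = m.bounds
    assert xmax >= 46.0 and ymax >= 46.0
    outside = np.abs(m.x_coords) > 36.0
    assert np.all(m.values[:, outside] == 0.0)


# ---------------------------------------------------------------------------
# depth-dose curves
# ---------------------------------------------------------------------------

def test_pristine_r80_is_at_the_requested_range():
    curve = generate_depth_dose(76.0)
    step = np.diff(curve.depths).max()
    assert abs(find_r80(curve) - 76.0) <= step


def test_sobp_plateau_is_flat_to_one_percent():
    curve = generate_depth_dose(110.0, sobp_width_mm=20.0)
    sel = (curve.depths >= 90.0) & (curve.depths <= 110.0)
    plateau = curve.dose[sel]
    assert (plateau.max() - plateau.min()) / plateau.mean() <= 0.01


def test_r80_stable_under_grid_refinement():
    fine = generate_depth_dose(76.0, step_mm=0.05)
    coarse = generate_depth_dose(76.0, step_mm=0.1)
    assert abs(find_r80(fine) - find_r80(coarse)) <= 0.1


@pytest.mark.parametrize("kwargs", [
    dict(range_mm=-1.0),
    dict(range_mm=50.0, sobp_width_mm=50.0),
    dict(range_mm=50.0, sobp_width_mm=60.0),
])
def test_depth_dose_rejects_invalid_parameters(kwargs):
    with pytest.raises(ValueError):
        generate_depth_dose(**kwargs)


def test_depth_dose_invariants():
    for curve in (generate_depth_dose(76.0),
                  generate_depth_dose(110.0, sobp_width_mm=20.0)):
        assert np.all(np.diff(curve.depths) > 0)
        assert np.all(curve.dose >= 0)


# ---------------------------------------------------------------------------
# calorimeter traces
# ---------------------------------------------------------------------------

def test_zero_dose_trace_is_a_pure_linear_drift():
    tr = generate_calorimeter_trace("quasi_adiabatic", 0.0, drift_rate=0.02)
    assert np.allclose(tr.signal, 0.02 * tr.time, atol=1e-12)


def test_quasi_adiabatic_ramp_height_is_dose_over_heat_capacity():
    # dT = D / c = 1.412 / 706 K = 2.0 mK
    tr = generate_calorimeter_trace("quasi_adiabatic", 1.412, c=706.0)
    assert tr.signal[-1] - tr.signal[0] == pytest.approx(2.0, abs=1e-12)


def test_isothermal_mean_depression_matches_energy_balance():
    # integral of the depression = D * m  ->  mean depression D*m/T
    tr = generate_calorimeter_trace("isothermal", 1.0, mass=1e-3,
                                    baseline_power=10.0,
                                    irradiation=(120.0, 180.0))
    during = (tr.time > 120.0) & (tr.time < 180.0)
    depression = 10.0 - tr.signal[during]
    assert depression.mean() == pytest.approx(1.0 / 60.0, rel=1e-6)


def test_layer_steps_shape_the_quasi_adiabatic_ramp():
    steps = [(120.0, 1.0), (140.0, 0.5), (160.0, 0.25)]
    tr = generate_calorimeter_trace("quasi_adiabatic", 1.0, c=706.0,
                                    layer_steps=steps)
    # ramp slope halves then quarters across the layers
    def slope(t_lo, t_hi):
        sel = (tr.time >= t_lo) & (tr.time <= t_hi)
        return np.polyfit(tr.time[sel], tr.signal[sel], 1)[0]
    s1, s2, s3 = (slope(121, 139), slope(141, 159), slope(161, 179))
    assert s2 == pytest.approx(0.5 * s1, rel=1e-6)
    assert s3 == pytest.approx(0.25 * s1, rel=1e-6)


def test_trace_validation():
    with pytest.raises(ValueError, match="t_start < t_end"):
        generate_calorimeter_trace("quasi_adiabatic", 1.0,
                                   irradiation=(180.0, 120.0))
    with pytest.raises(ValueError, match="seed"):
        generate_calorimeter_trace("isothermal", 1.0, noise_sd=0.01)
    with pytest.raises(ValueError, match="mode"):
        generate_calorimeter_trace("unknown", 1.0)
    with pytest.raises(ValueError, match="constant"):
        CalorimeterTrace(np.array([0.0, 1.0, 3.0]), np.zeros(3),
                         "quasi_adiabatic", (0.5, 2.0))
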