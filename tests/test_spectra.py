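"""Spectrum model, mock predictor, peak matching, similarity metrics and
retention-time calibration."""

import numpy as np
import pytest

from splicescope.spectra import (
    PROTON_MASS,
    RESIDUE_MASS,
    WATER_MASS,
    MockSpectrumPredictor,
    PredictorError,
    Spectrum,
    fit_irt_calibration,
    fragment_mz,
    irt_error,
    match_peaks,
    spectral_angle,
    spearman_similarity,
)


def test_mock_predictor_is_deterministic(predictor):
    a = predictor.predict("ACDEFGHIK", 2)
    b = MockSpectrumPredictor().predict("ACDEFGHIK", 2)
    assert np.array_equal(a.mz, b.mz)
    assert np.array_equal(a.intensity, b.intensity)
    assert a.predicted_irt == b.predicted_irt


def test_y1_fragment_mass_closed_form():
    assert fragment_mz("AG", "y", 1) == pytest.approx(
        RESIDUE_MASS["G"] + WATER_MASS + PROTON_MASS
    )
    assert fragment_mz("AG", "b", 1) == pytest.approx(
        RESIDUE_MASS["A"] + PROTON_MASS
    )


def test_distinct_peptides_do_not_match_perfectly(predictor):
    a = predictor.predict("ACDEFGHIK", 2)
    b = predictor.predict("ACDEFGHIW", 2)
    v_pred, v_obs = match_peaks(
        Spectrum("x", 500.0, 2, 10.0, b.mz, b.intensity), a
    )
    assert spectral_angle(v_pred, v_obs) < 1.0


def test_predictor_rejects_unsupported_input(predictor):
    with pytest.raises(PredictorError):
        predictor.predict("ACDEZ", 2)
    with pytest.raises(PredictorError):
        predictor.predict("A", 2)


def test_match_peaks_identical_and_disjoint(predictor):
    pred = predictor.predict("ACDEFGHIK", 2)
    obs = Spectrum("s", 500.0, 2, 10.0, pred.mz, pred.intensity)
    v_pred, v_obs = match_peaks(obs, pred, tolerance=0.02)
    assert np.array_equal(v_obs, pred.intensity)
    far = Spectrum("s2", 500.0, 2, 10.0, pred.mz + 5.0, pred.intensity)
    _, v_obs = match_peaks(far, pred, tolerance=0.02)
    assert not np.any(v_obs)


def test_match_peaks_nearest_tie_break(predictor):
    pred = predictor.predict("ACDEFGHIK", 2)
    target = pred.mz[3]
    obs_mz = np.array([target - 0.015, target + 0.005])
    obs = Spectrum("s", 500.0, 2, 10.0, obs_mz, np.array([10.0, 20.0]))
    _, v_obs = match_peaks(obs, pred, tolerance=0.02)
    assert v_obs[3] == 20.0  # nearest peak wins


def test_match_peaks_monotone_in_tolerance(predictor, rng):
    pred = predictor.predict("ACDEFGHIK", 2)
    jittered = Spectrum(
        "s", 500.0, 2, 10.0,
        np.sort(pred.mz + rng.normal(0, 0.01, pred.mz.size)),
        pred.intensity,
    )
    matched = [
        np.count_nonzero(match_peaks(jittered, pred, tolerance=t)[1])
        for t in (0.001, 0.005, 0.02, 0.1)
    ]
    assert matched == sorted(matched)
    assert len(match_peaks(jittered, pred)[0]) == pred.mz.size


@pytest.mark.parametrize(
    "v1,v2,expected",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
        ([1.0, 0.0], [0.0, 1.0], 0.0),
        ([1.0, 1.0], [1.0, 0.0], 0.5),  # cosine sqrt(2)/2 -> angle pi/4
    ],
)
def test_spectral_angle_analytic(v1, v2, expected):
    assert spectral_angle(np.array(v1), np.array(v2)) == pytest.approx(expected)


def test_spectral_angle_properties(rng):
    for _ in range(100):
        v1 = rng.uniform(0, 1, 20)
        v2 = rng.uniform(0, 1, 20)
        sa = spectral_angle(v1, v2)
        assert 0.0 <= sa <= 1.0
        assert sa == pytest.approx(spectral_angle(v2, v1))
        assert sa == pytest.approx(spectral_angle(3.7 * v1, v2))
    assert spectral_angle(v1, 2.5 * v1) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        spectral_angle(np.zeros(3), np.zeros(3))


def test_spearman_similarity_examples():
    assert spearman_similarity([1, 2, 3], [2, 4, 9]) == pytest.approx(1.0)
    assert spearman_similarity([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    # hand-computed: d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
    assert spearman_similarity([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    assert np.isnan(spearman_similarity([1.0, 1.0, 1.0], [1, 2, 3]))


def test_irt_calibration_exact_line():
    irt = np.linspace(0, 50, 40)
    rt = 2.0 * irt + 5.0
    sa = np.full(40, 0.95)
    calib = fit_irt_calibration(irt, rt, sa, np.zeros(40, dtype=bool))
    assert calib.slope == pytest.approx(2.0)
    assert calib.intercept == pytest.approx(5.0)
    assert np.allclose(irt_error(irt, rt, calib), 0.0)
    assert not calib.used_fallback


def test_irt_calibration_excludes_spliced_outlier():
    irt = np.r_[np.linspace(0, 50, 40), 25.0]
    rt = np.r_[2.0 * np.linspace(0, 50, 40) + 5.0, 500.0]
    sa = np.full(41, 0.95)
    is_spliced = np.r_[np.zeros(40, dtype=bool), True]
    calib = fit_irt_calibration(irt, rt, sa, is_spliced)
    assert calib.slope == pytest.approx(2.0)
    assert calib.intercept == pytest.approx(5.0)


def test_irt_calibration_fallback_and_recovery(rng):
    n = 100
    irt = rng.uniform(0, 60, n)
    rt = 1.7 * irt + 3.0 + rng.normal(0, 0.5, n)
    sa = rng.uniform(0.3, 0.8, n)  # nobody passes the 0.9 gate
    calib = fit_irt_calibration(irt, rt, sa, np.zeros(n, dtype=bool))
    assert calib.used_fallback
    se = 0.5 / np.sqrt(np.sum((irt - irt.mean()) ** 2))
    assert abs(calib.slope - 1.7) < 3 * se
    assert np.isfinite(calib.oof_residuals).all()


def test_irt_calibration_needs_two_points():
    with pytest.raises(ValueError):
        fit_irt_calibration(
            np.array([1.0]), np.array([2.0]), np.array([0.95]),
            np.array([False]),
        )


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum("s", 500.0, 2, 1.0, np.array([2.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        Spectrum("s", 500.0, 2, 1.0, np.array([1.0, 2.0]), np.array([1.0, -1.0]))
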