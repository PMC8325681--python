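"""Ks sample filtering, peak recovery, rate correction and clock dating."""

import math

import numpy as np
import pytest

from paleowgd.ks_distribution import (
    PeakEstimate,
    apply_correction,
    build_ks_sample,
    date_event,
    estimate_peak,
    rate_correction,
)


def lognormal_sample(mode: float, sigma: float, n: int, seed: int) -> list[float]:
    rng = np.random.default_rng(seed)
    return list(np.exp(rng.normal(math.log(mode), sigma, size=n)))


# --------------------------------------------------------------- filtering
def test_build_sample_filters_undefined_and_out_of_range():
    sample = build_ks_sample([0.2, 0.5, 9.9, None], hi=3.0)
    assert sorted(sample.values) == [0.2, 0.5]
    with pytest.raises(ValueError):
        build_ks_sample([])
    with pytest.raises(ValueError):
        build_ks_sample([None, float("nan"), 99.0])


def test_build_sample_retains_simulated_lognormal():
    values = lognormal_sample(0.4, 0.2, 2000, seed=1)
    sample = build_ks_sample(values)
    assert len(sample) >= 1990  # essentially everything inside (0.01, 3)


# ------------------------------------------------------------------- peaks
def test_point_mass_peak_is_exact():
    sample = build_ks_sample([0.4] * 100)
    assert estimate_peak(sample, method="kde").mode == pytest.approx(0.4)


def test_kde_and_gmm_recover_unimodal_mode():
    sample = build_ks_sample(lognormal_sample(0.4, 0.25, 2000, seed=2))
    for method in ("kde", "gmm"):
        peak = estimate_peak(sample, method=method, seed=0)
        assert abs(peak.mode - 0.4) <= 0.05, method


def test_gmm_finds_heavier_of_two_components():
    values = lognormal_sample(0.4, 0.2, 1400, seed=3) + lognormal_sample(
        1.1, 0.25, 600, seed=4
    )
    peak = estimate_peak(build_ks_sample(values), method="gmm", seed=0)
    assert peak.n_components == 2
    assert abs(peak.mode - 0.4) <= 0.05
    assert sum(w for w, _, _ in peak.components) == pytest.approx(1.0, abs=1e-9)


def test_grape_like_background_peaks_near_its_mode():
    sample = build_ks_sample(lognormal_sample(1.1, 0.2, 2000, seed=5))
    peak = estimate_peak(sample, method="gmm", seed=0)
    assert abs(peak.mode - 1.1) <= 0.08


def test_small_sample_gmm_falls_back_to_kde():
    sample = build_ks_sample([0.3, 0.4, 0.5] * 5)
    peak = estimate_peak(sample, method="gmm", seed=0)
    assert peak.method == "kde"


def test_peak_estimation_deterministic_given_seed():
    sample = build_ks_sample(lognormal_sample(0.5, 0.3, 500, seed=6))
    p1 = estimate_peak(sample, method="gmm", seed=7)
    p2 = estimate_peak(sample, method="gmm", seed=7)
    assert p1 == p2


# -------------------------------------------------------------- correction
def test_correction_coefficient_arithmetic():
    ref = PeakEstimate(mode=0.8, method="kde")
    assert rate_correction(ref, PeakEstimate(mode=0.8, method="kde")).coefficient == 1.0
    corr = rate_correction(ref, PeakEstimate(mode=1.0, method="kde"))
    assert corr.coefficient == pytest.approx(0.8)
    sample = build_ks_sample([1.0, 2.0])
    corrected = apply_correction(sample, corr)
    assert corrected.values == pytest.approx((0.8, 1.6))
    assert corrected.filter_range == sample.filter_range


def test_correction_rescales_peak_consistently():
    """Peak of the corrected sample equals C times the original peak, and the
    rescaled split peaks of two lineages coincide (the equality the
    correction enforces)."""
    sample = build_ks_sample(lognormal_sample(0.53, 0.2, 2000, seed=8))
    original = estimate_peak(sample, method="kde")
    corr = rate_correction(
        PeakEstimate(mode=0.781, method="kde"), PeakEstimate(mode=0.976, method="kde")
    )
    corrected = estimate_peak(apply_correction(sample, corr), method="kde")
    assert corrected.mode == pytest.approx(original.mode * corr.coefficient, rel=0.02)


def test_zero_split_peak_rejected():
    with pytest.raises(ValueError):
        rate_correction(
            PeakEstimate(mode=0.8, method="kde"), PeakEstimate(mode=0.0, method="kde")
        )


# ------------------------------------------------------------------ dating
def test_dating_calibration_identity():
    result = date_event(0.781, (0.781, 118.0))
    assert result.t == pytest.approx(118.0, rel=1e-12)
    assert result.r == pytest.approx(0.781 / 236.0, rel=1e-12)


def test_dating_worked_example():
    result = date_event(0.425, (0.781, 118.0))
    assert result.t == pytest.approx(0.425 * 118.0 / 0.781, rel=1e-12)
    assert result.t == pytest.approx(64.2, abs=0.05)


def test_dating_linear_in_event_peak():
    t1 = date_event(0.2, (0.781, 118.0)).t
    t2 = date_event(0.4, (0.781, 118.0)).t
    assert t2 == pytest.approx(2 * t1, rel=1e-12)


@pytest.mark.parametrize("peak,cal", [(0.0, (0.781, 118)), (0.4, (0.0, 118)), (0.4, (0.781, 0))])
def test_dating_rejects_nonpositive_inputs(peak, cal):
    with pytest.raises(ValueError):
        date_event(peak, cal)
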