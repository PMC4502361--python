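"""Sone formula, exponent calibration, equal-loudness contour machinery."""

import numpy as np
import pytest

from angain.loudness import (
    DEFAULT_ELC_FREQUENCIES,
    DEFAULT_PHON_LEVELS,
    ActivityCurve,
    LoudnessCalibration,
    StepPolicy,
    calibrate_x,
    compute_elc_set,
    elcs_to_frame,
    find_equal_loudness_level,
    loudness_sones,
    sone_scale_law,
    to_model_hl,
)


# -- sones ------------------------------------------------------------------


def test_reference_tone_is_one_sone(micro_model):
    """The calibration responses give exactly 1 sone by construction."""
    cal = micro_model.loudness_
    summed = micro_model.response(1000.0, 40.0).summed()
    assert loudness_sones(summed, cal) == pytest.approx(1.0, abs=1e-9)


def test_baseline_activity_is_zero_sones():
    cal = LoudnessCalibration(x=1.61, reference_sum=1000.0, spontaneous_sum=500.0)
    assert loudness_sones(500.0, cal) == 0.0
    assert loudness_sones(100.0, cal) == 0.0  # below-baseline clamps


def test_doubling_the_evoked_sum_gives_two_to_the_x():
    cal = LoudnessCalibration(x=1.61, reference_sum=1000.0, spontaneous_sum=500.0)
    assert loudness_sones(2500.0, cal) == pytest.approx(2.0**1.61)


def test_loudness_doubling_per_ten_db(micro_model):
    """50 -> 60 dB SPL at 1 kHz doubles the sone value within 15%."""
    cal = micro_model.loudness_
    s50 = loudness_sones(micro_model.response(1000.0, 50.0).summed(), cal)
    s60 = loudness_sones(micro_model.response(1000.0, 60.0).summed(), cal)
    assert s60 / s50 == pytest.approx(2.0, rel=0.15)


# -- exponent calibration ---------------------------------------------------


def _levels():
    return np.arange(30.0, 91.0, 10.0)


def test_calibrate_x_identity_when_responses_equal_targets():
    spont = 100.0
    summed = {lv: spont + 50.0 * sone_scale_law(lv) for lv in _levels()}
    assert calibrate_x(summed, spont) == pytest.approx(1.0, abs=1e-9)


def test_calibrate_x_recovers_constructed_exponent():
    """Responses built as s(L)^(1/1.5) must refit to x = 1.5 exactly."""
    spont = 100.0
    summed = {lv: spont + 50.0 * sone_scale_law(lv) ** (1 / 1.5) for lv in _levels()}
    assert calibrate_x(summed, spont) == pytest.approx(1.5, abs=0.01)


def test_calibrate_x_rejects_non_monotone():
    spont = 0.0
    summed = {30.0: 10.0, 40.0: 20.0, 50.0: 15.0, 60.0: 30.0, 70.0: 40.0}
    with pytest.raises(ValueError, match="monotone"):
        calibrate_x(summed, spont)


def test_calibrate_x_requires_enough_levels():
    with pytest.raises(ValueError):
        calibrate_x({40.0: 1.0, 50.0: 2.0}, 0.0)


# -- equal-loudness search --------------------------------------------------


def _synthetic_activity(level):
    # smooth, monotone, roughly sigmoidal in log activity
    return 1000.0 + 2000.0 / (1.0 + np.exp(-(level - 57.3) / 12.0))


def test_search_matches_dense_grid_oracle():
    """The 2/10-dB stepping + interpolation lands within 1 dB of a 0.1-dB
    brute-force grid."""
    target = _synthetic_activity(57.3)
    found, flag = find_equal_loudness_level(_synthetic_activity, target)
    assert flag == "ok"
    grid = np.arange(-20.0, 130.0, 0.1)
    acts = _synthetic_activity(grid)
    brute = grid[np.argmax(acts >= target)]
    assert abs(found - brute) <= 1.0
    assert found == pytest.approx(57.3, abs=1.0)


def test_search_self_match_on_model_curve(micro_surface):
    curves = micro_surface.activity_curves()
    c = curves[1000.0]
    target = c.at_level(50.0)
    found, flag = c.invert(target)
    assert flag == "ok"
    assert found == pytest.approx(50.0, abs=1e-9)


def test_unreachable_reference_is_flagged():
    curve = ActivityCurve(frequency=1000.0,
                          levels=np.arange(-20.0, 131.0, 10.0),
                          summed=np.linspace(100.0, 200.0, 16))
    lvl, flag = curve.invert(50.0)  # below the spontaneous floor
    assert flag == "below-range"
    lvl, flag = curve.invert(500.0)  # beyond the grid ceiling
    assert flag == "above-range"


def test_non_monotone_activity_rejected_by_search():
    def wobble(level):
        return 1000.0 + level - 30.0 * np.sin(level / 5.0)

    with pytest.raises(ValueError, match="monotone"):
        find_equal_loudness_level(wobble, 1050.0)


# -- contour sets -----------------------------------------------------------


@pytest.fixture(scope="module")
def elcs(micro_surface):
    return compute_elc_set(micro_surface.activity_curves())


def test_default_set_has_eighteen_contours(elcs):
    assert len(elcs) == 18
    assert [e.phon_level for e in elcs] == sorted(e.phon_level for e in elcs)


def test_contours_contain_reference_point(elcs):
    for e in elcs:
        assert e.points[1000.0] == e.phon_level
        assert set(e.points) == set(DEFAULT_ELC_FREQUENCIES)


def test_contours_do_not_cross(elcs):
    """Higher reference level means pointwise higher (or flagged) levels."""
    for lo, hi in zip(elcs, elcs[1:]):
        for f in lo.points:
            if lo.flags[f] == "ok" and hi.flags[f] == "ok":
                assert hi.points[f] >= lo.points[f] - 1e-9


def test_model_hl_normalisation(elcs):
    hl = to_model_hl(elcs)
    two = [e for e in hl if e.phon_level == 2][0]
    assert all(v == 0.0 for v in two.model_hl.values())
    forty = [e for e in hl if e.phon_level == 40][0]
    base = [e for e in elcs if e.phon_level == 2][0]
    assert forty.model_hl[1000.0] == pytest.approx(40.0 - base.points[1000.0])
    # ordering preserved under the common per-frequency offset
    for lo, hi in zip(hl, hl[1:]):
        for f in lo.model_hl:
            if lo.flags[f] == "ok" and hi.flags[f] == "ok":
                assert hi.model_hl[f] >= lo.model_hl[f] - 1e-9


def test_model_hl_requires_two_phon_contour(elcs):
    with pytest.raises(ValueError, match="2-phon"):
        to_model_hl([e for e in elcs if e.phon_level != 2])


def test_contour_frame_layout(elcs):
    frame = elcs_to_frame(to_model_hl(elcs))
    assert list(frame.columns) == [
        "phon_level", "frequency_hz", "level_db_spl", "level_db_model_hl", "flag",
    ]
    assert len(frame) == 18 * len(DEFAULT_ELC_FREQUENCIES)


def test_step_policy_grids():
    pol = StepPolicy()
    coarse = pol.coarse_grid()
    assert coarse[0] == -60.0 and coarse[-1] == 160.0
    fine = pol.fine_grid(0.0)
    assert np.allclose(np.diff(fine), 2.0)
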