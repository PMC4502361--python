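"""Outer/middle-ear filter, broken-stick compression, DRNL filterbank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from angain.erb import erb_number, erb_space
from angain.periphery import (
    DRNLFilterbank,
    OuterMiddleEarConfig,
    apply_outer_middle_ear,
    broken_stick,
    load_drnl_params,
    make_human_filterbank,
    save_drnl_params,
)
from angain.stimuli import synthesize_tone, synthesize_white_noise

FS = 44100.0


def _band_gain_db(x, y, lo, hi, fs=FS):
    f, pxx = signal.welch(x, fs=fs, nperseg=8192)
    _f, pyy = signal.welch(y, fs=fs, nperseg=8192)
    m = (f >= lo) & (f <= hi)
    return 10.0 * np.log10(pyy[m].sum() / pxx[m].sum())


@pytest.fixture(scope="module")
def ome_noise():
    stim = synthesize_white_noise(60.0, 20.0, FS, seed=5)
    return stim.samples, apply_outer_middle_ear(stim)


@pytest.mark.parametrize(
    "lo,hi,expected",
    [(2500.0, 4000.0, -2.0), (4700.0, 6100.0, -3.0), (9000.0, 11000.0, -19.0)],
)
def test_ome_band_gains(ome_noise, lo, hi, expected):
    """White-noise band power matches the printed branch gains."""
    x, y = ome_noise
    assert _band_gain_db(x, y, lo, hi) == pytest.approx(expected, abs=0.5)


def test_ome_stopband_attenuates_low_tone():
    stim = synthesize_tone(200.0, 80.0, 1.0, FS)
    out = apply_outer_middle_ear(stim)
    atten = 20.0 * np.log10(stim.rms / np.sqrt(np.mean(out**2)))
    assert atten > 30.0  # far beyond the weakest branch gain of 19 dB


def test_ome_is_linear_time_invariant():
    stim = synthesize_tone(3000.0, 60.0, 0.3, FS)
    y1 = apply_outer_middle_ear(stim)
    y2 = apply_outer_middle_ear(stim.scaled_to(72.0))
    np.testing.assert_allclose(y2, y1 * 10 ** (12.0 / 20.0), rtol=1e-10)


def test_ome_rejects_low_sample_rate():
    with pytest.raises(ValueError):
        apply_outer_middle_ear(np.zeros(100), OuterMiddleEarConfig(), sample_rate=20000.0)


def test_ome_requires_three_ordered_bands():
    with pytest.raises(ValueError):
        OuterMiddleEarConfig(bands=((100.0, 50.0, 0.0),) * 3)
    with pytest.raises(ValueError):
        OuterMiddleEarConfig(bands=((100.0, 200.0, 0.0),))


# -- broken stick -----------------------------------------------------------


def test_broken_stick_zero_maps_to_zero():
    assert broken_stick(0.0, 1000.0, 0.1, 0.25) == 0.0


@settings(deadline=None, max_examples=50)
@given(st.floats(-1e3, 1e3, allow_nan=False))
def test_broken_stick_is_odd(i):
    a, b, c = 1000.0, 0.1, 0.25
    assert broken_stick(-i, a, b, c) == pytest.approx(-broken_stick(i, a, b, c))


def test_broken_stick_linear_branch_for_small_inputs():
    a, b, c = 1000.0, 0.1, 0.25
    i = 1e-12  # a|i| << b|i|^c
    assert broken_stick(i, a, b, c) == pytest.approx(a * i)


def test_broken_stick_compressive_slope_equals_c():
    a, b, c = 1000.0, 0.1, 0.25
    knee = (b / a) ** (1.0 / (1.0 - c))
    i = np.logspace(np.log10(knee * 10), np.log10(knee * 1e4), 200)
    y = broken_stick(i, a, b, c)
    slopes = np.diff(np.log10(y)) / np.diff(np.log10(i))
    assert np.allclose(slopes, c, atol=0.05)


def test_broken_stick_rejects_bad_exponent():
    with pytest.raises(ValueError):
        broken_stick(1.0, 1.0, 1.0, 1.5)


# -- filterbank construction ------------------------------------------------


def test_human_filterbank_endpoints_and_ordering():
    bank = make_human_filterbank(500, 40.0, 13000.0)
    cfs = bank.cfs
    assert cfs.size == 500
    assert cfs[0] == 40.0 and cfs[-1] == 13000.0
    assert np.all(np.diff(cfs) > 0)


def test_two_channel_bank_is_just_the_endpoints():
    bank = make_human_filterbank(2, 40.0, 13000.0)
    np.testing.assert_allclose(bank.cfs, [40.0, 13000.0])


def test_cfs_evenly_spaced_on_erb_scale():
    bank = make_human_filterbank(100, 40.0, 13000.0)
    e = erb_number(bank.cfs)
    steps = np.diff(e)
    assert np.allclose(steps, steps[0], rtol=1e-6)


def test_out_of_validity_range_warns():
    with pytest.warns(UserWarning):
        make_human_filterbank(10, 20.0, 13000.0)


def test_erb_space_inverts_erb_number():
    f = erb_space(40.0, 13000.0, 7)
    np.testing.assert_allclose(
        np.diff(erb_number(f)), np.full(6, (erb_number(13000.0) - erb_number(40.0)) / 6)
    )


def test_drnl_params_round_trip(tmp_path):
    params = load_drnl_params()
    path = tmp_path / "params.yaml"
    save_drnl_params(params, path)
    assert load_drnl_params(path) == params


# -- DRNL behaviour ---------------------------------------------------------


@pytest.fixture(scope="module")
def small_bank():
    bank = make_human_filterbank(5, 250.0, 4000.0)
    return DRNLFilterbank(bank, 32000.0, stapes_scale=1.5e-2)


def _on_cf_mean_response(fb, index, level, pathway="both"):
    cf = fb.cfs[index]
    stim = synthesize_tone(cf, level, 0.3, fb.sample_rate)
    tr = fb.process_channel(index, stim.samples, pathway=pathway)
    return float(np.mean(np.abs(tr)))


def _knee_level_db(fb, index):
    """Level (dB SPL) where the on-CF broken-stick input reaches the knee."""
    ch = fb.config.channels[index]
    i_knee = (ch.b / ch.a) ** (1.0 / (1.0 - ch.c))
    peak_per_db0 = fb.stapes_scale * np.sqrt(2.0) * 20e-6
    return 20.0 * np.log10(i_knee / peak_per_db0)


def test_drnl_io_slopes_linear_then_compressive(small_bank):
    """On-CF growth is ~1 dB/dB below the knee; well above it the
    compressive pathway settles to the channel's exponent c dB/dB."""
    idx = int(np.argmin(np.abs(small_bank.cfs - 1000.0)))
    c = small_bank.config.channels[idx].c
    knee = _knee_level_db(small_bank, idx)
    low_levels = np.arange(knee - 25.0, knee - 10.0, 2.0)
    resp = np.array([_on_cf_mean_response(small_bank, idx, lv) for lv in low_levels])
    low = np.diff(20.0 * np.log10(resp)) / np.diff(low_levels)
    assert np.allclose(low, 1.0, atol=0.1)
    mid_levels = np.arange(knee + 15.0, knee + 30.0, 2.0)
    resp = np.array(
        [_on_cf_mean_response(small_bank, idx, lv, "nonlinear") for lv in mid_levels]
    )
    mid = np.diff(20.0 * np.log10(resp)) / np.diff(mid_levels)
    assert np.allclose(mid, c, atol=0.05)


def test_drnl_tuning_off_cf_is_weaker(small_bank):
    """Two octaves below CF the (linear-regime) response is far smaller."""
    idx = int(np.argmin(np.abs(small_bank.cfs - 1000.0)))
    cf = small_bank.cfs[idx]
    level = _knee_level_db(small_bank, idx) - 15.0
    on = synthesize_tone(cf, level, 0.3, small_bank.sample_rate)
    off = synthesize_tone(cf / 4.0, level, 0.3, small_bank.sample_rate)
    r_on = np.mean(np.abs(small_bank.process_channel(idx, on.samples)))
    r_off = np.mean(np.abs(small_bank.process_channel(idx, off.samples)))
    assert r_off < 0.1 * r_on


def test_drnl_deterministic(small_bank):
    stim = synthesize_tone(1000.0, 50.0, 0.1, small_bank.sample_rate)
    a = small_bank.process(stim.samples)
    b = small_bank.process(stim.samples)
    np.testing.assert_array_equal(a, b)


def test_drnl_rejects_too_low_sample_rate():
    bank = make_human_filterbank(5, 250.0, 13000.0)
    with pytest.raises(ValueError):
        DRNLFilterbank(bank, 16000.0)
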