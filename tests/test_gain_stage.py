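"""Healthy-control gain and the eight hyperacusis gain variants."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from angain.an_population import ANResponse
from angain.gain_stage import (
    ALL_VARIANTS,
    HyperacusisGainSpec,
    QuadraticGain,
    apply_healthy_gain,
    apply_hyperacusis_gain,
    transform_rates,
)

MAX_RATES = np.array([1000.0, 1000.0, 1000.0])


def _response(rates, spont=None):
    rates = np.asarray(rates, float)
    if spont is None:
        spont = np.tile([35.0, 8.0, 2.0], (rates.shape[0], 1))
    cfs = np.geomspace(125.0, 8000.0, rates.shape[0])
    return ANResponse(rates=rates, spontaneous=spont, cfs=cfs)


@pytest.fixture
def resp():
    rng = np.random.default_rng(0)
    base = np.tile([35.0, 8.0, 2.0], (6, 1))
    return _response(base + rng.uniform(0.0, 300.0, size=(6, 3)))


def test_unit_gain_is_identity(resp):
    out = apply_healthy_gain(resp, QuadraticGain(a=1.0))
    np.testing.assert_array_equal(out.rates, resp.rates)


def test_constant_gain_doubles_rates_and_baseline(resp):
    out = apply_healthy_gain(resp, QuadraticGain(a=2.0))
    np.testing.assert_allclose(out.rates, 2.0 * resp.rates)
    np.testing.assert_allclose(out.spontaneous, 2.0 * resp.spontaneous)


def test_summed_output_matches_direct_weighted_sum(resp):
    g = QuadraticGain(a=1.0, b=1e-8, c=2000.0)
    out = apply_healthy_gain(resp, g)
    w = g.values(resp.cfs)
    brute = sum(
        w[i] * resp.rates[i, j]
        for i in range(resp.rates.shape[0])
        for j in range(3)
    )
    assert out.summed() == pytest.approx(brute, rel=1e-12)


def test_nonpositive_gain_rejected(resp):
    with pytest.raises(ValueError):
        transform_rates(resp.rates, resp.spontaneous, resp.cfs,
                        np.full(6, -1.0))


def test_quadratic_dip_clipped_with_warning():
    g = QuadraticGain(a=-1.0, b=1e-9, c=0.0)
    with pytest.warns(UserWarning, match="floor"):
        vals = g.values(np.array([125.0, 8000.0]))
    assert np.all(vals > 0)


def test_supra_threshold_gain_inert_at_baseline(resp):
    """With rates exactly at the baseline, any supra variant reduces to the
    healthy gain alone."""
    at_rest = _response(resp.spontaneous.copy(), resp.spontaneous)
    ghc = QuadraticGain(a=1.5)
    for spec in ALL_VARIANTS:
        if spec.scope != "supra":
            continue
        out = apply_hyperacusis_gain(at_rest, spec.with_gain(
            spec.gain if not isinstance(spec.gain, QuadraticGain)
            else QuadraticGain(a=3.0)), ghc, MAX_RATES)
        np.testing.assert_allclose(out.rates, 1.5 * at_rest.spontaneous)


def test_linear_sub_threshold_with_unit_gain_equals_healthy(resp):
    ghc = QuadraticGain(a=1.2)
    spec = HyperacusisGainSpec(form="linear", scope="sub",
                               frequency="independent", gain=1.0)
    out = apply_hyperacusis_gain(resp, spec, ghc, MAX_RATES)
    healthy = apply_healthy_gain(resp, ghc)
    np.testing.assert_allclose(out.rates, healthy.rates)


def test_power_law_gain_equals_gmax_at_saturation():
    rates = np.full((4, 3), 1000.0)
    r = _response(rates)
    spec = HyperacusisGainSpec(form="power", scope="sub",
                               frequency="independent", gain=2.5)
    ghc = QuadraticGain(a=1.0)
    out = apply_hyperacusis_gain(r, spec, ghc, MAX_RATES)
    np.testing.assert_allclose(out.rates, 2.5 * rates)


@settings(deadline=None, max_examples=30)
@given(
    rates=hnp.arrays(float, (5, 3), elements=st.floats(0.0, 2000.0)),
    gmax=st.floats(0.1, 50.0),
    z=st.floats(0.5, 3.0),
)
def test_power_law_gain_never_exceeds_gmax(rates, gmax, z):
    r = _response(rates)
    spec = HyperacusisGainSpec(form="power", scope="sub",
                               frequency="independent", gain=gmax, z=z)
    out = apply_hyperacusis_gain(r, spec, QuadraticGain(a=1.0), MAX_RATES)
    with np.errstate(invalid="ignore"):
        implied_gain = np.where(rates > 0, out.rates / rates, 0.0)
    assert np.all(implied_gain <= gmax * (1 + 1e-12))


def test_frequency_independent_equals_quadratic_with_zero_curvature(resp):
    ghc = QuadraticGain(a=1.0)
    flat = HyperacusisGainSpec(form="linear", scope="sub",
                               frequency="independent", gain=3.0)
    quad = HyperacusisGainSpec(form="linear", scope="sub",
                               frequency="quadratic",
                               gain=QuadraticGain(a=3.0, b=0.0))
    a = apply_hyperacusis_gain(resp, flat, ghc, MAX_RATES)
    b = apply_hyperacusis_gain(resp, quad, ghc, MAX_RATES)
    np.testing.assert_allclose(a.rates, b.rates)


@pytest.mark.parametrize("spec", ALL_VARIANTS, ids=lambda s: s.label)
def test_monotone_in_rates(spec, resp):
    """Raising every fiber rate never lowers the gained summed activity."""
    ghc = QuadraticGain(a=1.0)
    spec = spec if not isinstance(spec.gain, QuadraticGain) else spec.with_gain(
        QuadraticGain(a=2.0, b=1e-8, c=1000.0)
    )
    lo = apply_hyperacusis_gain(resp, spec, ghc, MAX_RATES).summed()
    bigger = _response(resp.rates + 50.0, resp.spontaneous)
    hi = apply_hyperacusis_gain(bigger, spec, ghc, MAX_RATES).summed()
    assert hi >= lo


def test_sub_raises_baseline_supra_preserves_it(resp):
    """The tinnitus-vs-no-tinnitus distinction: sub-threshold gain amplifies
    spontaneous activity, supra-threshold gain leaves it unchanged."""
    ghc = QuadraticGain(a=1.0)
    at_rest = _response(resp.spontaneous.copy(), resp.spontaneous)
    base = at_rest.summed()
    sub = HyperacusisGainSpec(form="linear", scope="sub",
                              frequency="independent", gain=2.0)
    supra = HyperacusisGainSpec(form="linear", scope="supra",
                                frequency="independent", gain=2.0)
    assert apply_hyperacusis_gain(at_rest, sub, ghc, MAX_RATES).summed() \
        == pytest.approx(2.0 * base)
    assert apply_hyperacusis_gain(at_rest, supra, ghc, MAX_RATES).summed() \
        == pytest.approx(base)


def test_exactly_eight_variants_encoded():
    labels = {v.label for v in ALL_VARIANTS}
    assert len(ALL_VARIANTS) == 8 and len(labels) == 8


@pytest.mark.parametrize("spec", ALL_VARIANTS, ids=lambda s: s.label)
def test_spec_yaml_round_trip(spec, tmp_path):
    spec = spec if not isinstance(spec.gain, QuadraticGain) else spec.with_gain(
        QuadraticGain(a=1.5, b=2e-8, c=3000.0)
    )
    path = tmp_path / "spec.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh)
    with open(path) as fh:
        back = HyperacusisGainSpec.from_dict(yaml.safe_load(fh))
    assert back == spec


def test_invalid_variant_flags_rejected():
    with pytest.raises(ValueError):
        HyperacusisGainSpec(form="cubic", scope="sub", frequency="independent")
    with pytest.raises(ValueError):
        HyperacusisGainSpec(form="linear", scope="sub", frequency="quadratic",
                            gain=2.0)
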