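"""Central gain stage: healthy-control gain and hyperacusis gain variants.

The healthy-control gain is a quadratic function of characteristic
frequency, g_hc(cf) = a + b*(cf - c)^2, fitted so model equal-loudness
contours match control-subject loudness discomfort levels.  A hyperacusis
gain is one of 2x2x2 = 8 variants: {linear | power-law} x {sub-threshold |
supra-threshold} x {frequency-independent | quadratic frequency-dependent}.

With raw fiber rate R, spontaneous rate Rsp, and per-fiber gain factor g:

    linear      g = g_l(cf)
    power-law   g = (R / Rmax)^z * g_max(cf)          (always <= g_max)
    sub         R' = g * g_hc * R
    supra       R' = (max(0, R - Rsp) * g + Rsp) * g_hc
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .erb import erb_number

__all__ = [
    "QuadraticGain",
    "HyperacusisGainSpec",
    "ALL_VARIANTS",
    "apply_healthy_gain",
    "apply_hyperacusis_gain",
    "transform_rates",
]

#: Floor used when a fitted quadratic dips non-positive.
GAIN_FLOOR = 1e-3


@dataclass(frozen=True)
class QuadraticGain:
    """g(cf) = a + b * (u(cf) - c)^2 with u = cf in Hz (or its ERB-number).

    The Hz argument follows the quadratic's printed form; the ERB-number
    alternative compresses the axis so curvature acts more evenly across
    the bank's three decades.
    """

    a: float
    b: float = 0.0
    c: float = 0.0
    scale: str = "hz"

    def __post_init__(self):
        if self.scale not in ("erb", "hz"):
            raise ValueError("scale must be 'erb' or 'hz'")

    def values(self, cfs: np.ndarray) -> np.ndarray:
        u = erb_number(cfs) if self.scale == "erb" else np.asarray(cfs, float)
        g = self.a + self.b * (u - self.c) ** 2
        if np.any(g < GAIN_FLOOR):
            warnings.warn(
                "quadratic gain dips below the positivity floor; clipping",
                stacklevel=2,
            )
            g = np.maximum(g, GAIN_FLOOR)
        return g

    def to_dict(self) -> dict:
        return {"a": float(self.a), "b": float(self.b), "c": float(self.c),
                "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticGain":
        return cls(a=d["a"], b=d.get("b", 0.0), c=d.get("c", 0.0),
                   scale=d.get("scale", "hz"))


@dataclass(frozen=True)
class HyperacusisGainSpec:
    """One of the eight hyperacusis gain variants.

    ``gain`` is the scalar g_l / g_max for frequency-independent variants,
    or a :class:`QuadraticGain` for the frequency-dependent ones.  ``z`` is
    the power-law exponent, fixed at 1.1 for all hyperacusis simulations.
    """

    form: str  # 'linear' | 'power'
    scope: str  # 'sub' | 'supra'
    frequency: str  # 'independent' | 'quadratic'
    gain: float | QuadraticGain = 1.0
    z: float = 1.1

    def __post_init__(self):
        if self.form not in ("linear", "power"):
            raise ValueError("form must be 'linear' or 'power'")
        if self.scope not in ("sub", "supra"):
            raise ValueError("scope must be 'sub' or 'supra'")
        if self.frequency not in ("independent", "quadratic"):
            raise ValueError("frequency must be 'independent' or 'quadratic'")
        if self.frequency == "quadratic" and not isinstance(self.gain, QuadraticGain):
            raise ValueError("quadratic variant needs a QuadraticGain")
        if self.frequency == "independent" and isinstance(self.gain, QuadraticGain):
            raise ValueError("frequency-independent variant needs a scalar gain")

    @property
    def label(self) -> str:
        return f"{self.scope}/{self.form}/{self.frequency}"

    def gain_values(self, cfs: np.ndarray) -> np.ndarray:
        if isinstance(self.gain, QuadraticGain):
            return self.gain.values(cfs)
        return np.full(len(cfs), float(self.gain))

    def with_gain(self, gain) -> "HyperacusisGainSpec":
        return HyperacusisGainSpec(
            form=self.form, scope=self.scope, frequency=self.frequency,
            gain=gain, z=self.z,
        )

    def to_dict(self) -> dict:
        g = self.gain.to_dict() if isinstance(self.gain, QuadraticGain) else float(self.gain)
        return {"form": self.form, "scope": self.scope,
                "frequency": self.frequency, "gain": g, "z": float(self.z)}

    @classmethod
    def from_dict(cls, d: dict) -> "HyperacusisGainSpec":
        g = d["gain"]
        if isinstance(g, dict):
            g = QuadraticGain.from_dict(g)
        return cls(form=d["form"], scope=d["scope"], frequency=d["frequency"],
                   gain=g, z=d.get("z", 1.1))


#: The eight variant templates in a stable report order.
ALL_VARIANTS = tuple(
    HyperacusisGainSpec(
        form=form, scope=scope, frequency=freq,
        gain=QuadraticGain(a=1.0) if freq == "quadratic" else 1.0,
    )
    for scope in ("supra", "sub")
    for form in ("power", "linear")
    for freq in ("independent", "quadratic")
)


# ---------------------------------------------------------------------------
# Rate transforms
# ---------------------------------------------------------------------------

def _variant_gain(spec, rates, cfs, max_rates):
    g = spec.gain_values(cfs)[:, None]
    if spec.form == "power":
        if max_rates is None:
            raise ValueError("power-law gain needs per-class max rates")
        base = np.minimum(rates / np.asarray(max_rates, float), 1.0)
        return base**spec.z * g
    return np.broadcast_to(g, rates.shape)


def transform_rates(
    rates: np.ndarray,
    spont: np.ndarray,
    cfs: np.ndarray,
    ghc_values: np.ndarray,
    spec: HyperacusisGainSpec | None = None,
    max_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Gained per-fiber rates for raw ``rates`` of shape (..., n_ch, n_cls)."""
    w = np.asarray(ghc_values, float)[:, None]
    if np.any(w <= 0):
        raise ValueError("healthy-control gain must be positive everywhere")
    if spec is None:
        return rates * w
    g = _variant_gain(spec, rates, cfs, max_rates)
    if spec.scope == "sub":
        return g * w * rates
    if spont is None:
        raise ValueError("supra-threshold gain needs the spontaneous baseline")
    return (np.maximum(0.0, rates - spont) * g + spont) * w


def apply_healthy_gain(response, g_hc: QuadraticGain):
    """Multiply every fiber's rate (and baseline) by g_hc(cf)."""
    from .an_population import ANResponse

    w = g_hc.values(response.cfs)
    if np.any(w <= 0):
        raise ValueError("healthy-control gain must be positive everywhere")
    return ANResponse(
        rates=response.rates * w[:, None],
        spontaneous=response.spontaneous * w[:, None],
        cfs=response.cfs,
        class_names=response.class_names,
        stimulus=response.stimulus,
    )


def apply_hyperacusis_gain(
    response,
    spec: HyperacusisGainSpec,
    g_hc: QuadraticGain,
    max_rates: np.ndarray | None = None,
):
    """Apply one hyperacusis variant followed by the healthy gain.

    The healthy gain is the outer multiplicative factor in every variant;
    supra-threshold variants leave the spontaneous baseline untouched by
    the hyperacusis factor.
    """
    from .an_population import ANResponse

    if spec.scope == "supra" and response.spontaneous is None:
        raise ValueError("supra-threshold gain needs the spontaneous baseline")
    if max_rates is None and spec.form == "power":
        raise ValueError("power-law gain needs per-class max rates")
    w = g_hc.values(response.cfs)
    out = transform_rates(
        response.rates, response.spontaneous, response.cfs, w, spec, max_rates
    )
    return ANResponse(
        rates=out,
        spontaneous=response.spontaneous * w[:, None],
        cfs=response.cfs,
        class_names=response.class_names,
        stimulus=response.stimulus,
    )
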