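"""Auditory periphery: outer/middle-ear filter and DRNL cochlear filterbank.

The outer/middle-ear stage is a parallel bank of three Butterworth bandpass
branches that shapes the pressure waveform into a stapes-velocity proxy.
The basilar membrane is modelled per cochlear place by a dual resonance
non-linear (DRNL) filter: a linear pathway (gain, two first-order
gammatones, four second-order Butterworth low-passes) in parallel with a
compressive pathway (three gammatones, broken-stick non-linearity, three
gammatones, three low-passes).  Per-channel coefficients follow the
published human parameter-set regressions, generated on an ERB-spaced grid
of characteristic frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import signal

from .erb import erb_space
from .stimuli import Stimulus

__all__ = [
    "OuterMiddleEarConfig",
    "apply_outer_middle_ear",
    "broken_stick",
    "ChannelParams",
    "FilterbankConfig",
    "load_drnl_params",
    "save_drnl_params",
    "make_human_filterbank",
    "DRNLFilterbank",
    "apply_drnl",
]

# ---------------------------------------------------------------------------
# Outer / middle ear
# ---------------------------------------------------------------------------

#: (low cut Hz, high cut Hz, gain dB) of the three parallel branches.
DEFAULT_OME_BANDS = (
    (1900.0, 4200.0, -2.0),
    (4500.0, 6300.0, -3.0),
    (8000.0, 12000.0, -19.0),
)


@dataclass(frozen=True)
class OuterMiddleEarConfig:
    """Three parallel Butterworth bandpass branches.

    ``filter_order`` is the order passed to :func:`scipy.signal.butter` per
    branch.  Order 4 keeps cross-branch leakage low enough that the branch
    gains are recovered as measured band gains (see docs/methods.md).
    """

    bands: tuple = DEFAULT_OME_BANDS
    filter_order: int = 4

    def __post_init__(self):
        if len(self.bands) != 3:
            raise ValueError("outer/middle-ear filter has exactly 3 bands")
        for lo, hi, _gain in self.bands:
            if not lo < hi:
                raise ValueError("band low cut must be below high cut")

    def sos_and_gains(self, sample_rate: float):
        if sample_rate < 2 * max(hi for _lo, hi, _g in self.bands):
            raise ValueError(
                f"sample rate {sample_rate} Hz cannot represent the "
                f"{max(hi for _lo, hi, _g in self.bands):.0f} Hz upper cut-off"
            )
        out = []
        for lo, hi, gain_db in self.bands:
            sos = signal.butter(
                self.filter_order, [lo, hi], btype="bandpass", fs=sample_rate,
                output="sos",
            )
            out.append((sos, 10.0 ** (gain_db / 20.0)))
        return out


def apply_outer_middle_ear(
    stimulus: Stimulus | np.ndarray,
    config: OuterMiddleEarConfig | None = None,
    sample_rate: float | None = None,
) -> np.ndarray:
    """Sum of the gain-scaled bandpass branches (stapes-velocity proxy).

    The filter is linear and time-invariant; the output keeps the input's
    units (the pressure-to-velocity conversion happens in the filterbank).
    """
    config = config or OuterMiddleEarConfig()
    if isinstance(stimulus, Stimulus):
        x = stimulus.samples
        sample_rate = stimulus.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        x = np.asarray(stimulus, dtype=float)
    y = np.zeros_like(x)
    for sos, g in config.sos_and_gains(sample_rate):
        y += g * signal.sosfilt(sos, x)
    return y


# ---------------------------------------------------------------------------
# Broken-stick non-linearity
# ---------------------------------------------------------------------------

def broken_stick(i, a: float, b: float, c: float):
    """Compressive broken-stick: ``sign(i) * min(a|i|, b|i|**c)``.

    Linear with slope ``a`` for small inputs, compressive with log-log
    slope ``c`` above the knee.  Odd-symmetric and total on the reals.
    """
    if not (a > 0 and b > 0):
        raise ValueError("a and b must be positive")
    if not 0 < c < 1:
        raise ValueError("compression exponent c must be in (0, 1)")
    x = np.asarray(i, dtype=float)
    ax = np.abs(x)
    return np.sign(x) * np.minimum(a * ax, b * ax**c)


# ---------------------------------------------------------------------------
# DRNL channel parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelParams:
    """DRNL coefficients for one characteristic frequency."""

    cf: float
    a: float
    b: float
    c: float
    lin_gain: float
    cf_lin: float
    bw_lin: float
    lp_lin: float
    cf_nl: float
    bw_nl: float
    lp_nl: float
    n_gt_lin: int = 2
    n_lp_lin: int = 4
    n_gt_nl: int = 3
    n_lp_nl: int = 3
    lp_order: int = 2

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("broken-stick a, b must be positive")
        if not 0 < self.c < 1:
            raise ValueError("broken-stick c must be in (0, 1)")


@dataclass(frozen=True)
class FilterbankConfig:
    """Ordered DRNL channels on an ERB-spaced CF grid."""

    channels: tuple
    cf_min: float
    cf_max: float
    spacing: str = "erb"

    def __post_init__(self):
        cfs = self.cfs
        if len(cfs) == 0:
            raise ValueError("empty channel list")
        if np.any(np.diff(cfs) <= 0):
            raise ValueError("channel CFs must be strictly increasing")

    @property
    def cfs(self) -> np.ndarray:
        return np.array([ch.cf for ch in self.channels])

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def load_drnl_params(path=None) -> dict:
    """Read a DRNL regression parameter file (package default if no path)."""
    if path is None:
        ref = resources.files("angain.data").joinpath("drnl_human.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def save_drnl_params(params: dict, path) -> None:
    """Write a DRNL regression parameter file (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)


def _regress(params: dict, key: str, cf: float) -> float:
    reg = params["regressions"][key]
    if key == "lin_gain":
        slope = -params["g0"]
    else:
        slope = reg.get("m", 0.0)
    return 10.0 ** (reg["p0"] + slope * np.log10(cf))


def channel_from_regressions(cf: float, params: dict) -> ChannelParams:
    st = params["structure"]
    return ChannelParams(
        cf=cf,
        a=_regress(params, "a", cf),
        b=_regress(params, "b", cf),
        c=_regress(params, "c", cf),
        lin_gain=_regress(params, "lin_gain", cf),
        cf_lin=_regress(params, "cf_lin", cf),
        bw_lin=_regress(params, "bw_lin", cf),
        lp_lin=_regress(params, "lp_lin", cf),
        cf_nl=_regress(params, "cf_nl", cf),
        bw_nl=_regress(params, "bw_nl", cf),
        lp_nl=_regress(params, "lp_nl", cf),
        n_gt_lin=st["n_gt_lin"],
        n_lp_lin=st["n_lp_lin"],
        n_gt_nl=st["n_gt_nl"],
        n_lp_nl=st["n_lp_nl"],
        lp_order=st["lp_order"],
    )


def make_human_filterbank(
    n_channels: int = 500,
    cf_min: float = 40.0,
    cf_max: float = 13000.0,
    params: dict | None = None,
) -> FilterbankConfig:
    """Human DRNL filterbank with CFs evenly spaced on the ERB-number scale."""
    if params is None:
        params = load_drnl_params()
    lo, hi = params.get("valid_cf_range", [40.0, 13000.0])
    if cf_min < lo or cf_max > hi:
        warnings.warn(
            f"CF range [{cf_min}, {cf_max}] Hz outside the validity range "
            f"[{lo}, {hi}] Hz of the coefficient regressions",
            stacklevel=2,
        )
    cfs = erb_space(cf_min, cf_max, n_channels)
    channels = tuple(channel_from_regressions(cf, params) for cf in cfs)
    return FilterbankConfig(channels=channels, cf_min=cf_min, cf_max=cf_max)


# ---------------------------------------------------------------------------
# DRNL filterbank
# ---------------------------------------------------------------------------

def _gammatone_sos(fc: float, bw: float, fs: float, n_stages: int) -> np.ndarray:
    """Cascade of first-order gammatone stages as unit-peak-gain resonators.

    Each stage is the two-pole filter with poles at r*exp(+-i*theta),
    r = exp(-2*pi*bw/fs), normalised to unity gain at fc.
    """
    theta = 2.0 * np.pi * fc / fs
    r = np.exp(-2.0 * np.pi * bw / fs)
    a1, a2 = -2.0 * r * np.cos(theta), r * r
    z = np.exp(-1j * theta)
    k = abs(1.0 + a1 * z + a2 * z * z)
    row = [k, 0.0, 0.0, 1.0, a1, a2]
    return np.array([row] * n_stages)


def _lowpass_sos(cutoff: float, order: int, fs: float, n_stages: int) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return np.vstack([sos] * n_stages)


class DRNLFilterbank:
    """Applies the DRNL filterbank to an outer/middle-ear-filtered waveform.

    Parameters
    ----------
    config : FilterbankConfig
    sample_rate : float
    stapes_scale : float
        Conversion from the (dimensionless-gain) stapes-velocity proxy to
        stapes velocity in m/s per Pa of input pressure.
    bm_scale : float
        Constant converting the summed pathway output to basilar-membrane
        velocity (m/s).
    """

    def __init__(
        self,
        config: FilterbankConfig,
        sample_rate: float,
        stapes_scale: float = 1.0,
        bm_scale: float = 1.0,
    ):
        nyq = sample_rate / 2.0
        for ch in config.channels:
            top = max(ch.cf_lin, ch.cf_nl, ch.lp_lin, ch.lp_nl)
            if top >= 0.98 * nyq:
                raise ValueError(
                    f"sample rate {sample_rate} Hz too low for channel at "
                    f"CF {ch.cf:.0f} Hz (filter frequency {top:.0f} Hz)"
                )
        self.config = config
        self.sample_rate = float(sample_rate)
        self.stapes_scale = float(stapes_scale)
        self.bm_scale = float(bm_scale)
        fs = self.sample_rate
        self._stages = []
        for ch in config.channels:
            lin = np.vstack(
                [
                    _gammatone_sos(ch.cf_lin, ch.bw_lin, fs, ch.n_gt_lin),
                    _lowpass_sos(ch.lp_lin, ch.lp_order, fs, ch.n_lp_lin),
                ]
            )
            nl_pre = _gammatone_sos(ch.cf_nl, ch.bw_nl, fs, ch.n_gt_nl)
            nl_post = np.vstack(
                [
                    _gammatone_sos(ch.cf_nl, ch.bw_nl, fs, ch.n_gt_nl),
                    _lowpass_sos(ch.lp_nl, ch.lp_order, fs, ch.n_lp_nl),
                ]
            )
            self._stages.append((ch, lin, nl_pre, nl_post))

    @property
    def cfs(self) -> np.ndarray:
        return self.config.cfs

    def process_channel(
        self, index: int, stapes_proxy: np.ndarray, pathway: str = "both"
    ) -> np.ndarray:
        """BM velocity trace (m/s) for one channel.

        ``pathway`` selects 'both' (the summed DRNL output), 'linear' or
        'nonlinear' — the isolated pathways are useful for compression
        diagnostics, since near the pathway crossover the summed output
        shows interference plateaus.
        """
        ch, lin, nl_pre, nl_post = self._stages[index]
        x = np.asarray(stapes_proxy, dtype=float) * self.stapes_scale
        out = 0.0
        if pathway in ("both", "linear"):
            out = out + signal.sosfilt(lin, ch.lin_gain * x)
        if pathway in ("both", "nonlinear"):
            u = signal.sosfilt(nl_pre, x)
            out = out + signal.sosfilt(nl_post, broken_stick(u, ch.a, ch.b, ch.c))
        return self.bm_scale * out

    def iter_channels(self, stapes_proxy: np.ndarray):
        """Yield ``(index, bm_velocity_trace)`` channel by channel."""
        for i in range(self.config.n_channels):
            yield i, self.process_channel(i, stapes_proxy)

    def process(self, stapes_proxy: np.ndarray) -> np.ndarray:
        """All channels at once, shape ``(n_channels, n_samples)``."""
        return np.stack([tr for _i, tr in self.iter_channels(stapes_proxy)])


def apply_drnl(
    waveform: np.ndarray,
    bank: FilterbankConfig,
    sample_rate: float,
    stapes_scale: float = 1.0,
) -> np.ndarray:
    """Functional wrapper: per-channel BM velocity for a filtered waveform."""
    return DRNLFilterbank(bank, sample_rate, stapes_scale).process(waveform)
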