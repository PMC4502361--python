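"""Equivalent-rectangular-bandwidth (ERB) frequency scale.

The ERB-number (Cam) scale approximates cochlear place spacing for normal
human hearing: E(f) = 21.4 * log10(4.37 * f/1000 + 1).
"""

from __future__ import annotations

import numpy as np

__all__ = ["erb_number", "erb_number_to_hz", "erb_space"]

_SCALE = 21.4
_Q = 4.37


def erb_number(frequency_hz):
    """ERB-number (Cam) of a frequency in Hz."""
    f = np.asarray(frequency_hz, dtype=float)
    return _SCALE * np.log10(_Q * f / 1000.0 + 1.0)


def erb_number_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    e = np.asarray(erb, dtype=float)
    return 1000.0 / _Q * (10.0 ** (e / _SCALE) - 1.0)


def erb_space(f_min: float, f_max: float, n: int) -> np.ndarray:
    """``n`` frequencies from ``f_min`` to ``f_max``, evenly spaced in ERB-number.

    The endpoints are anchored exactly at ``f_min`` and ``f_max``.
    """
    if n < 2:
        raise ValueError("need at least 2 channels")
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    e = np.linspace(erb_number(f_min), erb_number(f_max), n)
    f = erb_number_to_hz(e)
    f[0] = f_min
    f[-1] = f_max
    return f
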