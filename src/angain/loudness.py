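"""Loudness in sones and equal-loudness contours from summed AN activity.

The core assumption: perceived loudness is proportional to the summed
activity of the whole AN population, and two tones evoking the same summed
activity are equally loud.  Loudness in sones is

    Ldn(f, L) = ((S(f, L) - Ssp) / (S(1 kHz, 40 dB) - Ssp)) ** x

with S the summed rate, Ssp the summed spontaneous rate, and x a fitted
exponent (1.61 for the default model).  Equal-loudness contours (ELCs) are
found, per reference 1-kHz level, by searching each test frequency for the
level whose (linearly interpolated) summed activity matches the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PHON_LEVELS",
    "DEFAULT_ELC_FREQUENCIES",
    "LoudnessCalibration",
    "loudness_sones",
    "calibrate_x",
    "ActivityCurve",
    "StepPolicy",
    "find_equal_loudness_level",
    "ELC",
    "compute_elc_set",
    "to_model_hl",
    "elcs_to_frame",
]

#: Reference 1-kHz levels (dB SPL): -10..130 in 10-dB steps plus -5, -2, 2.
DEFAULT_PHON_LEVELS = tuple(sorted(list(range(-10, 131, 10)) + [-5, -2, 2]))

#: Test frequencies (Hz) at which contours are evaluated.
DEFAULT_ELC_FREQUENCIES = (125.0, 250.0, 500.0, 1000.0, 2000.0, 3000.0,
                           4000.0, 6000.0, 8000.0)


# ---------------------------------------------------------------------------
# Sones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoudnessCalibration:
    """Normalisation of the sone formula for one model/gain configuration."""

    x: float
    reference_sum: float  # summed evoked rate for 1 kHz @ 40 dB SPL (sp/s)
    spontaneous_sum: float  # summed spontaneous rate (sp/s)

    def __post_init__(self):
        if self.reference_sum <= 0:
            raise ValueError("reference evoked sum must be positive")


def loudness_sones(response, cal: LoudnessCalibration) -> float:
    """Loudness of a response (ANResponse or summed rate in sp/s).

    A summed rate below the spontaneous baseline (possible by chance in
    spiking mode) clamps to 0 sones.
    """
    summed = response.summed() if hasattr(response, "summed") else float(response)
    num = max(0.0, summed - cal.spontaneous_sum)
    return (num / cal.reference_sum) ** cal.x


def sone_scale_law(level_db_spl) -> np.ndarray:
    """Sone value of a 1-kHz tone: 2 ** ((L - 40) / 10)."""
    return 2.0 ** ((np.asarray(level_db_spl, float) - 40.0) / 10.0)


def calibrate_x(
    summed_responses: dict,
    spontaneous_sum: float,
    sone_targets: dict | None = None,
    reference_level: float = 40.0,
) -> float:
    """Least-squares exponent matching normalised summed activity to sones.

    ``summed_responses`` maps 1-kHz tone level (dB SPL) to the summed AN
    rate.  Targets default to the 1-kHz sone-scale law 2**((L-40)/10).
    The exponent is the closed-form log-domain least-squares slope through
    the (log normalised activity, log sones) pairs, anchored at the 40-dB
    reference where both are 1 by construction.
    """
    levels = np.array(sorted(summed_responses))
    if levels.size < 5:
        raise ValueError("need at least 5 levels to calibrate the exponent")
    summed = np.array([summed_responses[lv] for lv in levels])
    if np.any(np.diff(summed) < 0):
        raise ValueError("summed responses must be monotone in level")
    if reference_level not in summed_responses:
        raise ValueError("the reference level must be among the responses")
    evoked = summed - spontaneous_sum
    ref = summed_responses[reference_level] - spontaneous_sum
    if ref <= 0:
        raise ValueError("reference response does not exceed baseline")
    if sone_targets is None:
        targets = sone_scale_law(levels)
    else:
        targets = np.array([sone_targets[lv] for lv in levels])
    u = evoked / ref
    keep = (u > 0) & (targets > 0) & (np.abs(np.log(u)) > 1e-12)
    lu, lt = np.log(u[keep]), np.log(targets[keep])
    return float(np.sum(lu * lt) / np.sum(lu * lu))


# ---------------------------------------------------------------------------
# Equal-loudness search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepPolicy:
    """Level-grid policy: coarse 10-dB steps, 2-dB steps near threshold.

    The default grid spans [-60, 160] dB SPL: wider than any physical
    stimulus, because the periphery's frequency response places some model
    thresholds far below 0 dB SPL and some high-phon contour crossings
    above 130 dB SPL, and the model-HL normalisation needs the mathematical
    crossing points.  Points outside the grid are flagged, mirroring
    clinical equipment ceilings.
    """

    lo: float = -60.0
    hi: float = 160.0
    coarse_step: float = 10.0
    fine_step: float = 2.0
    fine_halfwidth: float = 12.0

    def coarse_grid(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1e-9, self.coarse_step)

    def fine_grid(self, center: float) -> np.ndarray:
        lo = max(self.lo, center - self.fine_halfwidth)
        hi = min(self.hi, center + self.fine_halfwidth)
        return np.arange(lo, hi + 1e-9, self.fine_step)


@dataclass
class ActivityCurve:
    """Summed AN activity sampled on a level grid at one frequency."""

    frequency: float
    levels: np.ndarray
    summed: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.levels)
        self.levels = np.asarray(self.levels, float)[order]
        self.summed = np.asarray(self.summed, float)[order]

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.summed) >= 0))

    def at_level(self, level: float) -> float:
        return float(np.interp(level, self.levels, self.summed))

    def invert(self, target: float) -> tuple[float, str]:
        """Smallest level whose interpolated activity reaches ``target``.

        Returns ``(level, flag)`` with flag 'ok', 'below-range' (target not
        exceeded even at the bottom of the grid, i.e. at or below the
        spontaneous floor) or 'above-range' (unreachable within the grid,
        mirroring clinical equipment ceilings).
        """
        s, lv = self.summed, self.levels
        if target <= s[0]:
            return lv[0], "below-range"
        if target > s[-1]:
            return lv[-1], "above-range"
        idx = int(np.searchsorted(s, target, side="left"))
        s0, s1 = s[idx - 1], s[idx]
        if s1 == s0:
            return float(lv[idx]), "ok"
        frac = (target - s0) / (s1 - s0)
        return float(lv[idx - 1] + frac * (lv[idx] - lv[idx - 1])), "ok"


def find_equal_loudness_level(
    activity,
    reference_sum: float,
    step_policy: StepPolicy | None = None,
) -> tuple[float, str]:
    """Level (dB SPL) at which ``activity`` matches ``reference_sum``.

    ``activity`` is an :class:`ActivityCurve` or a callable level -> summed
    rate.  For a callable, the curve is sampled coarsely, then refined with
    fine steps around the bracketing interval, and the crossing is obtained
    by linear interpolation of activity vs level.
    """
    policy = step_policy or StepPolicy()
    if isinstance(activity, ActivityCurve):
        return activity.invert(reference_sum)
    levels = list(policy.coarse_grid())
    summed = [activity(lv) for lv in levels]
    curve = ActivityCurve(frequency=np.nan, levels=np.array(levels),
                          summed=np.array(summed))
    if not curve.is_monotone:
        raise ValueError("summed activity is not monotone in level")
    guess, flag = curve.invert(reference_sum)
    if flag != "ok":
        return guess, flag
    fine = [lv for lv in policy.fine_grid(guess) if lv not in levels]
    levels += fine
    summed += [activity(lv) for lv in fine]
    curve = ActivityCurve(frequency=np.nan, levels=np.array(levels),
                          summed=np.array(summed))
    return curve.invert(reference_sum)


# ---------------------------------------------------------------------------
# Contour sets
# ---------------------------------------------------------------------------

@dataclass
class ELC:
    """One equal-loudness contour: frequency -> dB SPL at one phon level."""

    phon_level: float
    points: dict  # frequency Hz -> level dB SPL
    flags: dict  # frequency Hz -> 'ok' | 'below-range' | 'above-range'
    reference_sum: float
    model_hl: dict | None = None  # filled by to_model_hl


def compute_elc_set(
    activity_curves: dict,
    reference_levels=DEFAULT_PHON_LEVELS,
    frequencies=DEFAULT_ELC_FREQUENCIES,
    reference_activities: dict | None = None,
) -> list[ELC]:
    """One ELC per reference level.

    ``activity_curves`` maps frequency -> ActivityCurve (must include the
    1-kHz reference curve).  By default the reference activity for P phon
    is the 1-kHz curve evaluated at P dB SPL, and the contour contains the
    reference point (1 kHz, P) exactly.  Passing ``reference_activities``
    (phon level -> summed rate, e.g. from the healthy model when probing a
    hyperacusis variant) makes 1 kHz a searched frequency like any other.
    """
    if 1000.0 not in activity_curves and reference_activities is None:
        raise ValueError("the 1-kHz activity curve is required")
    elcs = []
    for phon in reference_levels:
        if reference_activities is not None:
            ref = reference_activities[phon]
        else:
            ref = activity_curves[1000.0].at_level(phon)
        points, flags = {}, {}
        for f in frequencies:
            if reference_activities is None and f == 1000.0:
                points[f], flags[f] = float(phon), "ok"
                continue
            lvl, flag = activity_curves[f].invert(ref)
            points[f], flags[f] = lvl, flag
        elcs.append(ELC(phon_level=float(phon), points=points, flags=flags,
                        reference_sum=float(ref)))
    return elcs


def to_model_hl(elcs: list[ELC]) -> list[ELC]:
    """Express contours in model dB HL by subtracting the 2-phon contour.

    The 2-phon contour roughly corresponds to the hearing threshold; after
    subtraction it maps to 0 dB model HL at every frequency and contour
    ordering is preserved.
    """
    base = [e for e in elcs if e.phon_level == 2]
    if not base:
        raise ValueError("the 2-phon contour is required for model HL")
    zero = base[0].points
    out = []
    for e in elcs:
        hl = {f: e.points[f] - zero[f] for f in e.points}
        out.append(replace(e, model_hl=hl))
    return out


def elcs_to_frame(elcs: list[ELC]) -> pd.DataFrame:
    """Long-format table: phon_level, frequency_hz, level_db_spl, ... flags."""
    rows = []
    for e in elcs:
        for f in sorted(e.points):
            rows.append(
                {
                    "phon_level": e.phon_level,
                    "frequency_hz": f,
                    "level_db_spl": e.points[f],
                    "level_db_model_hl": (
                        np.nan if e.model_hl is None else e.model_hl[f]
                    ),
                    "flag": e.flags[f],
                }
            )
    return pd.DataFrame(rows)
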