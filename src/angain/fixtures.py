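"""Synthetic audiometric tables emulating the clinical data pattern.

The modelled cohorts are normal-hearing: control hearing thresholds near
0 dB HL with loudness discomfort levels (LDLs) around 100 dB HL, and
hyperacusis-patient LDLs uniformly shifted about 20 dB below the control
LDLs across the audiometric range.  Group-mean tables are exact by
construction; optional per-subject jitter is re-centred so the sample mean
still equals the target mean at every frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    AudiometricTable,
    CLINICAL_FREQUENCIES,
    DEFAULT_CEILINGS,
)

__all__ = ["FixtureSpec", "make_control_table", "make_patient_table"]

#: Frequencies (Hz) where control LDLs are available.
CONTROL_LDL_FREQUENCIES = (500.0, 1000.0, 2000.0, 4000.0)
#: Frequencies (Hz) where control thresholds are available.
CONTROL_HT_FREQUENCIES = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)


def _flat(freqs, value) -> dict:
    return {float(f): float(value) for f in freqs}


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic cohort tables.

    ``control_ldl_shape`` gives the group-mean control LDL (dB HL) per
    clinical frequency; patient LDLs are that shape plus ``patient_shift``
    (default -20 dB).  ``jitter_sd`` adds per-subject scatter when subject
    tables are drawn; group means are unaffected.
    """

    control_ldl_shape: dict = field(
        default_factory=lambda: _flat(CLINICAL_FREQUENCIES, 100.0)
    )
    control_ht_shape: dict = field(
        default_factory=lambda: _flat(CLINICAL_FREQUENCIES, 0.0)
    )
    patient_shift: float = -20.0
    jitter_sd: float = 0.0
    n_subjects: int = 13
    seed: int = 0

    def __post_init__(self):
        for f in self.control_ldl_shape:
            if float(f) not in CLINICAL_FREQUENCIES:
                raise ValueError(f"{f} Hz not in the clinical frequency set")


def _subject_jitter(spec: FixtureSpec, rng, n_freqs: int) -> np.ndarray:
    """(n_subjects, n_freqs) zero-mean jitter: sample mean is exactly 0."""
    j = rng.normal(0.0, spec.jitter_sd, size=(spec.n_subjects, n_freqs))
    return j - j.mean(axis=0, keepdims=True)


def make_control_table(spec: FixtureSpec | None = None) -> AudiometricTable:
    """Group-mean control table: normal thresholds, LDLs at 0.5-4 kHz."""
    spec = spec or FixtureSpec()
    rows = []
    for f in CONTROL_HT_FREQUENCIES:
        ht = min(spec.control_ht_shape[f], 20.0)
        ldl = spec.control_ldl_shape[f] if f in CONTROL_LDL_FREQUENCIES else np.nan
        rows.append(
            {
                "frequency_hz": f,
                "ht_db_hl": ht,
                "ldl_db_hl": ldl,
                "ceiling_db_hl": DEFAULT_CEILINGS[f],
            }
        )
    return AudiometricTable(cohort="control", data=pd.DataFrame(rows))


def make_patient_table(
    spec: FixtureSpec | None = None,
    control: AudiometricTable | None = None,
) -> AudiometricTable:
    """Group-mean patient table: control LDL shape shifted by patient_shift.

    Thresholds stay normal; raises if the shift would push any LDL at or
    below the threshold.
    """
    spec = spec or FixtureSpec()
    if control is None:
        control = make_control_table(spec)
    rows = []
    for f in CLINICAL_FREQUENCIES:
        ht = min(spec.control_ht_shape[f], 20.0)
        ldl = spec.control_ldl_shape[f] + spec.patient_shift
        if ldl <= ht:
            raise ValueError(
                f"patient LDL {ldl} dB HL at {f} Hz does not exceed the "
                f"threshold {ht} dB HL"
            )
        rows.append(
            {
                "frequency_hz": f,
                "ht_db_hl": ht,
                "ldl_db_hl": ldl,
                "ceiling_db_hl": DEFAULT_CEILINGS[f],
            }
        )
    return AudiometricTable(cohort="patient", data=pd.DataFrame(rows))


def subject_tables(spec: FixtureSpec, cohort: str = "control") -> list[AudiometricTable]:
    """Per-subject jittered tables whose mean equals the group-mean table."""
    mean = make_control_table(spec) if cohort == "control" else make_patient_table(spec)
    rng = np.random.default_rng(spec.seed)
    freqs = mean.data["frequency_hz"].to_numpy()
    jit = _subject_jitter(spec, rng, len(freqs))
    out = []
    for i in range(spec.n_subjects):
        d = mean.data.copy()
        d["ldl_db_hl"] = d["ldl_db_hl"] + jit[i]
        out.append(AudiometricTable(cohort=f"{cohort}-{i}", data=d))
    return out
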