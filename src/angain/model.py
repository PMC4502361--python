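"""End-to-end auditory model: stimulus -> periphery -> AN population.

:class:`AuditoryModel` wires the calibrated pieces together and caches
per-stimulus AN responses; :class:`ResponseSurface` tabulates raw per-fiber
rates on (frequency, level) grids so that gain variants and contour
searches can be evaluated cheaply on top of one set of periphery runs.

Presets
-------
``full``  500 channels, 10-s stimuli, spiking fibers (reproduction scale).
``desk``  64 channels, 1-s stimuli, deterministic rate mode (test scale).
``micro`` 24 channels, 0.25-s stimuli at 32 kHz (smoke-test scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import an_population as anp
from .an_population import (
    DEFAULT_THRESHOLDS,
    SR_TARGETS,
    ANResponse,
    FiberClassParams,
    calibrate_fiber_classes,
    siegert_rate,
)
from .gain_stage import HyperacusisGainSpec, transform_rates
from .loudness import (
    DEFAULT_ELC_FREQUENCIES,
    DEFAULT_PHON_LEVELS,
    ActivityCurve,
    LoudnessCalibration,
    StepPolicy,
    calibrate_x,
)
from .periphery import DRNLFilterbank, OuterMiddleEarConfig, apply_outer_middle_ear, make_human_filterbank
from .stimuli import Stimulus, synthesize_tone

__all__ = ["ModelConfig", "PRESETS", "AuditoryModel", "ResponseSurface"]

#: Levels (dB SPL) of 1-kHz tones used to fit the sone exponent.
X_FIT_LEVELS = tuple(range(30, 91, 10))


@dataclass(frozen=True)
class ModelConfig:
    """Scale and physiology constants of one model instance."""

    name: str = "full"
    n_channels: int = 500
    cf_min: float = 40.0
    cf_max: float = 13000.0
    sample_rate: float = 44100.0
    duration: float = 10.0
    mode: str = "spiking"  # 'spiking' | 'rate'
    ome_order: int = 4
    #: Pa -> m/s conversion applied to the stapes-velocity proxy.
    stapes_scale: float = 1.5e-2
    #: drive current per (m/s of rectified BM velocity); None -> calibrate.
    current_scale: float | None = None
    #: anchor for the current-scale calibration: the low-threshold class's
    #: rate for a 1-kHz tone at `anchor_level_db` sits `anchor_rate_rise`
    #: sp/s above its spontaneous rate (places the model HT near 0 dB SPL).
    anchor_level_db: float = -2.5
    anchor_rate_rise: float = 10.0
    #: CF-dependence of the transduction sensitivity: the per-channel drive
    #: scale is current_scale * (cf / 1 kHz) ** (-exponent), with separate
    #: exponents above and below 1 kHz, compensating the cochlear stages'
    #: CF-dependent gain so that model thresholds and dynamic ranges follow
    #: a realistic audibility profile across frequency.
    drive_cf_exponent: float = 2.0
    drive_cf_exponent_low: float | None = None
    thresholds: tuple = DEFAULT_THRESHOLDS
    sr_targets: tuple = SR_TARGETS
    tau: float = 0.01
    t_ref: float = 0.001

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


PRESETS = {
    "full": ModelConfig(name="full"),
    "desk": ModelConfig(name="desk", n_channels=64, duration=1.0, mode="rate"),
    "micro": ModelConfig(
        name="micro", n_channels=24, duration=0.25, sample_rate=32000.0,
        mode="rate",
    ),
}


def preset(name: str, **overrides) -> ModelConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name].with_overrides(**overrides)


class AuditoryModel:
    """Calibrated periphery + AN population with response caching.

    Usage::

        model = AuditoryModel(preset("desk"))
        model.calibrate(seed=1)
        resp = model.response(1000.0, 40.0)   # ANResponse
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.ome = OuterMiddleEarConfig(filter_order=config.ome_order)
        self.bank_config = make_human_filterbank(
            config.n_channels, config.cf_min, config.cf_max
        )
        self.filterbank = DRNLFilterbank(
            self.bank_config, config.sample_rate, stapes_scale=config.stapes_scale
        )
        self.classes_: tuple[FiberClassParams, ...] | None = None
        self.current_scale_: float | None = None
        self.spont_rates_: np.ndarray | None = None
        self.loudness_: LoudnessCalibration | None = None
        self.seed: int | None = None
        self._cache: dict = {}

    # -- plumbing -----------------------------------------------------------

    @property
    def cfs(self) -> np.ndarray:
        return self.bank_config.cfs

    @property
    def max_rates(self) -> np.ndarray:
        """Per-class saturation rates (refractory ceiling)."""
        return np.array([p.max_rate for p in self.classes_])

    def seed_for(self, frequency: float, level: float) -> int:
        """Deterministic per-stimulus seed schedule (spiking mode)."""
        ss = np.random.SeedSequence(
            [int(self.seed or 0), int(round(frequency)), int(round(level * 10)) & 0xFFFF]
        )
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def stimulus(self, frequency: float, level: float) -> Stimulus:
        return synthesize_tone(
            frequency, level, self.config.duration, self.config.sample_rate
        )

    def _cf_weights(self) -> np.ndarray:
        cfg = self.config
        p_hi = cfg.drive_cf_exponent
        p_lo = p_hi if cfg.drive_cf_exponent_low is None else cfg.drive_cf_exponent_low
        rel = self.cfs / 1000.0
        return np.where(rel >= 1.0, rel ** (-p_hi), rel ** (-p_lo))

    @property
    def channel_scales(self) -> np.ndarray:
        """Per-channel drive scale (transduction sensitivity profile)."""
        return self.current_scale_ * self._cf_weights()

    def drive_means(self, stimulus: Stimulus) -> np.ndarray:
        """Per-channel mean rectified drive current for a stimulus."""
        proxy = apply_outer_middle_ear(stimulus, self.ome)
        scales = self.channel_scales
        return np.array(
            [
                float(np.mean(np.maximum(0.0, tr))) * scales[i]
                for i, tr in self.filterbank.iter_channels(proxy)
            ]
        )

    # -- calibration --------------------------------------------------------

    def calibrate(self, seed: int = 0) -> "AuditoryModel":
        """Fiber classes, current scale, baseline rates, sone exponent."""
        cfg = self.config
        self.seed = seed
        self.classes_ = calibrate_fiber_classes(
            targets=cfg.sr_targets, thresholds=cfg.thresholds,
            tau=cfg.tau, t_ref=cfg.t_ref,
        )
        if cfg.current_scale is not None:
            self.current_scale_ = float(cfg.current_scale)
        else:
            self.current_scale_ = self._calibrate_current_scale()
        # stored mean baseline used for supra-threshold gating and sones
        self.spont_rates_ = anp.measure_spontaneous(
            self.classes_, self.cfs, mode="rate"
        )
        self._cache.clear()
        self._calibrate_loudness()
        return self

    def _calibrate_current_scale(self) -> float:
        cfg = self.config
        stim = self.stimulus(1000.0, cfg.anchor_level_db)
        proxy = apply_outer_middle_ear(stim, self.ome)
        w = self._cf_weights()
        best = max(
            float(np.mean(np.maximum(0.0, tr))) * w[i]
            for i, tr in self.filterbank.iter_channels(proxy)
        )
        low = self.classes_[0]
        target = low.target_sr + cfg.anchor_rate_rise

        def f(logk):
            return siegert_rate(10.0**logk * best, low) - target

        lo, hi = -6.0, 12.0
        if not (f(lo) < 0 < f(hi)):
            raise RuntimeError("current-scale calibration failed to bracket")
        return float(10.0 ** brentq(f, lo, hi, xtol=1e-10))

    def _calibrate_loudness(self) -> None:
        summed = {
            float(lv): self.response(1000.0, float(lv)).summed()
            for lv in X_FIT_LEVELS
        }
        spont_sum = float(self.spont_rates_.sum())
        x = calibrate_x(summed, spont_sum)
        ref = summed[40.0] - spont_sum
        self.loudness_ = LoudnessCalibration(
            x=x, reference_sum=ref, spontaneous_sum=spont_sum
        )

    # -- responses ----------------------------------------------------------

    def _require_calibrated(self):
        if self.classes_ is None:
            raise RuntimeError("call calibrate() first")

    def response(self, frequency: float, level: float) -> ANResponse:
        """Cached AN population response to a pure tone."""
        self._require_calibrated()
        key = (round(float(frequency), 6), round(float(level), 4))
        if key not in self._cache:
            stim = self.stimulus(frequency, level)
            proxy = apply_outer_middle_ear(stim, self.ome)
            resp = anp.an_respond(
                self.filterbank.iter_channels(proxy),
                self.classes_,
                self.cfs,
                current_scale=self.channel_scales,
                sample_rate=self.config.sample_rate,
                seed=self.seed_for(frequency, level),
                mode=self.config.mode,
                duration=self.config.duration,
            )
            resp.stimulus = (frequency, level)
            # spiking estimates replace the stored expected baseline
            resp.spontaneous = self.spont_rates_.copy()
            self._cache[key] = resp
        return self._cache[key]

    def spiking_response(
        self,
        frequency: float,
        level: float,
        duration: float | None = None,
        seed: int | None = None,
    ) -> ANResponse:
        """Spiking-mode population response regardless of the preset mode.

        ``duration`` may exceed the stimulus length; the periodic drive is
        tiled.  Uncached (each call simulates afresh).
        """
        self._require_calibrated()
        stim = self.stimulus(frequency, level)
        proxy = apply_outer_middle_ear(stim, self.ome)
        resp = anp.an_respond(
            self.filterbank.iter_channels(proxy),
            self.classes_,
            self.cfs,
            current_scale=self.channel_scales,
            sample_rate=self.config.sample_rate,
            seed=self.seed_for(frequency, level) if seed is None else seed,
            mode="spiking",
            duration=duration or self.config.duration,
        )
        resp.stimulus = (frequency, level)
        return resp

    def summed_activity(
        self,
        frequency: float,
        level: float,
        ghc_values: np.ndarray | None = None,
        spec: HyperacusisGainSpec | None = None,
    ) -> float:
        """Summed (optionally gained) population rate for a tone."""
        resp = self.response(frequency, level)
        if ghc_values is None and spec is None:
            return resp.summed()
        w = np.ones(len(self.cfs)) if ghc_values is None else ghc_values
        out = transform_rates(
            resp.rates, resp.spontaneous, self.cfs, w, spec, self.max_rates
        )
        return float(out.sum())

    def spontaneous_summed(
        self,
        ghc_values: np.ndarray | None = None,
        spec: HyperacusisGainSpec | None = None,
    ) -> float:
        """No-stimulus summed activity under a gain configuration."""
        self._require_calibrated()
        sp = self.spont_rates_
        w = np.ones(len(self.cfs)) if ghc_values is None else ghc_values
        out = transform_rates(sp, sp, self.cfs, w, spec, self.max_rates)
        return float(out.sum())


    # -- artifacts ----------------------------------------------------------

    def to_artifacts(self) -> dict:
        """Serializable calibration state (YAML-safe plain types)."""
        self._require_calibrated()
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
        return {
            "config": cfg,
            "seed": int(self.seed),
            "current_scale": float(self.current_scale_),
            "classes": [
                {
                    "name": p.name,
                    "target_sr": float(p.target_sr),
                    "activation_threshold": float(p.activation_threshold),
                    "noise_sigma": float(p.noise_sigma),
                    "tau": float(p.tau),
                    "t_ref": float(p.t_ref),
                    "v_reset": float(p.v_reset),
                }
                for p in self.classes_
            ],
            "loudness": {
                "x": float(self.loudness_.x),
                "reference_sum": float(self.loudness_.reference_sum),
                "spontaneous_sum": float(self.loudness_.spontaneous_sum),
            },
        }

    @classmethod
    def from_artifacts(cls, artifacts: dict) -> "AuditoryModel":
        """Rebuild a calibrated model from :meth:`to_artifacts` output."""
        cfg = dict(artifacts["config"])
        for k in ("thresholds", "sr_targets"):
            cfg[k] = tuple(cfg[k])
        model = cls(ModelConfig(**cfg))
        model.seed = int(artifacts["seed"])
        model.current_scale_ = float(artifacts["current_scale"])
        model.classes_ = tuple(
            FiberClassParams(**c) for c in artifacts["classes"]
        )
        model.spont_rates_ = anp.measure_spontaneous(
            model.classes_, model.cfs, mode="rate"
        )
        ld = artifacts["loudness"]
        model.loudness_ = LoudnessCalibration(
            x=ld["x"], reference_sum=ld["reference_sum"],
            spontaneous_sum=ld["spontaneous_sum"],
        )
        return model


class ResponseSurface:
    """Raw per-fiber rates tabulated on per-frequency level grids.

    The level grid follows the contour-search step policy: coarse 10-dB
    steps from -20 to 130 dB SPL, refined to 2-dB steps around the model
    hearing threshold (where the raw summed activity crosses the 1-kHz
    2-dB-SPL reference).  All gain variants reuse the same raw grids.
    """

    def __init__(
        self,
        model: AuditoryModel,
        frequencies=DEFAULT_ELC_FREQUENCIES,
        policy: StepPolicy | None = None,
    ):
        model._require_calibrated()
        self.model = model
        self.frequencies = tuple(float(f) for f in frequencies)
        if 1000.0 not in self.frequencies:
            self.frequencies = self.frequencies + (1000.0,)
        self.policy = policy or StepPolicy()
        self._levels: dict[float, np.ndarray] = {}
        self._rates: dict[float, np.ndarray] = {}

    def build(self, phon_levels=DEFAULT_PHON_LEVELS) -> "ResponseSurface":
        # 1-kHz grid: phon levels plus the coarse/fine search grid
        ref_levels = sorted(
            set(float(p) for p in phon_levels)
            | set(float(v) for v in self.policy.coarse_grid())
            | set(float(v) for v in X_FIT_LEVELS)
        )
        self._ensure(1000.0, ref_levels)
        ht_ref = self._raw_curve(1000.0).at_level(2.0)
        for f in self.frequencies:
            self._ensure(f, self.policy.coarse_grid())
            guess, flag = self._raw_curve(f).invert(ht_ref)
            if flag == "ok":
                self._ensure(f, self.policy.fine_grid(guess))
        return self

    def _ensure(self, f: float, levels) -> None:
        have = set(np.round(self._levels.get(f, np.array([])), 4))
        new = [lv for lv in np.asarray(levels, float) if round(lv, 4) not in have]
        if not new:
            return
        rates = [self.model.response(f, lv).rates for lv in new]
        lv_all = np.concatenate([self._levels.get(f, np.array([])), np.array(new)])
        r_all = (
            np.concatenate([self._rates[f], np.stack(rates)])
            if f in self._rates
            else np.stack(rates)
        )
        order = np.argsort(lv_all)
        self._levels[f] = lv_all[order]
        self._rates[f] = r_all[order]

    def levels(self, f: float) -> np.ndarray:
        return self._levels[float(f)]

    def rates_tensor(self, f: float) -> np.ndarray:
        """Shape (n_levels, n_channels, n_classes) of raw rates."""
        return self._rates[float(f)]

    def _raw_curve(self, f: float) -> ActivityCurve:
        return ActivityCurve(
            frequency=f,
            levels=self._levels[f],
            summed=self._rates[f].sum(axis=(1, 2)),
        )

    def activity_curves(
        self,
        ghc_values: np.ndarray | None = None,
        spec: HyperacusisGainSpec | None = None,
    ) -> dict:
        """Gained activity-vs-level curves for every surface frequency."""
        model = self.model
        w = np.ones(len(model.cfs)) if ghc_values is None else ghc_values
        sp = model.spont_rates_
        curves = {}
        for f in self.frequencies:
            out = transform_rates(
                self._rates[f], sp, model.cfs, w, spec, model.max_rates
            )
            curves[f] = ActivityCurve(
                frequency=f, levels=self._levels[f], summed=out.sum(axis=(1, 2))
            )
        return curves
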