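"""Run configuration and end-to-end orchestration.

A single YAML config drives every stage — phantom generation, protocol
timing, capture, detector calibration and the pulse ROI — so the simulation
ground truth and the extraction settings cannot drift apart.  Omitted keys
fall back to documented defaults that reproduce the device's stated
constants: 20 ADU detection threshold, t_on 10 ms, t_delay 3 ms, 5 ms
exposure, 130 frames/s, a 260-pixel longitudinal slice and the
730/875/940 nm wavelength rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .acquisition import (
    Cycle,
    EventTimeline,
    FrameSequence,
    Geometry,
    PatternSequence,
    SceneRenderer,
    TimingConfig,
    build_timeline,
    capture,
)
from .extraction import DetectorLayout, extract
from .phantom import (
    DEFAULT_ABSORPTION,
    DiodeBank,
    FingerPhantom,
    PhantomConfig,
    PulseParams,
    default_diode_bank,
    generate_phantom,
)
from .pulse import Roi, estimate_pulse_rate, normalize_combine, roi_mean_series

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "load_config",
    "default_roi",
    "SimulationOutput",
    "simulate",
    "ground_truth_codes",
    "cycle_for_frame",
    "run_end_to_end",
]


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending key."""


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""


def default_roi(geometry: Geometry) -> Roi:
    """Default intensity-measurement patch: a central rectangle well inside
    the finger, where the vein network is densest."""
    rows, fcs = geometry.rows, geometry.finger_col_stop
    return Roi(
        row0=int(round(0.38 * rows)),
        col0=int(round(0.35 * fcs)),
        height=max(2, int(round(0.24 * rows))),
        width=max(2, int(round(0.25 * fcs))),
    )


@dataclass
class RunConfig:
    """Cross-validated bundle of all stage parameters."""

    seed: int = 1
    frames: int = 1000
    noise_sigma: float = 0.0  # ADU read noise, 0 = ideal sensor
    geometry: Geometry = field(default_factory=Geometry)
    timing: TimingConfig = field(default_factory=TimingConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    threshold: int = 20
    sites: Optional[Tuple[Tuple[int, int], ...]] = None  # None -> default layout
    roi: Optional[Roi] = None  # None -> default_roi(geometry)
    repeat_count: Optional[int] = None  # None -> enough sweeps to cover frames

    def __post_init__(self) -> None:
        if self.frames <= 0:
            raise ConfigError("frames: must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma: must be >= 0")
        if self.timing.rows != self.geometry.rows:
            raise ConfigError(
                f"timing.rows ({self.timing.rows}) must equal geometry.rows "
                f"({self.geometry.rows})"
            )
        layout = self.detector_layout()  # validates threshold and site count
        layout.check_bounds(self.geometry.shape)
        self.effective_roi().check_bounds(self.geometry.shape)

    def detector_layout(self) -> DetectorLayout:
        if self.sites is not None:
            return DetectorLayout(sites=tuple(tuple(s) for s in self.sites),
                                  threshold=self.threshold)
        return DetectorLayout.default(self.geometry, threshold=self.threshold)

    def effective_roi(self) -> Roi:
        return self.roi if self.roi is not None else default_roi(self.geometry)

    def pattern_sequence(self) -> PatternSequence:
        if self.repeat_count is not None:
            return PatternSequence.default(self.repeat_count)
        span = self.frames / self.timing.frame_rate + self.timing.frame_period + self.timing.exposure
        sweeps = max(1, math.ceil(span / (13 * self.timing.cycle)))
        return PatternSequence.default(sweeps)


def _merge(defaults: dict, override: dict, prefix: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ConfigError(f"{prefix}{key}: unknown configuration key")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, prefix=f"{prefix}{key}.")
        else:
            out[key] = value
    return out


_SCHEMA: dict = {
    "seed": 1,
    "frames": 1000,
    "noise_sigma": 0.0,
    "repeat_count": None,
    "geometry": {"rows": 260, "cols": 400, "finger_col_stop": 320},
    "timing": {
        "t_u": 0.017,
        "t_delay": 0.003,
        "t_on": 0.010,
        "exposure": 0.005,
        "frame_rate": 130.0,
        "seg_lag": 0.0015,
    },
    "phantom": {
        "vein_density": 1.0,
        "vein_width_px": [2.0, 8.0],
        "vein_depth_scale": 0.8,
        "tissue_depth_max": 2.0,
        "nail_factor": 0.35,
        "texture_contrast": 0.35,
        "pulse": {"rate_bpm": 90.0, "amplitude": 0.03, "phase": 0.0},
        "absorption": None,  # wavelength -> [mu_tissue, mu_blood]
    },
    "detector": {"threshold": 20, "sites": None},
    "roi": None,  # {row0, col0, height, width}
}


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or missing) file yields all documented defaults.  Unknown keys
    and out-of-range values raise :class:`ConfigError` naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}
    cfg = _merge(_SCHEMA, data)

    if not 0 < cfg["detector"]["threshold"] < 255:
        raise ConfigError(
            f"detector.threshold: {cfg['detector']['threshold']} must lie strictly "
            "between 0 and the 255 ADU saturation level"
        )

    geometry = _build("geometry", Geometry, cfg["geometry"])
    timing = _build("timing", TimingConfig,
                    {**cfg["timing"], "rows": geometry.rows})

    ph = cfg["phantom"]
    pulse = _build("phantom.pulse", PulseParams, ph["pulse"])
    absorption = dict(DEFAULT_ABSORPTION)
    if ph["absorption"] is not None:
        try:
            absorption = {float(k): (float(v[0]), float(v[1]))
                          for k, v in ph["absorption"].items()}
        except (TypeError, ValueError, IndexError) as exc:
            raise ConfigError(f"phantom.absorption: {exc}") from exc
    phantom = _build(
        "phantom",
        PhantomConfig,
        {
            "vein_density": ph["vein_density"],
            "vein_width_px": tuple(ph["vein_width_px"]),
            "vein_depth_scale": ph["vein_depth_scale"],
            "tissue_depth_max": ph["tissue_depth_max"],
            "nail_factor": ph["nail_factor"],
            "texture_contrast": ph["texture_contrast"],
            "pulse": pulse,
            "absorption": absorption,
        },
    )

    sites = cfg["detector"]["sites"]
    if sites is not None:
        sites = tuple((int(r), int(c)) for r, c in sites)
    roi = None
    if cfg["roi"] is not None:
        roi = _build("roi", Roi, cfg["roi"])

    try:
        return RunConfig(
            seed=int(cfg["seed"]),
            frames=int(cfg["frames"]),
            noise_sigma=float(cfg["noise_sigma"]),
            geometry=geometry,
            timing=timing,
            phantom=phantom,
            threshold=int(cfg["detector"]["threshold"]),
            sites=sites,
            roi=roi,
            repeat_count=None if cfg["repeat_count"] is None else int(cfg["repeat_count"]),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _build(key: str, cls, kwargs: dict):
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: {exc}") from exc


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    video: FrameSequence
    timeline: EventTimeline
    phantom: FingerPhantom
    bank: DiodeBank
    layout: DetectorLayout
    ground_truth: List[str]  # per-frame dominant indicator code ('dark' if none)
    config: RunConfig


def cycle_for_frame(timeline: EventTimeline, timing: TimingConfig,
                    t0: float) -> Optional[Cycle]:
    """Cycle whose indicator window overlaps this frame's total exposure span
    the most (None when the frame saw no indicator light at all)."""
    span_end = t0 + (timing.rows - 1) * timing.row_readout + timing.exposure
    best, best_ov = None, 0.0
    for cyc in timeline.cycles:
        ov = min(span_end, cyc.t_seg_off) - max(t0, cyc.t_seg_on)
        if ov > best_ov:
            best, best_ov = cyc, ov
    return best


def ground_truth_codes(timeline: EventTimeline, timing: TimingConfig,
                       n_frames: int) -> List[str]:
    codes = []
    for k in range(n_frames):
        cyc = cycle_for_frame(timeline, timing, k * timing.frame_period)
        codes.append(cyc.pattern.indicator_code if cyc is not None else "dark")
    return codes


def simulate(config: RunConfig) -> SimulationOutput:
    """Generate the phantom, run the protocol and capture the free-run video."""
    phantom = generate_phantom(config.seed, shape=config.geometry.shape,
                               config=config.phantom)
    bank = default_diode_bank(config.geometry.shape, config.geometry.finger_col_stop)
    timeline = build_timeline(config.timing, config.pattern_sequence())
    renderer = SceneRenderer(phantom, bank, timeline, config.geometry)
    rng = np.random.default_rng(config.seed % (2**31)) if config.noise_sigma > 0 else None
    video = capture(
        renderer,
        timeline,
        config.timing,
        config.frames,
        noise_sigma=config.noise_sigma,
        rng=rng,
        geometry=config.geometry,
    )
    truth = ground_truth_codes(timeline, config.timing, config.frames)
    return SimulationOutput(video=video, timeline=timeline, phantom=phantom,
                            bank=bank, layout=config.detector_layout(),
                            ground_truth=truth, config=config)


def run_end_to_end(config: RunConfig, processed_dir=None) -> dict:
    """simulate → extract → pulse; returns a deterministic report.

    Any stage failure is re-raised as :class:`StageError` tagged with the
    stage name.  When ``processed_dir`` is given the extracted images are
    also written there in the release layout.
    """
    try:
        sim = simulate(config)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    duration = config.frames / config.timing.frame_rate
    try:
        result = extract(sim.video, sim.layout)
        if processed_dir is not None:
            from .extraction import write_processed

            write_processed(result, processed_dir)
    except Exception as exc:
        raise StageError(f"extract: {exc}") from exc

    code_counts: Dict[str, int] = {}
    for code in result.codes:
        code_counts[code] = code_counts.get(code, 0) + 1

    try:
        signal = normalize_combine(roi_mean_series(result, config.effective_roi()))
        estimate = estimate_pulse_rate(signal)
    except Exception as exc:
        raise StageError(f"pulse: {exc}") from exc

    return {
        "seed": config.seed,
        "frames_captured": config.frames,
        "duration_s": duration,
        "frames_extracted": len(result),
        "yield_per_s": len(result) / duration,
        "code_counts": code_counts,
        "distinct_codes": len(code_counts),
        "pulse": {
            "frequency_hz": estimate.frequency_hz,
            "rate_bpm": estimate.rate_bpm,
            "amplitude": estimate.amplitude,
            "detected": estimate.detected,
            "snr": estimate.snr,
        },
    }
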