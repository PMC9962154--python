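"""Free-run acquisition of the illumination protocol.

This module executes the device's timing protocol against a scene renderer
and captures it with a simulated free-run rolling-shutter camera:

* :class:`TimingConfig` / :class:`PatternSequence` — the protocol state
  machine: per pattern, all LEDs are dark for ``t_u + t_delay`` (register
  update + settling, the dark/reference window), then the selected NIR LEDs
  turn on, the 7-segment indicator displays the pattern strictly inside the
  LED window, and after ``t_on`` everything switches off again.  Twelve
  single-diode patterns P1–P12 are followed by the external-illumination
  pattern P13 (indicator sentinel ``000011110000``).
* :func:`build_timeline` — compiles the protocol into an explicit event list.
* :func:`render_indicator` — the in-frame 7-segment state indicator
  (4 displays × 3 segments = 12 detector sites, lit at saturating level).
* :func:`capture` — rolling-shutter integrate-and-dump: row ``r`` of frame
  ``k`` integrates the scene over ``[k/f + r·ρ, k/f + r·ρ + exposure]`` with
  ``ρ = frame period / rows``; frames straddling a switching event contain
  mixed rows, which is exactly what the extraction stage must reject.
  Timestamps depend only on the frame rate — free-run means no
  synchronization with the illuminator.

The camera gain is fixed so that an irradiance of 1.0 sustained over a full
exposure quantizes to 255 ADU (the saturation level).
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .phantom import (
    DiodeBank,
    FingerPhantom,
    cardiac_waveform,
    code_to_bits,
    diode_static_image,
    render_frontlit,
    _absorption_for,
)

__all__ = [
    "EXTERNAL_CODE",
    "DARK_CODE",
    "Geometry",
    "TimingConfig",
    "PatternEntry",
    "PatternSequence",
    "Event",
    "Cycle",
    "EventTimeline",
    "build_timeline",
    "default_detector_sites",
    "render_indicator",
    "SceneRenderer",
    "FrameSequence",
    "capture",
    "add_stray_light",
    "write_raw_frames",
    "load_raw_frames",
]

#: Indicator code shown while the external front illuminator is on (P13).
EXTERNAL_CODE = "000011110000"
DARK_CODE = "000000000000"

#: Irradiance of a lit 7-segment site, in units of the camera's saturation
#: irradiance: 4× saturation, so a segment lit for ≥ 25% of the exposure
#: still reads 255 ADU and even a ~2% sliver clears the 20 ADU threshold.
SEG_LEVEL = 4.0


@dataclass(frozen=True)
class Geometry:
    """Frame geometry: a finger region with an indicator strip appended as a
    longitudinal extension (the displays sit beyond the fingertip)."""

    rows: int = 260
    cols: int = 400
    finger_col_stop: int = 320  # strip occupies columns [finger_col_stop, cols)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not 0 < self.finger_col_stop < self.cols:
            raise ValueError("finger_col_stop must lie strictly inside the frame")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def strip_width(self) -> int:
        return self.cols - self.finger_col_stop


@dataclass(frozen=True)
class TimingConfig:
    """Timing of the illumination protocol and the camera.

    ``t_u`` (register update) is hardware-determined in the real device and a
    free parameter here; its 17 ms default makes the per-pattern cycle
    ``t_u + t_delay + t_on`` equal 30 ms, which at 13 patterns per sweep
    yields ~33 extracted frames per second from a ~130 FPS stream.
    """

    t_u: float = 0.017  # s, controller register update
    t_delay: float = 0.003  # s, settling delay after the update
    t_on: float = 0.010  # s, 7-segment indicator window length
    exposure: float = 0.005  # s, per-row camera exposure
    frame_rate: float = 130.0  # frames / s, free-run
    rows: int = 260  # frame height (post-binning longitudinal slice)
    seg_lag: float = 0.0015  # s, controller/display transaction latency: the
    # NIR LEDs switch on one lag before SEG_ON and off one lag after SEG_OFF,
    # so the LED window is t_on + 2·seg_lag, eating into the off period.
    # The default makes the LED window (13 ms) exceed exposure + frame period
    # (12.7 ms), the bound at which every sensor row is guaranteed one fully
    # illuminated exposure per cycle — without it the per-pixel maximum could
    # not reconstruct fully lit images from the unsynchronized stream.

    def __post_init__(self) -> None:
        for name in ("t_u", "t_delay", "t_on", "exposure", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"timing parameter {name} must be positive")
        if self.t_on < self.exposure:
            raise ValueError("t_on must be >= exposure")
        if self.rows <= 0:
            raise ValueError("rows must be positive")
        if not 0 <= self.seg_lag < (self.t_u + self.t_delay) / 2:
            raise ValueError("seg_lag must lie in [0, t_off/2)")

    @property
    def t_off(self) -> float:
        """Nominal all-LEDs-off time per cycle (dark/reference window); the
        LED switching lags shave ``2·seg_lag`` off it in practice."""
        return self.t_u + self.t_delay

    @property
    def cycle(self) -> float:
        return self.t_u + self.t_delay + self.t_on

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def row_readout(self) -> float:
        """Row exposure stagger of the rolling shutter (s per row)."""
        return self.frame_period / self.rows


@dataclass(frozen=True)
class PatternEntry:
    name: str
    nir_code: str  # 12-bit state of the back-light NIR diodes
    indicator_code: str  # 12-bit state shown on the 7-segment detector sites
    external: bool = False

    def __post_init__(self) -> None:
        code_to_bits(self.nir_code)
        code_to_bits(self.indicator_code)


@dataclass(frozen=True)
class PatternSequence:
    """One sweep = 12 NIR-only single-diode patterns, then the external one."""

    patterns: Tuple[PatternEntry, ...]
    repeat_count: int = 1

    def __post_init__(self) -> None:
        if self.repeat_count < 0:
            raise ValueError("repeat_count must be >= 0")
        for p in self.patterns:
            if p.external and code_to_bits(p.nir_code).any():
                raise ValueError("external pattern must not light NIR diodes")

    @staticmethod
    def default(repeat_count: int = 1) -> "PatternSequence":
        entries = []
        for j in range(12):
            code = "".join("1" if k == j else "0" for k in range(12))
            entries.append(PatternEntry(name=f"P{j + 1}", nir_code=code, indicator_code=code))
        entries.append(
            PatternEntry(name="P13", nir_code=DARK_CODE,
                         indicator_code=EXTERNAL_CODE, external=True)
        )
        return PatternSequence(patterns=tuple(entries), repeat_count=repeat_count)

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass(frozen=True)
class Event:
    time: float
    kind: str  # LEDS_ON | LEDS_OFF | SEG_ON | SEG_OFF | EXT_ON | EXT_OFF
    pattern: PatternEntry


@dataclass(frozen=True)
class Cycle:
    index: int
    pattern: PatternEntry
    t_start: float
    t_led_on: float
    t_seg_on: float
    t_seg_off: float
    t_led_off: float
    t_end: float


class EventTimeline:
    """Compiled protocol: ordered events plus per-cycle bookkeeping, with a
    piecewise-constant state lookup used by the scene renderer."""

    def __init__(self, events: Sequence[Event], cycles: Sequence[Cycle], duration: float):
        self.events: List[Event] = list(events)
        self.cycles: List[Cycle] = list(cycles)
        self.duration = float(duration)
        # state segments: starts[i] <= t < starts[i+1] -> states[i]
        starts = [0.0]
        states: List[Tuple[str, str, bool]] = [(DARK_CODE, DARK_CODE, False)]
        for cyc in self.cycles:
            p = cyc.pattern
            for t, state in (
                (cyc.t_led_on, (p.nir_code, DARK_CODE, p.external)),
                (cyc.t_seg_on, (p.nir_code, p.indicator_code, p.external)),
                (cyc.t_seg_off, (p.nir_code, DARK_CODE, p.external)),
                (cyc.t_led_off, (DARK_CODE, DARK_CODE, False)),
            ):
                if t > starts[-1]:
                    starts.append(t)
                    states.append(state)
                else:  # degenerate zero-length phase (seg_lag = 0)
                    states[-1] = state
        self._seg_starts = starts
        self._seg_states = states

    def event_times(self) -> np.ndarray:
        return np.array(sorted({e.time for e in self.events}), dtype=float)

    def state_at(self, t: float) -> Tuple[str, str, bool]:
        """(nir_code, indicator_code, external_on) active at time t."""
        if t < 0.0:
            return (DARK_CODE, DARK_CODE, False)
        i = bisect_right(self._seg_starts, t) - 1
        return self._seg_states[i]

    def __len__(self) -> int:
        return len(self.events)


def build_timeline(timing: TimingConfig, seq: PatternSequence) -> EventTimeline:
    """Compile the protocol into events.

    Per cycle: register update (t_u) → delay (t_delay) → LEDS_ON →
    SEG_ON → … t_on elapses … → SEG_OFF → LEDS_OFF.  The 7-segment window
    is exactly ``t_on`` long and sits strictly inside the LED window (the
    switching lags extend the LED window by ``seg_lag`` on either side, at
    the expense of the off period); the cycle lasts exactly
    ``t_u + t_delay + t_on``.
    """
    if len(seq) == 0:
        raise ValueError("pattern sequence must not be empty")
    events: List[Event] = []
    cycles: List[Cycle] = []
    t = 0.0
    index = 0
    for _ in range(seq.repeat_count):
        for pattern in seq.patterns:
            t_seg_on = t + timing.t_u + timing.t_delay
            t_led_on = t_seg_on - timing.seg_lag
            t_seg_off = t_seg_on + timing.t_on
            t_led_off = t_seg_off + timing.seg_lag
            t_end = t + timing.cycle
            events.append(Event(t_led_on, "LEDS_ON", pattern))
            events.append(Event(t_seg_on, "SEG_ON", pattern))
            if pattern.external:
                events.append(Event(t_led_on, "EXT_ON", pattern))
            events.append(Event(t_seg_off, "SEG_OFF", pattern))
            if pattern.external:
                events.append(Event(t_led_off, "EXT_OFF", pattern))
            events.append(Event(t_led_off, "LEDS_OFF", pattern))
            cycles.append(
                Cycle(index, pattern, t, t_led_on, t_seg_on, t_seg_off,
                      t_led_off, t_end)
            )
            t = t_end
            index += 1
    return EventTimeline(events, cycles, duration=t)


# ---------------------------------------------------------------------------
# Indicator strip
# ---------------------------------------------------------------------------

def default_detector_sites(geometry: Geometry) -> List[Tuple[int, int]]:
    """Detector-pixel coordinates of the 12 indicator sites, diode order.

    Diode ``j`` maps to display ``j % 4`` (longitudinal position) and segment
    ``j // 4`` (wavelength row); the four displays are spread across the
    strip, the three segments stacked vertically around the finger mid-line.
    """
    seg_rows = [int(round(f * geometry.rows)) for f in (0.38, 0.50, 0.62)]
    disp_cols = [
        geometry.finger_col_stop + int(round(f * geometry.strip_width))
        for f in (0.18, 0.38, 0.58, 0.78)
    ]
    return [(seg_rows[j // 4], disp_cols[j % 4]) for j in range(12)]


def render_indicator(pattern, geometry: Geometry, *, seg_level: float = SEG_LEVEL,
                     blob_radius: int = 1) -> np.ndarray:
    """Irradiance fragment of the indicator strip for a 12-bit code.

    Lit segments render as small blobs at ``seg_level`` (≥ the level that
    saturates a full exposure at 255 ADU); unlit segments are dark.  Glyph
    shapes are cosmetic in the real device — only the detector pixels are
    ever read — so sites are rendered as plain blobs.
    """
    bits = code_to_bits(pattern)
    frag = np.zeros((geometry.rows, geometry.strip_width), dtype=float)
    for j in np.flatnonzero(bits):
        r, c = default_detector_sites(geometry)[j]
        c -= geometry.finger_col_stop
        r0, r1 = max(0, r - blob_radius), min(geometry.rows, r + blob_radius + 1)
        c0, c1 = max(0, c - blob_radius), min(geometry.strip_width, c + blob_radius + 1)
        frag[r0:r1, c0:c1] = seg_level
    return frag


# ---------------------------------------------------------------------------
# Scene renderer
# ---------------------------------------------------------------------------

class SceneRenderer:
    """Time-dependent irradiance of the full frame under the protocol.

    Precomputes each diode's static Beer–Lambert image once and applies the
    cardiac modulation only on vein pixels per evaluation, so rendering a
    multi-second video stays cheap.  Calling the renderer at time ``t``
    returns the composite irradiance image: back light + indicator strip +
    (for the external pattern) the front-lit reflectance image.
    """

    def __init__(self, phantom: FingerPhantom, bank: DiodeBank,
                 timeline: EventTimeline, geometry: Geometry, *,
                 seg_level: float = SEG_LEVEL):
        if phantom.shape != geometry.shape:
            raise ValueError(
                f"phantom shape {phantom.shape} != frame geometry {geometry.shape}"
            )
        self.phantom = phantom
        self.bank = bank
        self.timeline = timeline
        self.geometry = geometry
        self.seg_level = seg_level
        self._zeros = np.zeros(geometry.shape, dtype=float)
        self._bases = [diode_static_image(phantom, bank, j) for j in range(12)]
        self._vein_idx = np.flatnonzero(phantom.vein_depth_map > 0)
        vein_flat = phantom.vein_depth_map.ravel()[self._vein_idx]
        self._mu_b_v = {}
        for j in range(12):
            lam = bank.wavelength(j)
            if lam not in self._mu_b_v:
                _, mu_b = _absorption_for(phantom, lam)
                self._mu_b_v[lam] = mu_b * vein_flat
        self._front = render_frontlit(phantom, bank)
        self._seg_cache: dict[str, np.ndarray] = {}

    def _seg_image(self, code: str) -> np.ndarray:
        if code not in self._seg_cache:
            frag = render_indicator(code, self.geometry, seg_level=self.seg_level)
            full = np.zeros(self.geometry.shape, dtype=float)
            full[:, self.geometry.finger_col_stop:] = frag
            self._seg_cache[code] = full
        return self._seg_cache[code]

    def __call__(self, t: float) -> np.ndarray:
        nir_code, seg_code, ext = self.timeline.state_at(t)
        nir = code_to_bits(nir_code)
        if not nir.any() and seg_code == DARK_CODE and not ext:
            return self._zeros
        img = np.zeros(self.geometry.shape, dtype=float)
        if nir.any():
            pulse = self.phantom.pulse
            w = float(cardiac_waveform(t, pulse.rate_bpm, pulse.phase))
            for j in np.flatnonzero(nir):
                base = self._bases[int(j)]
                img += base
                if pulse.amplitude > 0 and self._vein_idx.size:
                    lam = self.bank.wavelength(int(j))
                    mod = np.exp(-self._mu_b_v[lam] * pulse.amplitude * w) - 1.0
                    img.ravel()[self._vein_idx] += base.ravel()[self._vein_idx] * mod
        if ext:
            img += self._front
        if seg_code != DARK_CODE:
            img += self._seg_image(seg_code)
        return img


# ---------------------------------------------------------------------------
# Capture
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Timestamped stack of 8-bit frames (the free-run video)."""

    frames: np.ndarray  # (n, rows, cols) uint8
    timestamps: np.ndarray  # (n,) seconds, frame start
    geometry: Geometry | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8, ADU 0-255)")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


def capture(
    scene: Callable[[float], np.ndarray],
    timeline: EventTimeline,
    timing: TimingConfig,
    n_frames: int,
    *,
    gain: float | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    geometry: Geometry | None = None,
) -> FrameSequence:
    """Simulate the free-run rolling-shutter camera.

    Row ``r`` of frame ``k`` integrates the scene over
    ``[k/f + r·ρ, k/f + r·ρ + exposure]`` (ρ = row readout time); the
    integral is taken piecewise between illumination events, evaluating the
    scene at each piece's midpoint (exact for the piecewise-constant
    illumination states; the slow cardiac modulation is sampled per piece).
    Integrated irradiance is scaled by the gain, optionally degraded with
    Gaussian read noise, floored to integer ADU and clipped to [0, 255].

    Frame timestamps are ``k / frame_rate`` — they never depend on the
    timeline (free-run: no synchronization with the illuminator).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    probe = np.asarray(scene(0.0), dtype=float)
    if probe.ndim != 2 or probe.shape[0] != timing.rows:
        raise ValueError(
            f"scene must return a ({timing.rows}, cols) image, got {probe.shape}"
        )
    rows, cols = probe.shape
    if gain is None:
        gain = 255.0 / timing.exposure  # irradiance 1.0 over full exposure -> 255
    if noise_sigma > 0 and rng is None:
        rng = np.random.default_rng(0)

    rho = timing.row_readout
    exposure = timing.exposure
    row_starts = np.arange(rows, dtype=float) * rho
    bps = timeline.event_times()
    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    timestamps = np.arange(n_frames, dtype=float) * timing.frame_period

    for k in range(n_frames):
        t0 = timestamps[k]
        t_end = t0 + row_starts[-1] + exposure
        inner = bps[(bps > t0) & (bps < t_end)]
        edges = np.concatenate(([t0], inner, [t_end]))
        acc = np.zeros((rows, cols), dtype=float)
        starts = t0 + row_starts
        ends = starts + exposure
        for a, b in zip(edges[:-1], edges[1:]):
            ov = np.clip(np.minimum(b, ends) - np.maximum(a, starts), 0.0, None)
            if not ov.any():
                continue
            img = scene(0.5 * (a + b))
            acc += ov[:, None] * img
        adu = gain * acc
        if noise_sigma > 0:
            adu = adu + rng.normal(0.0, noise_sigma, size=adu.shape)
        # epsilon keeps exact-integer ADU products off the floor boundary
        frames[k] = np.clip(np.floor(adu + 1e-9), 0, 255).astype(np.uint8)

    return FrameSequence(frames=frames, timestamps=timestamps, geometry=geometry)


def add_stray_light(video: FrameSequence, offset) -> FrameSequence:
    """Add a constant or slowly varying stray-light field, clipping at 255.

    Used to exercise the background-subtraction robustness of the extraction
    stage; a scalar ADU offset or a per-pixel field broadcastable to a frame.
    """
    offset = np.asarray(offset, dtype=float)
    if np.any(offset < 0):
        raise ValueError("stray-light offset must be >= 0")
    lifted = np.clip(np.floor(video.frames.astype(float) + offset), 0, 255)
    return FrameSequence(frames=lifted.astype(np.uint8),
                         timestamps=video.timestamps.copy(),
                         geometry=video.geometry)


# ---------------------------------------------------------------------------
# Raw-frame I/O (public-release layout: PNGs named by second of measurement)
# ---------------------------------------------------------------------------

def write_raw_frames(video: FrameSequence, out_dir, *,
                     ground_truth: Sequence[str] | None = None) -> List[str]:
    """Write the video as 8-bit grayscale PNGs named by capture second.

    Three decimals are used (``0.508.png``): at 130 FPS two decimals would
    collide between neighbouring frames.  A sidecar ``index.csv``
    (filename, timestamp, per-frame ground-truth code — testing only) is
    written when ground truth is supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for frame, t in zip(video.frames, video.timestamps):
        name = f"{t:.3f}.png"
        iio.imwrite(out / name, frame)
        names.append(name)
    if ground_truth is not None:
        codes = list(ground_truth)
        if len(codes) != len(names):
            raise ValueError("one ground-truth code per frame required")
        with open(out / "index.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "timestamp", "code"])
            for name, t, code in zip(names, video.timestamps, codes):
                writer.writerow([name, f"{t:.6f}", code])
    return names


def load_raw_frames(in_dir) -> FrameSequence:
    """Load a directory of raw PNGs, timestamps parsed from the filenames
    (seconds of measurement); frames sort numerically, not lexically."""
    in_dir = Path(in_dir)
    entries = []
    for path in in_dir.glob("*.png"):
        try:
            t = float(path.stem)
        except ValueError:
            continue
        entries.append((t, path))
    if not entries:
        raise ValueError(f"no timestamp-named PNG frames found in {in_dir}")
    entries.sort(key=lambda e: e[0])
    frames = np.stack([np.asarray(iio.imread(p)) for _, p in entries])
    if frames.dtype != np.uint8:
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    timestamps = np.array([t for t, _ in entries])
    return FrameSequence(frames=frames, timestamps=timestamps)
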