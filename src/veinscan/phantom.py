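"""Procedural finger optical phantom.

Generates a synthetic trans-illuminated finger — silhouette, branching vein
network, bulk-tissue thickness, nail/lunula region and a front-lit surface
texture — and renders the irradiance reaching the sensor for any combination
of the twelve back-light NIR diodes at any point in time.

The optical model is deliberately simple and closed-form testable:
Beer–Lambert attenuation along per-pixel effective path lengths, with a
separable Gaussian falloff per light source standing in for diffuse
transmission through tissue.  For each pixel and each lit diode ``j`` of
wavelength ``λ``::

    E_j = P_j · G_j(r, c) · exp(−μ_t(λ)·T_eff − μ_b(λ)·V·(1 + a·w(t)))

where ``T_eff`` is the bulk-tissue path (reduced inside the nail), ``V`` the
vein-blood path, ``a`` the fractional cardiac modulation amplitude and
``w(t)`` a zero-mean cardiac waveform normalized to unit peak-to-peak.  The
total backlit irradiance is the sum over lit diodes, zero outside the finger
silhouette (the housing aperture blocks direct light).

Units are arbitrary but consistent: depths in "finger thickness units",
absorption coefficients in their inverse; an irradiance of 1.0 sustained over
a full camera exposure maps to the 255 ADU saturation level downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PulseParams",
    "PhantomConfig",
    "FingerPhantom",
    "DiodeBank",
    "ExternalLed",
    "generate_phantom",
    "default_diode_bank",
    "render_backlit",
    "render_frontlit",
    "cardiac_waveform",
    "code_to_bits",
    "DEFAULT_ABSORPTION",
]

# λ [nm] -> (μ_tissue, μ_blood) in inverse depth units.  The paper's device
# states only the wavelengths (730/875/940 back light, 830 front light); the
# coefficients are free parameters chosen so that veins are visible at all
# three wavelengths with a strict, configurable contrast ordering
# (μ_b(730) < μ_b(875) < μ_b(940) by default).  Only the ordering is asserted.
DEFAULT_ABSORPTION: Dict[float, Tuple[float, float]] = {
    730.0: (0.22, 0.70),
    830.0: (0.18, 0.90),
    875.0: (0.16, 1.00),
    940.0: (0.12, 1.30),
}

#: Relative weight of the first harmonic in the cardiac waveform (gives the
#: asymmetric systolic upstroke of a real photoplethysmogram).
_HARMONIC_WEIGHT = 0.3


def _waveform_ptp() -> float:
    th = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    g = np.sin(th) + _HARMONIC_WEIGHT * np.sin(2.0 * th)
    return float(g.max() - g.min())


_WAVEFORM_PTP = _waveform_ptp()


def cardiac_waveform(t, rate_bpm: float, phase: float = 0.0):
    """Zero-mean cardiac waveform with unit peak-to-peak amplitude.

    Fundamental sinusoid at ``rate_bpm/60`` Hz plus one second harmonic at
    relative weight 0.3, normalized so max(w) − min(w) = 1.  With this
    normalization a pixel with unit blood optical depth modulated at
    amplitude ``a`` shows a fractional peak-to-peak intensity swing ≈ ``a``.
    """
    theta = 2.0 * np.pi * (rate_bpm / 60.0) * np.asarray(t, dtype=float) + phase
    return (np.sin(theta) + _HARMONIC_WEIGHT * np.sin(2.0 * theta)) / _WAVEFORM_PTP


@dataclass(frozen=True)
class PulseParams:
    """Cardiac modulation of the vein-blood optical path.

    amplitude is the fractional modulation of the blood path length; the
    resulting image-intensity modulation "does not exceed a few percent" for
    physiological settings, so amplitudes are capped at 0.2.
    """

    rate_bpm: float = 90.0
    amplitude: float = 0.03
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise ValueError("pulse rate_bpm must be positive")
        if not 0.0 <= self.amplitude <= 0.2:
            raise ValueError("pulse amplitude must lie in [0, 0.2]")


@dataclass(frozen=True)
class PhantomConfig:
    """Tunable parameters of the procedural phantom generator."""

    #: scales the number of vein trunks and the branching probability;
    #: 0 disables veins entirely.
    vein_density: float = 1.0
    #: vein widths drawn in this pixel range (dilated curvilinear strokes).
    vein_width_px: Tuple[float, float] = (2.0, 8.0)
    #: blood path length per pixel = local vein radius × this factor.
    vein_depth_scale: float = 0.8
    #: bulk tissue path length at the finger mid-line.
    tissue_depth_max: float = 2.0
    #: multiplier on tissue depth inside the nail/lunula (bright nail regions).
    nail_factor: float = 0.35
    #: depth of the multiplicative surface texture (skin folds), in (0, 1).
    texture_contrast: float = 0.35
    #: fraction of the frame width occupied by the finger (the rest is the
    #: indicator strip); the finger is rendered along the column axis.
    finger_col_fraction: float = 0.8
    #: finger half-width as a fraction of the frame height.
    halfwidth_fraction: float = 0.27
    pulse: PulseParams = field(default_factory=PulseParams)
    absorption: Dict[float, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ABSORPTION)
    )

    def __post_init__(self) -> None:
        if self.vein_density < 0:
            raise ValueError("vein_density must be >= 0")
        if not 0 < self.finger_col_fraction <= 1:
            raise ValueError("finger_col_fraction must lie in (0, 1]")
        if not 0 < self.texture_contrast < 1:
            raise ValueError("texture_contrast must lie in (0, 1)")


@dataclass
class FingerPhantom:
    """Optical model of a finger on a per-pixel basis.

    All maps share one shape (row-major, origin top-left, 0-based indices).
    """

    finger_mask: np.ndarray  # bool
    vein_depth_map: np.ndarray  # float >= 0, nonzero only inside the mask
    tissue_depth_map: np.ndarray  # float >= 0
    texture_map: np.ndarray  # float in (0, 1]
    nail_mask: np.ndarray  # bool
    absorption: Dict[float, Tuple[float, float]]
    pulse: PulseParams
    nail_factor: float = 0.35

    def __post_init__(self) -> None:
        shape = self.finger_mask.shape
        for name in ("vein_depth_map", "tissue_depth_map", "texture_map", "nail_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if not np.all(np.isfinite(self.vein_depth_map)) or self.vein_depth_map.min() < 0:
            raise ValueError("vein_depth_map must be finite and >= 0")
        if not np.all(np.isfinite(self.tissue_depth_map)) or self.tissue_depth_map.min() < 0:
            raise ValueError("tissue_depth_map must be finite and >= 0")
        if np.any(self.vein_depth_map[~self.finger_mask] > 0):
            raise ValueError("vein_depth_map must be zero outside finger_mask")
        if self.texture_map.min() <= 0 or self.texture_map.max() > 1:
            raise ValueError("texture_map values must lie in (0, 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.finger_mask.shape

    def effective_tissue_depth(self) -> np.ndarray:
        """Bulk tissue path with the nail relief applied (bright nail/lunula)."""
        depth = self.tissue_depth_map.copy()
        depth[self.nail_mask] *= self.nail_factor
        return depth


@dataclass(frozen=True)
class ExternalLed:
    """Front illuminator (externally mounted LED lighting the finger surface)."""

    wavelength_nm: float = 830.0
    power: float = 0.6  # relative optical power after reflectance efficiency
    position: Tuple[float, float] | None = None  # defaults to finger centre
    falloff_sigma: float = 150.0


@dataclass(frozen=True)
class DiodeBank:
    """The 12 back-light NIR sources: 3 wavelength rows × 4 positions.

    Row 0 carries 940 nm diodes, row 1 875 nm, row 2 730 nm, with relative
    optical powers matching the device's 140/210/240 mW parts.  Diode index
    ``j`` (0-based) sits in wavelength row ``j // 4``, longitudinal position
    ``j % 4``; the pattern codes P1..P12 map to these indices in order.
    """

    positions: Tuple[Tuple[float, float], ...]  # 12 (row, col) source centres
    wavelengths_by_row: Dict[int, float] = field(
        default_factory=lambda: {0: 940.0, 1: 875.0, 2: 730.0}
    )
    powers_by_row: Dict[int, float] = field(
        default_factory=lambda: {0: 140.0 / 240.0, 1: 210.0 / 240.0, 2: 1.0}
    )
    external_led: ExternalLed = field(default_factory=ExternalLed)
    falloff_sigma: float = 70.0  # px, diffuse-transmission blur of a source
    source_scale: float = 0.8  # global brightness scale (keeps finger < 255 ADU)

    def __post_init__(self) -> None:
        if len(self.positions) != 12:
            raise ValueError("a DiodeBank has exactly 12 back-light sources")
        if set(self.wavelengths_by_row) != {0, 1, 2}:
            raise ValueError("wavelengths_by_row must define rows 0, 1, 2")

    def wavelength(self, diode: int) -> float:
        return self.wavelengths_by_row[diode // 4]

    def power(self, diode: int) -> float:
        return self.source_scale * self.powers_by_row[diode // 4]


def default_diode_bank(shape: Tuple[int, int], finger_col_stop: int | None = None) -> DiodeBank:
    """Diode bank laid out for a phantom of the given frame shape.

    Three LED rows straddle the finger mid-line; the four columns are spread
    along the finger axis within the finger region of the frame.
    """
    rows, cols = shape
    if finger_col_stop is None:
        finger_col_stop = int(round(0.8 * cols))
    led_rows = [0.365 * rows, 0.5 * rows, 0.635 * rows]
    led_cols = [f * finger_col_stop for f in (0.18, 0.36, 0.54, 0.72)]
    positions = tuple(
        (led_rows[r], led_cols[c]) for r in range(3) for c in range(4)
    )
    ext = ExternalLed(position=(0.5 * rows, 0.45 * finger_col_stop),
                      falloff_sigma=0.5 * finger_col_stop)
    return DiodeBank(positions=positions, external_led=ext,
                     falloff_sigma=max(8.0, 0.22 * finger_col_stop))


def code_to_bits(pattern) -> np.ndarray:
    """Normalize a 12-bit diode pattern (string like '100000000000', int
    sequence, or bool array) to a length-12 boolean vector."""
    if isinstance(pattern, str):
        if len(pattern) != 12 or set(pattern) - {"0", "1"}:
            raise ValueError(f"pattern must be a 12-character binary string, got {pattern!r}")
        return np.array([ch == "1" for ch in pattern], dtype=bool)
    bits = np.asarray(pattern).astype(bool).ravel()
    if bits.size != 12:
        raise ValueError(f"pattern must have 12 bits, got {bits.size}")
    return bits


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _halfwidth_profile(u: np.ndarray, halfwidth: float) -> np.ndarray:
    """Finger half-width along the normalized axis u in [0, 1]: a rounded
    base, a straight shaft, and an elliptical fingertip."""
    h = np.full_like(u, halfwidth, dtype=float)
    base = u < 0.04
    h[base] = halfwidth * np.sqrt(np.clip(1.0 - ((0.04 - u[base]) / 0.04) ** 2, 0.0, 1.0))
    tip = u > 0.72
    h[tip] = halfwidth * np.sqrt(np.clip(1.0 - ((u[tip] - 0.72) / 0.28) ** 2, 0.0, 1.0))
    return h


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float, value: float) -> None:
    rows, cols = canvas.shape
    r0, r1 = int(max(0, math.floor(r - radius))), int(min(rows, math.ceil(r + radius) + 1))
    c0, c1 = int(max(0, math.floor(c - radius))), int(min(cols, math.ceil(c + radius) + 1))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, np.where(inside, value, 0.0), out=patch)


def _grow_vein_network(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    c_start: int,
    c_stop: int,
    centre_row: float,
    halfwidth: float,
    config: PhantomConfig,
) -> np.ndarray:
    """Connected branching network of curvilinear strokes, drawn as disks of
    slowly varying radius; returns the vein blood-path-length map."""
    canvas = np.zeros(shape, dtype=float)
    if config.vein_density <= 0:
        return canvas
    w_lo, w_hi = config.vein_width_px
    n_trunks = max(1, int(round(2 * config.vein_density)))
    root = (centre_row + rng.uniform(-0.15, 0.15) * halfwidth, float(c_start))
    # every trunk starts from the common root so the network is connected
    walkers = []
    for _ in range(n_trunks):
        walkers.append(
            {
                "row": root[0],
                "drift": rng.normal(0.0, 0.45),
                "width": rng.uniform(0.6 * w_hi, w_hi),
            }
        )
    branch_prob = 0.030 * config.vein_density
    max_walkers = max(4, int(10 * config.vein_density))
    span = max(1, c_stop - c_start)
    for c in range(c_start, c_stop):
        u = (c - c_start) / span
        h = float(_halfwidth_profile(np.array([u]), halfwidth)[0])
        taper = 0.45 + 0.55 * math.sqrt(max(1e-6, h / halfwidth))
        new_walkers = []
        for w in walkers:
            w["drift"] = 0.9 * w["drift"] + rng.normal(0.0, 0.22)
            w["row"] += w["drift"]
            limit = 0.8 * max(h, 2.0)
            w["row"] = float(np.clip(w["row"], centre_row - limit, centre_row + limit))
            w["width"] = float(np.clip(w["width"] + rng.normal(0.0, 0.25), w_lo, w_hi))
            radius = 0.5 * w["width"] * taper
            _stamp_disk(canvas, w["row"], c, max(radius, 0.5 * w_lo),
                        config.vein_depth_scale * max(radius, 0.5 * w_lo))
            if len(walkers) + len(new_walkers) < max_walkers and rng.random() < branch_prob:
                new_walkers.append(
                    {
                        "row": w["row"],
                        "drift": w["drift"] + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1),
                        "width": max(w_lo, 0.7 * w["width"]),
                    }
                )
        walkers.extend(new_walkers)
    return gaussian_filter(canvas, 0.7)


def generate_phantom(
    seed: int,
    shape: Tuple[int, int] = (260, 400),
    config: PhantomConfig | None = None,
) -> FingerPhantom:
    """Generate a deterministic finger phantom for the given seed.

    The frame is wide enough to hold both the finger (left
    ``finger_col_fraction`` of the columns) and the indicator strip appended
    by the acquisition stage; all phantom content stays in the finger region.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must have positive dimensions, got {shape}")
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    c_start = max(2, int(round(0.03 * cols)))
    c_stop = int(round(config.finger_col_fraction * cols))
    centre_row = 0.5 * rows
    halfwidth = config.halfwidth_fraction * rows

    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    u = np.clip((cc - c_start) / max(1, c_stop - c_start), 0.0, 1.0)
    h = _halfwidth_profile(u, halfwidth)
    inside_cols = (cc >= c_start) & (cc <= c_stop)
    rel = np.zeros_like(rr)
    np.divide(rr - centre_row, np.maximum(h, 1e-9), out=rel, where=h > 0)
    finger_mask = inside_cols & (h > 0) & (np.abs(rel) <= 1.0)

    # elliptical-chord tissue thickness, max at the mid-line
    tissue = np.zeros((rows, cols), dtype=float)
    tissue[finger_mask] = config.tissue_depth_max * np.sqrt(
        np.clip(1.0 - rel[finger_mask] ** 2, 0.0, 1.0)
    )

    veins = _grow_vein_network(rng, (rows, cols), c_start, c_stop, centre_row,
                               halfwidth, config)
    veins[~finger_mask] = 0.0

    # nail/lunula ellipse near the fingertip (low attenuation region)
    nail_c = c_start + 0.88 * (c_stop - c_start)
    nail = (
        ((rr - centre_row) / (0.45 * halfwidth)) ** 2
        + ((cc - nail_c) / (0.09 * (c_stop - c_start))) ** 2
    ) <= 1.0
    nail &= finger_mask

    # multiplicative surface texture: smooth mottle + quasi-periodic skin folds
    mottle = gaussian_filter(rng.standard_normal((rows, cols)), 4.0)
    mottle = (mottle - mottle.min()) / max(float(np.ptp(mottle)), 1e-12)
    folds = 0.5 + 0.5 * np.sin(2.0 * np.pi * (cc / 9.0 + 0.8 * mottle))
    texture = 1.0 - config.texture_contrast * (0.35 * mottle + 0.65 * folds)
    texture = np.clip(texture, 0.05, 1.0)

    return FingerPhantom(
        finger_mask=finger_mask,
        vein_depth_map=veins,
        tissue_depth_map=tissue,
        texture_map=texture,
        nail_mask=nail,
        absorption=dict(config.absorption),
        pulse=config.pulse,
        nail_factor=config.nail_factor,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _gaussian_falloff(shape: Tuple[int, int], position: Tuple[float, float],
                      sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    d2 = (rr - position[0]) ** 2 + (cc - position[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _absorption_for(phantom: FingerPhantom, wavelength: float) -> Tuple[float, float]:
    try:
        return phantom.absorption[wavelength]
    except KeyError:
        raise ValueError(
            f"no absorption coefficients configured for wavelength {wavelength} nm"
        ) from None


def diode_static_image(phantom: FingerPhantom, bank: DiodeBank, diode: int) -> np.ndarray:
    """Backlit irradiance contribution of one diode at zero cardiac phase
    (the ``1 + a·w`` factor evaluated at w = 0)."""
    lam = bank.wavelength(diode)
    mu_t, mu_b = _absorption_for(phantom, lam)
    g = _gaussian_falloff(phantom.shape, bank.positions[diode], bank.falloff_sigma)
    att = np.exp(-mu_t * phantom.effective_tissue_depth() - mu_b * phantom.vein_depth_map)
    return bank.power(diode) * g * att * phantom.finger_mask


def render_backlit(phantom: FingerPhantom, bank: DiodeBank, pattern, t: float) -> np.ndarray:
    """Irradiance image for a 12-bit diode pattern at time ``t`` seconds.

    Beer–Lambert per pixel and per lit diode, with the vein blood path
    modulated by the cardiac waveform; deterministic in (phantom, pattern, t).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    bits = code_to_bits(pattern)
    img = np.zeros(phantom.shape, dtype=float)
    if not bits.any():
        return img
    a = phantom.pulse.amplitude
    w = float(cardiac_waveform(t, phantom.pulse.rate_bpm, phantom.pulse.phase)) if a > 0 else 0.0
    for diode in np.flatnonzero(bits):
        base = diode_static_image(phantom, bank, int(diode))
        if a > 0:
            _, mu_b = _absorption_for(phantom, bank.wavelength(int(diode)))
            base = base * np.exp(-mu_b * phantom.vein_depth_map * a * w)
        img += base
    return img


def render_frontlit(phantom: FingerPhantom, bank: DiodeBank) -> np.ndarray:
    """Reflectance image under the external front illuminator.

    Surface texture only — veins are sub-surface and carry no contrast in
    reflection; zero outside the finger silhouette.
    """
    led = bank.external_led
    position = led.position
    if position is None:
        rows, cols = phantom.shape
        position = (0.5 * rows, 0.4 * cols)
    g = _gaussian_falloff(phantom.shape, position, led.falloff_sigma)
    return led.power * g * phantom.texture_map * phantom.finger_mask


def with_pulse(phantom: FingerPhantom, pulse: PulseParams) -> FingerPhantom:
    """Copy of the phantom with different cardiac parameters."""
    return replace(phantom, pulse=pulse)
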