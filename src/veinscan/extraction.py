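"""Demultiplexing a free-run video into per-diode finger images.

The camera runs unsynchronized, so the recorded stream interleaves dark
reference frames, clean frames in which one illumination pattern was on for
the whole exposure, and rolling-shutter transition frames in which diodes
switched mid-exposure.  The state indicator in the field of view makes the
stream self-describing: twelve fixed *detector pixels* (one per diode,
calibrated once per device) encode which diodes were lit during each frame's
exposure.

Extraction proceeds per frame ``i``:

1. read the detector levels ``d_j(i)``;
2. classify — bit ``j`` is set iff ``d_j(i)`` ≥ the 20 ADU detection
   threshold (saturation is 255 ADU; the low threshold catches diodes lit
   for only a small fraction of the exposure), all-zero ⇒ DARK;
3. segment the stream into illumination windows delimited by DARK frames;
4. within a window, combine all frames carrying the window's consensus code
   with a per-pixel **maximum** (the maximum keeps, per pixel, the frame in
   which that row was fully illuminated), and subtract the most recent DARK
   frame ``B`` pixelwise (clipped at 0) so constant stray light cancels.

The result is three parallel buffers: images, acquisition times and detected
diode-state codes.  ``write_processed`` serializes them in the public-release
layout (``D01_0.51.png`` … / ``DEXT_…`` inside a ``*_processed`` directory).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .acquisition import EXTERNAL_CODE, FrameSequence, Geometry, default_detector_sites

__all__ = [
    "DetectorLayout",
    "ExtractionResult",
    "read_detectors",
    "classify_frame",
    "extract",
    "write_processed",
    "read_processed",
]

logger = logging.getLogger("veinscan.extraction")


@dataclass(frozen=True)
class DetectorLayout:
    """Calibration of the 12 detector pixels and the detection threshold."""

    sites: Tuple[Tuple[int, int], ...]
    threshold: int = 20
    saturation: int = 255

    def __post_init__(self) -> None:
        if len(self.sites) != 12:
            raise ValueError("a detector layout has exactly 12 sites")
        if len(set(self.sites)) != 12:
            raise ValueError("detector sites must be distinct pixels")
        if not 0 < self.threshold < self.saturation:
            raise ValueError("threshold must lie strictly between 0 and saturation")

    @staticmethod
    def default(geometry: Geometry, threshold: int = 20) -> "DetectorLayout":
        return DetectorLayout(sites=tuple(default_detector_sites(geometry)),
                              threshold=threshold)

    def check_bounds(self, shape: Tuple[int, int]) -> None:
        for r, c in self.sites:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"detector site ({r}, {c}) out of bounds for {shape}")


def read_detectors(frame: np.ndarray, layout: DetectorLayout) -> np.ndarray:
    """ADU levels of the 12 detector pixels, in fixed diode order."""
    frame = np.asarray(frame)
    layout.check_bounds(frame.shape)
    rr = np.array([s[0] for s in layout.sites])
    cc = np.array([s[1] for s in layout.sites])
    return frame[rr, cc].astype(int)


def classify_frame(levels: Sequence[int], threshold: int = 20) -> Optional[str]:
    """Classify one frame from its detector levels.

    Bit ``j`` of the code is set iff ``levels[j] >= threshold`` (a level
    exactly at the threshold counts as lit).  Returns the 12-character code,
    or ``None`` for a DARK frame (no bit set).
    """
    levels = np.asarray(levels)
    if levels.shape != (12,):
        raise ValueError("expected 12 detector levels")
    bits = levels >= threshold
    if not bits.any():
        return None
    return "".join("1" if b else "0" for b in bits)


@dataclass
class ExtractionResult:
    """The three parallel output buffers of the extraction algorithm."""

    images: List[np.ndarray] = field(default_factory=list)  # uint8
    times: List[float] = field(default_factory=list)  # s, strictly increasing
    codes: List[str] = field(default_factory=list)  # 12-bit strings

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.times) == len(self.codes)):
            raise ValueError("images, times and codes must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for code in self.codes:
            if code != EXTERNAL_CODE and "1" not in code:
                raise ValueError("each code must have >= 1 set bit")

    def __len__(self) -> int:
        return len(self.images)


def _consensus(codes: Sequence[str]) -> str:
    """Window code: most set bits wins (transition frames can only lose
    bits), ties broken by frequency, then first occurrence."""
    order = {c: i for i, c in enumerate(dict.fromkeys(codes))}
    counts = {c: codes.count(c) for c in order}
    return max(order, key=lambda c: (c.count("1"), counts[c], -order[c]))


def extract(video: FrameSequence, layout: DetectorLayout) -> ExtractionResult:
    """Run the post-processing extraction over a free-run video.

    Detector levels are referenced to a per-site dark baseline (the minimum
    over the stream — the software analogue of the device calibration) before
    thresholding, so a constant stray-light pedestal cannot flip detectors;
    combined with the dark-frame background subtraction this makes the whole
    pipeline invariant to constant side illumination below saturation.

    The background ``B`` is the pixel-wise minimum over the most recent
    contiguous run of DARK frames: it tracks slowly varying stray light just
    like a single reference frame would, while rejecting the slivers of LED
    light that can leak into delimiter frames whose exposure brushes the LED
    switching lags at a window's edge.

    Frames preceding the first DARK frame have no background reference and
    are dropped with a warning.
    """
    if len(video) == 0:
        raise ValueError("video must not be empty")
    layout.check_bounds(video.shape)
    rr = np.array([s[0] for s in layout.sites])
    cc = np.array([s[1] for s in layout.sites])
    levels = video.frames[:, rr, cc].astype(int)  # (n, 12)
    baseline = levels.min(axis=0)
    corrected = levels - baseline

    codes = [classify_frame(corrected[i], layout.threshold) for i in range(len(video))]
    dark = [c is None for c in codes]
    if not any(dark):
        raise ValueError(
            "video contains no dark reference frame; cannot delimit windows "
            "or establish a background"
        )
    if not any(c is not None for c in codes):
        raise ValueError("video contains no illumination pattern frames")

    result = ExtractionResult()
    background: np.ndarray | None = None
    window: List[int] = []

    def flush(window_frames: List[int]) -> None:
        if not window_frames:
            return
        if background is None:
            logger.warning(
                "dropping window of %d frame(s) before the first dark frame "
                "(no background reference)", len(window_frames),
            )
            return
        window_codes = [codes[i] for i in window_frames]
        code = _consensus(window_codes)
        matched = [i for i in window_frames if codes[i] == code]
        rejected = len(window_frames) - len(matched)
        if rejected:
            logger.debug(
                "window at t=%.3f: rejected %d mixed/transition frame(s), kept %d with code %s",
                video.timestamps[matched[0]], rejected, len(matched), code,
            )
        stack = video.frames[matched].astype(int)
        combined = stack.max(axis=0)
        image = np.clip(combined - background.astype(int), 0, 255).astype(np.uint8)
        result.images.append(image)
        result.times.append(float(video.timestamps[matched[0]]))
        result.codes.append(code)

    for i in range(len(video)):
        if dark[i]:
            flush(window)
            window = []
            if background is None or (i > 0 and not dark[i - 1]):
                background = video.frames[i].copy()
            else:  # extend the current dark run: pixel-wise minimum
                background = np.minimum(background, video.frames[i])
        else:
            window.append(i)
    if window:
        # an illumination window must be delimited on both sides: a trailing
        # window cut off by the end of the recording is incomplete (its
        # per-pixel maximum would under-represent the illumination)
        logger.debug("dropping unterminated trailing window of %d frame(s)",
                     len(window))

    if len(result) == 0:
        raise ValueError("no illumination windows could be extracted")
    return result


# ---------------------------------------------------------------------------
# Processed-directory serialization (public-release layout)
# ---------------------------------------------------------------------------

_SINGLE_RE = re.compile(r"^D(\d{2})_([0-9.]+)\.png$")
_EXT_RE = re.compile(r"^DEXT_([0-9.]+)\.png$")
_MULTI_RE = re.compile(r"^P([01]{12})_([0-9.]+)\.png$")


def code_to_filename(code: str, t: float) -> str:
    """Release naming: ``D<nn>_<t>.png`` for single-diode codes (nn 1-based,
    two digits; t in seconds, 2 decimals), ``DEXT_<t>.png`` for the external
    pattern; other multi-diode codes fall back to ``P<code>_<t>.png``."""
    if code == EXTERNAL_CODE:
        return f"DEXT_{t:.2f}.png"
    if code.count("1") == 1:
        return f"D{code.index('1') + 1:02d}_{t:.2f}.png"
    logger.warning("multi-diode non-external code %s written with P-prefix naming", code)
    return f"P{code}_{t:.2f}.png"


def filename_to_code(name: str) -> Tuple[str, float]:
    m = _SINGLE_RE.match(name)
    if m:
        j = int(m.group(1)) - 1
        if not 0 <= j < 12:
            raise ValueError(f"diode index out of range in {name!r}")
        code = "".join("1" if k == j else "0" for k in range(12))
        return code, float(m.group(2))
    m = _EXT_RE.match(name)
    if m:
        return EXTERNAL_CODE, float(m.group(1))
    m = _MULTI_RE.match(name)
    if m:
        return m.group(1), float(m.group(2))
    raise ValueError(f"unrecognized processed filename {name!r}")


def write_processed(result: ExtractionResult, out_dir) -> List[dict]:
    """Write an extraction result as a ``*_processed`` directory of PNGs plus
    a ``manifest.csv`` (filename, time_s, code; full-precision times so a
    round trip reproduces the buffers exactly)."""
    out = Path(out_dir)
    if not out.name.endswith("_processed"):
        out = out.with_name(out.name + "_processed")
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for image, t, code in zip(result.images, result.times, result.codes):
        name = code_to_filename(code, t)
        iio.imwrite(out / name, image)
        manifest.append({"filename": name, "time_s": t, "code": code})
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "time_s", "code"])
        writer.writeheader()
        for row in manifest:
            writer.writerow({**row, "time_s": f"{row['time_s']:.9f}"})
    return manifest


def read_processed(in_dir) -> ExtractionResult:
    """Read a ``*_processed`` directory back into an ExtractionResult.

    Uses ``manifest.csv`` when present (exact times); otherwise times and
    codes are parsed from the release filenames."""
    in_dir = Path(in_dir)
    entries: List[Tuple[float, str, Path]] = []
    manifest = in_dir / "manifest.csv"
    if manifest.exists():
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append((float(row["time_s"]), row["code"],
                                in_dir / row["filename"]))
    else:
        for path in in_dir.glob("*.png"):
            try:
                code, t = filename_to_code(path.name)
            except ValueError:
                continue
            entries.append((t, code, path))
    if not entries:
        raise ValueError(f"no processed frames found in {in_dir}")
    entries.sort(key=lambda e: e[0])
    images = [np.asarray(iio.imread(p)).astype(np.uint8) for _, _, p in entries]
    return ExtractionResult(images=images,
                            times=[t for t, _, _ in entries],
                            codes=[c for _, c, _ in entries])
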