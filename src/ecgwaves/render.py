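"""Render a labelled 12-lead ECG signal into a standard paper-style image
plus a pixel-aligned class mask.

Geometry follows clinical ECG paper: 25 mm/s, 10 mm/mV, a 1 mm minor /
5 mm major calibration grid, and the conventional 3x4 lead layout
(columns I,II,III | aVR,aVL,aVF | V1-V3 | V4-V6, 2.5 s per column),
optionally with a full-duration lead II rhythm strip.

The trace and the mask are rasterised by the same integer column-run
routine with no anti-aliasing, so every mask pixel corresponds exactly to
a trace pixel and carries the wave class of the sample that produced it.
The grid never enters the mask.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform
from skimage.filters import gaussian as _sk_gaussian

from .errors import ConfigError
from .synthesis import LEAD_NAMES, LabelledSignal

__all__ = [
    "Layout",
    "RenderConfig",
    "LeadBox",
    "LayoutMetadata",
    "render_ecg",
    "pixel_of",
    "invert_pixel",
    "degrade_image",
    "save_layout",
    "load_layout",
]

RHYTHM_STRIP_KEY = "II:rhythm"


class Layout(str, enum.Enum):
    GRID_3x4 = "GRID_3x4"
    GRID_3x4_RHYTHM = "GRID_3x4_RHYTHM"


@dataclass(frozen=True)
class RenderConfig:
    px_per_mm: float = 8.0
    paper_speed: float = 25.0   # mm/s
    gain: float = 10.0          # mm/mV
    layout: Layout = Layout.GRID_3x4
    trace_width: int = 2        # px
    grid: bool = True
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    grid_minor_rgb: tuple[int, int, int] = (255, 204, 204)
    grid_major_rgb: tuple[int, int, int] = (244, 154, 154)
    trace_rgb: tuple[int, int, int] = (0, 0, 0)
    row_height_mm: float = 30.0
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0 or self.paper_speed <= 0 or self.gain <= 0:
            raise ConfigError("px_per_mm, paper_speed and gain must be > 0")
        if self.trace_width < 1:
            raise ConfigError("trace_width must be >= 1")


@dataclass(frozen=True)
class LeadBox:
    """Half-open pixel rect [row0, row1) x [col0, col1) displaying one lead
    from time t0 for `window` seconds."""

    lead: str
    row0: int
    row1: int
    col0: int
    col1: int
    t0: float
    window: float
    baseline_row: int


@dataclass
class LayoutMetadata:
    """Exact (time, voltage, lead) -> pixel mapping used by a render."""

    boxes: dict[str, LeadBox]
    px_per_second: float
    px_per_mV: float
    width: int
    height: int

    def box(self, lead: str) -> LeadBox:
        return self.boxes[lead]


_COLUMN_LEADS = (("I", "II", "III"), ("aVR", "aVL", "aVF"),
                 ("V1", "V2", "V3"), ("V4", "V5", "V6"))


def _build_layout(config: RenderConfig, duration: float) -> LayoutMetadata:
    pmm = config.px_per_mm
    pps = config.paper_speed * pmm
    ppmv = config.gain * pmm
    margin = int(round(config.margin_mm * pmm))
    row_h = int(round(config.row_height_mm * pmm))
    col_window = 2.5
    col_w = int(round(col_window * pps))

    n_rows = 3 + (1 if config.layout is Layout.GRID_3x4_RHYTHM else 0)
    width = 2 * margin + 4 * col_w
    height = 2 * margin + n_rows * row_h

    boxes: dict[str, LeadBox] = {}
    for c, leads in enumerate(_COLUMN_LEADS):
        for r, lead in enumerate(leads):
            row0 = margin + r * row_h
            col0 = margin + c * col_w
            boxes[lead] = LeadBox(
                lead=lead, row0=row0, row1=row0 + row_h,
                col0=col0, col1=col0 + col_w,
                t0=c * col_window, window=col_window,
                baseline_row=row0 + row_h // 2,
            )
    if config.layout is Layout.GRID_3x4_RHYTHM:
        row0 = margin + 3 * row_h
        boxes[RHYTHM_STRIP_KEY] = LeadBox(
            lead="II", row0=row0, row1=row0 + row_h,
            col0=margin, col1=margin + 4 * col_w,
            t0=0.0, window=min(duration, 4 * col_window),
            baseline_row=row0 + row_h // 2,
        )
    return LayoutMetadata(
        boxes=boxes, px_per_second=pps, px_per_mV=ppmv,
        width=width, height=height,
    )


def _draw_grid(image: np.ndarray, config: RenderConfig) -> None:
    pmm = config.px_per_mm
    margin = int(round(config.margin_mm * pmm))
    h, w = image.shape[:2]
    minor = np.asarray(config.grid_minor_rgb, dtype=np.uint8)
    major = np.asarray(config.grid_major_rgb, dtype=np.uint8)
    for mm in range(int(np.floor((w - 2 * margin) / pmm)) + 1):
        c = margin + int(round(mm * pmm))
        if c >= w - margin + 1:
            break
        image[margin:h - margin, c] = major if mm % 5 == 0 else minor
    for mm in range(int(np.floor((h - 2 * margin) / pmm)) + 1):
        r = margin + int(round(mm * pmm))
        if r >= h - margin + 1:
            break
        row = image[r, margin:w - margin]
        if mm % 5 == 0:
            row[:] = major
        else:
            keep = np.all(row == np.asarray(config.background_rgb), axis=-1)
            row[keep] = minor


def _trace_runs(box: LeadBox, layout: LayoutMetadata,
                t: np.ndarray, v: np.ndarray):
    """Column/row runs for one lead: consecutive samples are joined by a
    vertical run in the later sample's column (assumes fs >= px/s, so
    columns are never skipped)."""
    cols = box.col0 + np.round((t - box.t0) * layout.px_per_second).astype(int)
    rows = box.baseline_row - np.round(v * layout.px_per_mV).astype(int)
    rows = np.clip(rows, box.row0, box.row1 - 1)
    cols = np.clip(cols, box.col0, box.col1 - 1)
    return rows, cols


def _stamp_runs(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                values: np.ndarray, width: int, box: LeadBox) -> None:
    """Paint the trace of one lead onto `canvas` (RGB image or class mask).

    Pixel i..i+1 are joined by a vertical run at cols[i+1] carrying
    values[i+1]; the run is thickened to `width` px in both axes and
    clipped to the lead box.
    """
    lo = (width - 1) // 2
    hi = width // 2

    def paint(r0: int, r1: int, c: int, val) -> None:
        ra, rb = (r0, r1) if r0 <= r1 else (r1, r0)
        ra = max(ra - lo, box.row0)
        rb = min(rb + hi, box.row1 - 1)
        ca = max(c - lo, box.col0)
        cb = min(c + hi, box.col1 - 1)
        canvas[ra:rb + 1, ca:cb + 1] = val

    r_prev, c_prev = rows[0], cols[0]
    paint(r_prev, r_prev, c_prev, values[0])
    for i in range(1, len(rows)):
        r, c = rows[i], cols[i]
        if c == c_prev:
            paint(r_prev, r, c, values[i])
        else:
            # split the bridging run between the two columns so steep
            # slopes stay centred (no systematic half-column lag)
            rm = (r_prev + r) // 2
            paint(r_prev, rm, c_prev, values[i - 1])
            paint(rm, r, c, values[i])
        r_prev, c_prev = r, c


def render_ecg(
    signal: LabelledSignal, config: RenderConfig | None = None
) -> tuple[np.ndarray, np.ndarray, LayoutMetadata]:
    """Plot ``signal`` into (image, mask, layout).

    The image is H x W x 3 uint8; the mask is H x W uint8 with wave-class
    codes (0 everywhere off-trace; the calibration grid is image-only).

    Raises
    ------
    ConfigError
        If the record is shorter than the displayed window, or the
        sampling rate is below the horizontal pixel rate (columns would
        be skipped and the trace disconnected).
    """
    config = config or RenderConfig()
    fs = signal.config.sampling_rate
    duration = signal.config.duration
    layout = _build_layout(config, duration)
    needed = max(b.t0 + b.window for b in layout.boxes.values())
    if duration + 1e-9 < needed:
        raise ConfigError(
            f"record duration {duration}s shorter than displayed window {needed}s"
        )
    if fs < layout.px_per_second:
        raise ConfigError(
            "sampling_rate below px/s; render would skip columns"
        )

    image = np.empty((layout.height, layout.width, 3), dtype=np.uint8)
    image[:] = np.asarray(config.background_rgb, dtype=np.uint8)
    mask = np.zeros((layout.height, layout.width), dtype=np.uint8)
    if config.grid:
        _draw_grid(image, config)

    n = signal.samples.shape[1]
    t_all = np.arange(n) / fs
    trace_rgb = np.asarray(config.trace_rgb, dtype=np.uint8)
    for key, box in layout.boxes.items():
        li = LEAD_NAMES.index(box.lead)
        sel = (t_all >= box.t0) & (t_all < box.t0 + box.window)
        t = t_all[sel]
        v = signal.samples[li, sel]
        lab = signal.labels[li, sel]
        if len(t) == 0:
            continue
        rows, cols = _trace_runs(box, layout, t, v)
        rgb_vals = np.broadcast_to(trace_rgb, (len(rows), 3))
        _stamp_runs(image, rows, cols, rgb_vals, config.trace_width, box)
        _stamp_runs(mask, rows, cols, lab, config.trace_width, box)
    return image, mask, layout


# ------------------------------------------------------------- geometry


def pixel_of(layout: LayoutMetadata, lead: str, t: float, v: float
             ) -> tuple[int, int]:
    """Map (time s, voltage mV) on ``lead`` to an image (row, col)."""
    box = layout.box(lead)
    if not (box.t0 <= t <= box.t0 + box.window):
        raise ConfigError(
            f"t={t} outside displayed window [{box.t0}, {box.t0 + box.window}]"
        )
    col = box.col0 + int(round((t - box.t0) * layout.px_per_second))
    row = box.baseline_row - int(round(v * layout.px_per_mV))
    return row, col


def invert_pixel(layout: LayoutMetadata, lead: str, row: int, col: int
                 ) -> tuple[float, float]:
    """Inverse of :func:`pixel_of` (exact up to 1 px quantisation)."""
    box = layout.box(lead)
    t = box.t0 + (col - box.col0) / layout.px_per_second
    v = (box.baseline_row - row) / layout.px_per_mV
    return t, v


# ----------------------------------------------------------- degradation

_ARTEFACTS = ("rotation", "blur", "brightness_gradient", "blotches")


def degrade_image(image: np.ndarray, artefacts: dict, seed: int) -> np.ndarray:
    """Apply synthetic print/scan artefacts; deterministic given ``seed``.

    Supported keys: ``rotation`` (degrees, |angle| <= 5), ``blur``
    (Gaussian sigma px), ``brightness_gradient`` (relative amplitude),
    ``blotches`` (count).  Masks are never modified by this function.
    """
    for name in artefacts:
        if name not in _ARTEFACTS:
            raise ConfigError(f"unknown artefact: {name!r}")
    rng = np.random.default_rng([int(seed), 11])
    out = image.astype(np.float64) / 255.0

    if "rotation" in artefacts:
        angle = float(artefacts["rotation"])
        if abs(angle) > 5.0:
            raise ConfigError("rotation limited to +-5 degrees")
        out = sktransform.rotate(out, angle, mode="edge", order=1)
    if "blur" in artefacts:
        out = _sk_gaussian(out, sigma=float(artefacts["blur"]),
                           channel_axis=-1)
    if "brightness_gradient" in artefacts:
        amp = float(artefacts["brightness_gradient"])
        ramp = np.linspace(1.0 - amp, 1.0 + amp, out.shape[1])
        if rng.random() < 0.5:
            ramp = ramp[::-1]
        out = out * ramp[None, :, None]
    if "blotches" in artefacts:
        h, w = out.shape[:2]
        for _ in range(int(artefacts["blotches"])):
            r = rng.integers(0, h)
            c = rng.integers(0, w)
            radius = rng.integers(5, 25)
            shade = rng.uniform(0.3, 0.8)
            rr, cc = np.ogrid[:h, :w]
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2
            out[disk] *= shade
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


# -------------------------------------------------------------- layout IO


def save_layout(path: str | Path, layout: LayoutMetadata) -> None:
    d = {
        "px_per_second": layout.px_per_second,
        "px_per_mV": layout.px_per_mV,
        "width": layout.width,
        "height": layout.height,
        "boxes": {
            key: {
                "lead": b.lead, "row0": b.row0, "row1": b.row1,
                "col0": b.col0, "col1": b.col1, "t0": b.t0,
                "window": b.window, "baseline_row": b.baseline_row,
            }
            for key, b in layout.boxes.items()
        },
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def load_layout(path: str | Path) -> LayoutMetadata:
    d = json.loads(Path(path).read_text())
    boxes = {key: LeadBox(**bd) for key, bd in d["boxes"].items()}
    return LayoutMetadata(
        boxes=boxes, px_per_second=d["px_per_second"],
        px_per_mV=d["px_per_mV"], width=d["width"], height=d["height"],
    )
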