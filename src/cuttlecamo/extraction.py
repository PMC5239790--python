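"""Frame-stack to reflectance-trace extraction.

Emulates the video analysis chain of the original study: single-channel
(green) conversion, photometric balancing against an 18% gray standard
card present in every frame, mantle tracking at 0.1 s intervals, and a
1000-pixel (40 x 25) mantle sample averaged per frame.

Tracking uses generator ground-truth hints by default, mirroring the
original *manual* tracking (which has no error model); a centroid-based
detector is provided as a convenience for hint-free stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FrameStack",
    "MantleROI",
    "to_single_channel",
    "balance_to_gray_card",
    "track_mantle",
    "sample_mantle_reflectance",
    "compute_velocity",
    "extract_stack",
    "save_frames",
    "load_frames",
]


@dataclass(frozen=True)
class FrameStack:
    """A sequence of 8-bit frames plus acquisition metadata.

    ``card_region`` is (row0, col0, row1, col1), half-open, locating the
    18% gray reference card.  ``hints`` (optional) are per-frame mantle
    centers (row, col) from the generator's ground truth.
    """

    frames: np.ndarray = field(repr=False)
    dt_s: float = 0.1
    px_per_cm: float = 10.0
    card_region: tuple[int, int, int, int] = (2, 2, 12, 12)
    hints: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, 3)")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class MantleROI:
    """Rectangular mantle sample: 40 x 25 px = 1000 pixels by default.

    Anchoring convention for the even width: columns span
    ``center-20 .. center+19``, rows ``center-12 .. center+12``.
    """

    width_px: int = 40
    height_px: int = 25

    @property
    def n_pixels(self) -> int:
        return self.width_px * self.height_px


def to_single_channel(frame: np.ndarray) -> np.ndarray:
    """Green plane of an RGB frame, or the frame unchanged if already
    single-channel."""
    f = np.asarray(frame)
    if f.ndim == 2:
        return f
    if f.ndim == 3 and f.shape[2] == 3:
        return f[:, :, 1]
    raise ValueError(f"unsupported frame shape {f.shape}")


def balance_to_gray_card(
    grid: np.ndarray,
    card_region: tuple[int, int, int, int],
    card_reflectance_pct: float = 18.0,
) -> np.ndarray:
    """Convert raw gray levels to percent reflectance via the card.

    ``reflectance = pixel * (card_reflectance / mean(card pixels))``,
    clipped to [0, 100]; invariant to global exposure scaling.
    """
    r0, c0, r1, c1 = card_region
    card = np.asarray(grid, dtype=float)[r0:r1, c0:c1]
    if card.size == 0:
        raise ValueError("empty card region")
    m = card.mean()
    if m <= 1e-9:
        raise ValueError("gray-card mean is zero; cannot balance")
    return np.clip(np.asarray(grid, dtype=float) * (card_reflectance_pct / m), 0.0, 100.0)


def track_mantle(
    stack: FrameStack,
    hints: np.ndarray | None = None,
    detection_threshold: float = 8.0,
) -> np.ndarray:
    """Per-frame mantle center (row, col), float array with NaN rows where
    detection failed.

    With hints (explicit or carried by the stack) the hints are returned
    verbatim — the synthetic-data analogue of manual tracking.  Otherwise
    each frame is searched for the connected region most different from
    the background (the frame's modal gray level), excluding the card,
    and its centroid is reported.
    """
    if hints is None:
        hints = stack.hints
    n = len(stack)
    if hints is not None:
        h = np.asarray(hints, dtype=float)
        if h.shape != (n, 2):
            raise ValueError("hints must be (n_frames, 2)")
        return h
    centers = np.full((n, 2), np.nan)
    r0, c0, r1, c1 = stack.card_region
    for i in range(n):
        g = to_single_channel(stack.frames[i]).astype(float)
        vals, counts = np.unique(g.astype(int), return_counts=True)
        background = vals[np.argmax(counts)]
        diff = np.abs(g - background) > detection_threshold
        diff[r0:r1, c0:c1] = False
        labels, nlab = ndimage.label(diff)
        if nlab == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
        best = int(np.argmax(sizes)) + 1
        centers[i] = ndimage.center_of_mass(labels == best)
    return centers


def sample_mantle_reflectance(
    grid: np.ndarray,
    center_rc: tuple[int, int],
    roi: MantleROI = MantleROI(),
) -> float:
    """Mean reflectance over the mantle ROI centered at ``center_rc``.

    Raises if the window would be clipped by a frame edge.
    """
    r, c = int(round(center_rc[0])), int(round(center_rc[1]))
    hw, hh = roi.width_px // 2, roi.height_px // 2
    r0, r1 = r - hh, r + hh + 1
    c0, c1 = c - hw, c + hw
    g = np.asarray(grid, dtype=float)
    if r0 < 0 or c0 < 0 or r1 > g.shape[0] or c1 > g.shape[1]:
        raise ValueError("mantle ROI clipped by the frame edge")
    win = g[r0:r1, c0:c1]
    assert win.size == roi.n_pixels
    return float(win.mean())


def compute_velocity(trajectory: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-interval speed (|dx|/dt, cm/s) and the crossing mean speed."""
    x = trajectory["x_cm"].to_numpy(dtype=float)
    t = trajectory["t_s"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two trajectory samples")
    speeds = np.abs(np.diff(x)) / np.diff(t)
    return speeds, float(speeds.mean())


def extract_stack(
    stack: FrameStack,
    hints: np.ndarray | None = None,
    card_reflectance_pct: float = 18.0,
    roi: MantleROI = MantleROI(),
) -> pd.DataFrame:
    """Full extraction: per-frame green-channel conversion, gray-card
    balancing, tracking, and mantle ROI averaging.

    Returns a DataFrame (t_s, x_cm, reflectance_pct, speed_cm_s); x is
    the tank coordinate of the tracked center, speeds are per-interval
    (first sample NaN).
    """
    centers = track_mantle(stack, hints)
    n = len(stack)
    t_s = np.arange(n) * stack.dt_s
    refl = np.full(n, np.nan)
    x_cm = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(centers[i]).any():
            continue
        g = to_single_channel(stack.frames[i])
        bal = balance_to_gray_card(g, stack.card_region, card_reflectance_pct)
        refl[i] = sample_mantle_reflectance(bal, tuple(centers[i]), roi)
        x_cm[i] = centers[i, 1] / stack.px_per_cm
    speed = np.full(n, np.nan)
    ok = ~np.isnan(x_cm)
    if ok.sum() >= 2:
        speed[1:] = np.abs(np.diff(x_cm)) / stack.dt_s
    return pd.DataFrame(
        {"t_s": t_s, "x_cm": x_cm, "reflectance_pct": refl, "speed_cm_s": speed}
    )


# --------------------------------------------------------------------------
# frame I/O (multi-page TIFF or numbered PNGs + JSON sidecar)
# --------------------------------------------------------------------------

def save_frames(stack: FrameStack, path: str | Path, fmt: str = "tiff") -> Path:
    """Write frames plus a JSON sidecar; returns the sidecar path."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        import tifffile

        img_path = path.with_suffix(".tiff")
        tifffile.imwrite(img_path, stack.frames)
        frame_files = [img_path.name]
    elif fmt == "png":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        frame_files = []
        for i, f in enumerate(stack.frames):
            name = f"frame_{i:05d}.png"
            iio.imwrite(path / name, f)
            frame_files.append(name)
        img_path = path
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    sidecar = {
        "dt_s": stack.dt_s,
        "px_per_cm": stack.px_per_cm,
        "card_region": list(stack.card_region),
        "hints": None if stack.hints is None else np.asarray(stack.hints).tolist(),
        "frames": frame_files,
        "format": fmt,
    }
    side_path = (path if fmt == "tiff" else path).with_suffix(".json")
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh)
    return side_path


def load_frames(sidecar_path: str | Path) -> FrameStack:
    """Load a frame stack written by :func:`save_frames`."""
    import json

    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    base = sidecar_path.parent
    if meta["format"] == "tiff":
        import tifffile

        frames = tifffile.imread(base / meta["frames"][0])
    else:
        import imageio.v3 as iio

        stem = sidecar_path.with_suffix("")
        frames = np.stack([iio.imread(stem / n) for n in meta["frames"]])
    hints = None if meta["hints"] is None else np.asarray(meta["hints"], dtype=float)
    return FrameStack(
        frames=frames,
        dt_s=meta["dt_s"],
        px_per_cm=meta["px_per_cm"],
        card_region=tuple(meta["card_region"]),
        hints=hints,
    )
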