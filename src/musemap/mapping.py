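"""Sliding-window metastasis mapping over mirror-padded whole images.

A classification window (default 256 px) is slid in fixed steps (default
10 px) across the image after mirror padding (default 128 px on all four
sides, so peripheral tumour regions survive the later majority voting).
Each window is optionally translated to the FFPE-like domain first, then
scored by the patch classifier; thresholded scores form a binary label map.

Grid-size convention: ``n = floor((L + 2*pad - window) / step)`` per axis —
the contract of the reference pipeline, which maps a 2592 x 2048 image with
window 256 / step 10 / pad 128 to a 259 x 204 grid.  The conventional
``+ 1`` (one extra window at the far edge) is available via
``inclusive_last_window``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import DecisionThreshold, PatchClassifier, normalize_clf
from .gan import TranslatorPair, translate_patches
from .synthetic import SyntheticImage


@dataclass(frozen=True)
class WindowConfig:
    window: int = 256
    step: int = 10
    pad: int = 128
    inclusive_last_window: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


@dataclass
class LabelMap:
    """Binary nh x nw grid of window verdicts (1 = metastasis-positive)."""

    grid: np.ndarray
    config: WindowConfig
    source_id: str = ""


def mirror_pad(image: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad on all four sides without duplicating the edge pixel."""
    image = np.asarray(image)
    if pad == 0:
        return image.copy()
    if pad >= min(image.shape[0], image.shape[1]):
        raise ValueError(f"pad {pad} must be smaller than image {image.shape[:2]}")
    widths = [(pad, pad), (pad, pad)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, widths, mode="reflect")


def map_dimensions(width: int, height: int,
                   cfg: WindowConfig = WindowConfig()) -> tuple[int, int]:
    """Label-map size (nw, nh) for an image of ``width`` x ``height``."""
    extra = 1 if cfg.inclusive_last_window else 0
    dims = []
    for length in (width, height):
        padded = length + 2 * cfg.pad
        if padded <= cfg.window:
            raise ValueError(
                f"padded length {padded} must exceed window {cfg.window}")
        n = (padded - cfg.window) // cfg.step + extra
        if n < 1:
            raise ValueError("degenerate geometry: no window positions")
        dims.append(n)
    return dims[0], dims[1]


def compute_label_map(image: SyntheticImage,
                      translator: TranslatorPair | None,
                      model: PatchClassifier,
                      t: DecisionThreshold,
                      cfg: WindowConfig = WindowConfig(),
                      chunk: int = 64) -> LabelMap:
    """Classify every window position into a binary metastasis grid.

    For grid cell (i, j) the window at (i*step, j*step) of the mirror-padded
    image is cropped; if a translator is given the window is first mapped to
    the FFPE-like domain (g_ab); the patch is then max-normalised and scored,
    and the cell is 1 iff score >= t.
    """
    nw, nh = map_dimensions(image.pixels.shape[1], image.pixels.shape[0], cfg)
    padded = mirror_pad(image.pixels, cfg.pad)
    s, w = cfg.step, cfg.window
    if translator is not None and image.domain != "unfixed":
        raise ValueError("translator expects an unfixed-domain image")
    grid = np.zeros((nh, nw), dtype=np.uint8)
    coords = [(i, j) for i in range(nh) for j in range(nw)]
    for start in range(0, len(coords), chunk):
        batch_coords = coords[start:start + chunk]
        windows = np.stack([
            padded[i * s:i * s + w, j * s:j * s + w] for i, j in batch_coords
        ]).astype(np.float32)
        if translator is not None:
            windows = translate_patches(translator.g_ab, windows, chunk=chunk)
        scores = model.decision_scores(windows)
        for (i, j), score in zip(batch_coords, scores):
            grid[i, j] = 1 if score >= t.value else 0
    return LabelMap(grid=grid, config=cfg, source_id=image.image_id)
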