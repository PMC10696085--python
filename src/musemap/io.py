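"""File I/O: 8-bit PNG/TIFF images, mask PNGs, CSV manifests, map sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .mapping import LabelMap, WindowConfig
from .synthetic import SyntheticImage
from .voting import VotedMap, VotingConfig


def save_image(image: SyntheticImage, path: Path) -> Path:
    """Write pixels as 8-bit RGB and the mask as a 0/255 sibling PNG."""
    path = Path(path)
    iio.imwrite(path, np.clip(image.pixels, 0, 255).astype(np.uint8))
    mask_path = path.with_name(path.stem + "_mask.png")
    iio.imwrite(mask_path, (image.mask * 255).astype(np.uint8))
    return path


def load_image(path: Path, domain: str, label: str | None = None) -> SyntheticImage:
    path = Path(path)
    pixels = iio.imread(path).astype(np.float32)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    mask_path = path.with_name(path.stem + "_mask.png")
    if mask_path.exists():
        mask = (iio.imread(mask_path) > 127).astype(np.uint8)
    else:
        mask = np.zeros(pixels.shape[:2], dtype=np.uint8)
    if label is None:
        label = "positive" if mask.any() else "negative"
    return SyntheticImage(pixels=pixels, domain=domain, label=label,
                          mask=mask, image_id=path.stem)


def write_manifest(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows, columns=["path", "domain", "label"]).to_csv(path, index=False)


def read_manifest(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_map(m: LabelMap | VotedMap, path: Path) -> None:
    """Binary grid as 0/255 PNG plus a JSON sidecar with its provenance."""
    path = Path(path)
    iio.imwrite(path, (m.grid * 255).astype(np.uint8))
    if isinstance(m, LabelMap):
        meta = {"kind": "label_map", "window": m.config.window,
                "step": m.config.step, "pad": m.config.pad,
                "source_id": m.source_id}
    else:
        meta = {"kind": "voted_map", "kernel": m.config.kernel,
                "vote_threshold": m.config.vote_threshold,
                "source_id": m.source_id}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_map(path: Path) -> LabelMap | VotedMap:
    path = Path(path)
    grid = (iio.imread(path) > 127).astype(np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["kind"] == "label_map":
        cfg = WindowConfig(window=meta["window"], step=meta["step"],
                           pad=meta["pad"])
        return LabelMap(grid=grid, config=cfg, source_id=meta["source_id"])
    cfg = VotingConfig(kernel=meta["kernel"],
                       vote_threshold=meta["vote_threshold"])
    return VotedMap(grid=grid, config=cfg, source_id=meta["source_id"])
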