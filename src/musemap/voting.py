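"""Majority-voting denoising of sliding-window label maps.

Sparse false-positive windows produce salt-noise in the label map; a k x k
voting kernel (k = ceil(window/step), i.e. the footprint of a point-like
region in map coordinates — 26 for window 256 / step 10) replaces each
block with a single verdict: positive iff the positive fraction reaches the
vote threshold (0.70–0.95).  Valid placement only, so the voted map shrinks
by k - 1 per axis and the image border is not mapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mapping import LabelMap


@dataclass(frozen=True)
class VotingConfig:
    kernel: int = 26
    vote_threshold: float = 0.95  # the voting ratio alpha; in (0.5, 1]
    strict: bool = False          # if True require count/k^2 > alpha, not >=

    def __post_init__(self) -> None:
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if not 0.5 < self.vote_threshold <= 1.0:
            raise ValueError(
                f"vote threshold must be in (0.5, 1], got {self.vote_threshold}")


@dataclass
class VotedMap:
    """Denoised binary grid, (nh-k+1) x (nw-k+1)."""

    grid: np.ndarray
    config: VotingConfig
    source_id: str = ""


def voting_kernel_size(window: int, step: int) -> int:
    """Map-space footprint of one window: ceil(window / step)."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    return math.ceil(window / step)


def majority_vote(label_map: LabelMap | np.ndarray,
                  cfg: VotingConfig = VotingConfig()) -> VotedMap:
    """Vote each k x k block of the label map into one output cell.

    Output cell (i, j) is 1 iff the fraction of positive cells in the block
    with top-left corner (i, j) reaches ``vote_threshold``.
    """
    if isinstance(label_map, LabelMap):
        grid, source = label_map.grid, label_map.source_id
    else:
        grid, source = np.asarray(label_map), ""
    k = cfg.kernel
    nh, nw = grid.shape
    if nh < k or nw < k:
        raise ValueError(f"map {nh}x{nw} smaller than kernel {k}")
    # exact block counts via a padded integral image
    integral = np.zeros((nh + 1, nw + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(grid.astype(np.int64), axis=0), axis=1)
    counts = (integral[k:, k:] - integral[:-k, k:]
              - integral[k:, :-k] + integral[:-k, :-k])
    frac = counts / float(k * k)
    voted = (frac > cfg.vote_threshold) if cfg.strict else (frac >= cfg.vote_threshold)
    return VotedMap(grid=voted.astype(np.uint8), config=cfg, source_id=source)
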