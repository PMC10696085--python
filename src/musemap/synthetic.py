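"""Two-domain synthetic MUSE-like image generator.

Emulates the two imaging domains of the diagnostic problem:

* **FFPE-like** ("clean") images: thin-section fluorescence appearance with
  dense, small, bright nuclei over dim cytoplasm.  Metastatic regions are
  gland-shaped — elliptical rings of larger nuclei around a dark lumen with
  broad cytoplasm, mimicking the low-nuclear-density / large-cytoplasm cue
  that separates carcinoma glands from lymphoid tissue.
* **Unfixed-like** ("degraded") images: derived from an FFPE-like image by
  optical blur, a smooth non-uniform additive fluorescence background (the
  out-of-focus haze of a thick, unsectioned specimen) and a global contrast
  reduction.

Every image carries a pixel-exact binary metastasis mask, so downstream
patch labelling, mapping and diagnosis are all testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic FFPE-like scene.

    Parameters
    ----------
    width, height:
        Image size in pixels (each >= 64).
    cancer_fraction:
        Target fraction of image area covered by metastatic glands, in [0, 1].
        Zero means a metastasis-negative image.
    n_glands:
        Number of elliptical glands used to reach ``cancer_fraction``.
    nucleus_density:
        Lymphoid nuclei per 100x100 px of non-gland tissue.
    rng_seed:
        Seed; identical spec (including seed) gives bit-identical output.
    """

    width: int = 648
    height: int = 512
    cancer_fraction: float = 0.0
    n_glands: int = 3
    nucleus_density: float = 110.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError(
                f"image must be at least 64x64, got {self.width}x{self.height}"
            )
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise ValueError(f"cancer_fraction must be in [0,1], got {self.cancer_fraction}")
        if self.n_glands < 0:
            raise ValueError("n_glands must be >= 0")


@dataclass(frozen=True)
class DegradeSpec:
    """Parameters of the unfixed-specimen degradation model.

    ``output = clip(contrast * blur(pixels, blur_sigma) + background, 0, 255)``
    where ``background`` is a smooth random field (sum of Gaussian bumps of
    scale ``bg_length_scale`` and peak height ~``bg_amplitude``).
    """

    blur_sigma: float = 1.2
    bg_amplitude: float = 60.0
    bg_length_scale: float = 48.0
    contrast: float = 0.55
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError(f"contrast must be in (0,1], got {self.contrast}")
        if self.bg_amplitude < 0:
            raise ValueError("bg_amplitude must be >= 0")
        if self.bg_length_scale <= 0:
            raise ValueError("bg_length_scale must be > 0")


@dataclass
class SyntheticImage:
    """An RGB image with its domain tag, image-level label and pixel mask."""

    pixels: np.ndarray  # H x W x 3 float array in [0, 255]
    domain: str  # "ffpe" | "unfixed"
    label: str  # "positive" | "negative"
    mask: np.ndarray  # H x W uint8 binary, 1 = metastatic
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("pixels and mask must share H x W")
        if self.domain not in ("ffpe", "unfixed"):
            raise ValueError(f"unknown domain {self.domain!r}")
        expected = "positive" if self.mask.any() else "negative"
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with mask (expected {expected!r})"
            )


@dataclass
class PatchDataset:
    """Patches cropped from source images with labels and origin coordinates."""

    patches: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.patches) == len(self.labels) == len(self.origins)):
            raise ValueError("patches, labels, origins must have equal length")
        sizes = {p.shape[:2] for p in self.patches}
        if len(sizes) > 1:
            raise ValueError(f"patches must share one size, got {sizes}")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_size(self) -> int | None:
        return self.patches[0].shape[0] if self.patches else None

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (N,S,S,3) float array and (N,) int array (1 = positive)."""
        x = np.stack(self.patches).astype(np.float32)
        y = np.array([1 if l == "positive" else 0 for l in self.labels])
        return x, y

    def extend(self, other: "PatchDataset") -> None:
        if self.patches and other.patches and self.patch_size != other.patch_size:
            raise ValueError("patch sizes differ")
        self.patches.extend(other.patches)
        self.labels.extend(other.labels)
        self.origins.extend(other.origins)


# fluorescence-like channel weights (cool nuclear stain over dim cytoplasm)
_NUCLEUS_RGB = np.array([0.55, 0.85, 1.0])
_CYTOPLASM_RGB = np.array([0.62, 0.78, 0.55])


def _stamp(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
           radius: float, amplitude: float, rng: np.random.Generator) -> None:
    """Add Gaussian blobs at integer centres (in place, monochrome canvas)."""
    h, w = canvas.shape
    r = int(np.ceil(3 * radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    blob = np.exp(-(yy ** 2 + xx ** 2) / (2.0 * radius ** 2))
    amps = amplitude * rng.uniform(0.7, 1.0, size=rows.size)
    for cy, cx, a in zip(rows, cols, amps):
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        by0, bx0 = max(0, -y0), max(0, -x0)
        by1 = blob.shape[0] - max(0, y1 - h)
        bx1 = blob.shape[1] - max(0, x1 - w)
        if by0 >= by1 or bx0 >= bx1:
            continue
        canvas[max(0, y0):min(h, y1), max(0, x0):min(w, x1)] += a * blob[by0:by1, bx0:bx1]


def _place_glands(spec: SceneSpec, rng: np.random.Generator
                  ) -> list[tuple[float, float, float, float, float]]:
    """Choose gland ellipses (cy, cx, ry, rx, theta) matching cancer_fraction.

    Glands are kept fully inside the frame and placed with limited mutual
    overlap (rejection sampling) so the realised mask fraction tracks the
    requested one.
    """
    if spec.cancer_fraction <= 0 or spec.n_glands == 0:
        return []
    area_per = spec.cancer_fraction * spec.width * spec.height / spec.n_glands
    glands: list[tuple[float, float, float, float, float]] = []
    for _ in range(spec.n_glands):
        ecc = rng.uniform(0.7, 1.0)
        rx = np.sqrt(area_per / (np.pi * ecc))
        ry = rx * ecc
        rmax = max(rx, ry)
        # shrink if the ellipse cannot fit inside the frame
        limit = 0.48 * min(spec.width, spec.height)
        if rmax > limit:
            scale = limit / rmax
            rx, ry, rmax = rx * scale, ry * scale, limit
        theta = rng.uniform(0, np.pi)
        best = None
        for _attempt in range(40):
            cy = rng.uniform(rmax, spec.height - rmax)
            cx = rng.uniform(rmax, spec.width - rmax)
            d_ok = all(
                np.hypot(cy - g[0], cx - g[1]) > 0.8 * (rmax + max(g[2], g[3]))
                for g in glands
            )
            if d_ok:
                best = (cy, cx, ry, rx, theta)
                break
            best = best or (cy, cx, ry, rx, theta)
        glands.append(best)
    return glands


def generate_ffpe_image(spec: SceneSpec) -> SyntheticImage:
    """Render a sharp FFPE-like scene with ground-truth metastasis mask."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width

    glands = _place_glands(spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, ry, rx, theta in glands:
        c, s = np.cos(theta), np.sin(theta)
        u = (yy - cy) * c - (xx - cx) * s
        v = (yy - cy) * s + (xx - cx) * c
        mask |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0

    # lymphoid field: dim cytoplasm + dense small bright nuclei outside glands
    lymphoid = np.full((h, w), 38.0)
    lymphoid += rng.normal(0, 4.0, size=(h, w))
    n_nuclei = int(spec.nucleus_density * h * w / 1e4)
    if n_nuclei:
        rows = rng.integers(0, h, size=n_nuclei)
        cols = rng.integers(0, w, size=n_nuclei)
        keep = ~mask[rows, cols]
        _stamp(lymphoid, rows[keep], cols[keep], radius=1.6, amplitude=170.0, rng=rng)

    # glandular field: dark lumen, broad mid-grey cytoplasm, ring of large nuclei
    glandular = np.full((h, w), 20.0)
    glandular += rng.normal(0, 3.0, size=(h, w))
    for cy, cx, ry, rx, theta in glands:
        c, s = np.cos(theta), np.sin(theta)
        u = (yy - cy) * c - (xx - cx) * s
        v = (yy - cy) * s + (xx - cx) * c
        rad = np.sqrt((u / ry) ** 2 + (v / rx) ** 2)
        inside = rad <= 1.0
        # broad cytoplasm band between lumen and boundary
        cyto = inside & (rad > 0.45)
        glandular[cyto] += 52.0
        # ring of large epithelial nuclei near the boundary
        rmean = 0.5 * (ry + rx)
        n_ring = max(8, int(2 * np.pi * rmean / 11.0))
        ang = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
        ru = 0.86 * ry * np.cos(ang)
        rv = 0.86 * rx * np.sin(ang)
        nr = np.round(cy + ru * c + rv * s).astype(int)
        nc = np.round(cx - ru * s + rv * c).astype(int)
        ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        _stamp(glandular, nr[ok], nc[ok], radius=3.1, amplitude=150.0, rng=rng)

    mono = np.where(mask, glandular, lymphoid)
    weight = np.where(mask, 1.0, 0.0)[..., None]
    rgb_w = weight * _CYTOPLASM_RGB * 0.9 + (1 - weight) * _CYTOPLASM_RGB
    base = mono[..., None] * np.where(mono[..., None] > 90.0, _NUCLEUS_RGB, rgb_w)
    pixels = np.clip(base, 0, 255)

    label = "positive" if mask.any() else "negative"
    return SyntheticImage(
        pixels=pixels.astype(np.float32),
        domain="ffpe",
        label=label,
        mask=mask.astype(np.uint8),
        image_id=f"ffpe-{spec.rng_seed}",
    )


def _background_field(pixels: np.ndarray, spec: DegradeSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Out-of-focus haze: heavily defocused tissue fluorescence.

    The background of a thick unfixed specimen is the fluorescence of
    tissue outside the focal plane, so the field is the image's own
    brightness smoothed at ``bg_length_scale``, normalised to peak at
    ``bg_amplitude``, with a gentle smooth random gain (0.75-1.0) standing
    in for the exogenous part of the non-uniformity (scattering, staining
    variation).  Being mostly content-derived, the haze is predictable
    from tissue context — which is what makes translation models able to
    remove and re-synthesise it.
    """
    h, w = pixels.shape[:2]
    if spec.bg_amplitude == 0:
        return np.zeros((h, w))
    brightness = pixels.mean(axis=2)
    defocus = ndimage.gaussian_filter(brightness, spec.bg_length_scale)
    top = np.percentile(defocus, 99)
    field = np.clip(defocus / top, 0, 1.2) if top > 0 else np.zeros((h, w))
    # smooth exogenous gain: a few broad random bumps rescaled into [0, 1]
    n_bumps = max(3, int(round(h * w / spec.bg_length_scale ** 2 / 8)))
    yy, xx = np.mgrid[0:h, 0:w]
    gain = np.zeros((h, w))
    two_s2 = 2.0 * (2 * spec.bg_length_scale) ** 2
    for cy, cx, a in zip(rng.uniform(0, h, n_bumps), rng.uniform(0, w, n_bumps),
                         rng.uniform(0.3, 1.0, n_bumps)):
        gain += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / two_s2)
    if gain.max() > gain.min():
        gain = (gain - gain.min()) / (gain.max() - gain.min())
    return spec.bg_amplitude * field * (0.75 + 0.25 * gain)


def degrade_to_unfixed(image: SyntheticImage, spec: DegradeSpec) -> SyntheticImage:
    """Derive the unfixed-specimen rendition of an FFPE-like image.

    Intensities only: the mask and label are copied unchanged.
    """
    if image.domain != "ffpe":
        raise ValueError(f"expected an ffpe-domain image, got {image.domain!r}")
    rng = np.random.default_rng(spec.rng_seed)
    px = image.pixels.astype(np.float64)
    if spec.blur_sigma > 0:
        px = ndimage.gaussian_filter(px, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    field = _background_field(px, spec, rng)
    out = np.clip(spec.contrast * px + field[..., None], 0, 255)
    return SyntheticImage(
        pixels=out.astype(np.float32),
        domain="unfixed",
        label=image.label,
        mask=image.mask.copy(),
        image_id=image.image_id.replace("ffpe", "unfixed") or "unfixed",
    )


def extract_patches(image: SyntheticImage, size: int, step: int,
                    label_threshold: float = 0.5) -> PatchDataset:
    """Crop a regular grid of S x S patches.

    A patch is labelled positive iff the fraction of mask-positive pixels it
    contains is >= ``label_threshold`` — a deterministic surrogate for the
    expert annotation used on real serial sections.
    """
    h, w = image.mask.shape
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image {h}x{w}")
    if step < 1:
        raise ValueError("step must be >= 1")
    # integral image for O(1) per-patch mask counts
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(image.mask, axis=0), axis=1)
    ds = PatchDataset()
    area = float(size * size)
    for r in range(0, h - size + 1, step):
        for c in range(0, w - size + 1, step):
            count = (integral[r + size, c + size] - integral[r, c + size]
                     - integral[r + size, c] + integral[r, c])
            ds.patches.append(np.asarray(image.pixels[r:r + size, c:c + size]))
            ds.labels.append("positive" if count / area >= label_threshold else "negative")
            ds.origins.append((r, c))
    return ds
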