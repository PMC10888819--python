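"""Synthetic serial histology with known artifacts and misalignments.

Sections are rendered from a smooth synthetic anatomy of nested, slowly
deforming elliptical shells so that every tissue label is spatially
contiguous and changes gradually along the cutting axis — the property the
registration and appearance stages rely on.  Three artifact classes are
injected: "tear" (pixels set to background white), "fold" (a local patch
duplicated with darkened values) and "stain shift" (hue rotated within a
region), alongside per-section rigid misalignments recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

from ..transforms import RigidTransform2D, image_center

BACKGROUND_RGB = (255, 255, 255)


class ConfigurationError(ValueError):
    """Raised when simulation parameters are out of their valid range."""


@dataclass
class HistologyConfig:
    n_sections: int = 10
    height: int = 256
    width: int = 256
    n_labels: int = 6            # tissue labels, excluding background 0
    tears_per_section: int = 1
    tear_size_px: int = 500
    folds_per_section: int = 0
    fold_size_px: int = 24       # side of the duplicated square patch
    stain_shifts_per_section: int = 0
    stain_region_px: int = 31    # diameter of the hue-rotated disc
    artifact_rate: float = 1.0   # probability each scheduled artifact is applied
    max_rotation_deg: float = 8.0
    max_translation_px: float = 6.0
    texture_sd: float = 6.0      # per-pixel RGB noise around label colours
    anatomy_drift: float = 0.03  # fractional shell-geometry change over stack

    def validate(self) -> None:
        if self.n_sections < 3:
            raise ConfigurationError("need at least 3 sections")
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("image size too small")
        if not (1 <= self.n_labels <= 20):
            raise ConfigurationError("label count must be in [1, 20]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        for name in ("tears_per_section", "folds_per_section",
                     "stain_shifts_per_section"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class InjectionRecord:
    section: int
    kind: str              # tear | fold | stain
    n_pixels: int          # pixels written by this artifact
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open


@dataclass
class SectionStackData:
    """Ordered sections: images (S, H, W, 3) uint8, labels (S, H, W) int."""
    images: np.ndarray
    labels: np.ndarray
    spacing_um: float = 20.0
    slice_spacing_um: float = 500.0

    @property
    def n_sections(self) -> int:
        return self.images.shape[0]


@dataclass
class HistologySimTruth:
    clean_stack: SectionStackData
    corrupted_stack: SectionStackData
    artifact_masks: np.ndarray           # (S, H, W) bool
    true_transforms: list[RigidTransform2D]
    injection_log: list[InjectionRecord] = field(default_factory=list)
    label_colors: np.ndarray | None = None


def _label_palette(n_labels: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct mid-range colours, violet-to-pink-ish like a Nissl stain."""
    hues = 0.55 + 0.3 * np.linspace(0, 1, n_labels)   # cyan to violet
    sats = rng.uniform(0.35, 0.7, n_labels)
    vals = np.linspace(0.45, 0.85, n_labels)
    hsv = np.stack([hues, sats, vals], axis=-1)[None]
    rgb = skcolor.hsv2rgb(hsv)[0] * 255.0
    return rgb


def _section_labels(cfg: HistologyConfig, s: int, rng_shape: np.random.Generator) -> np.ndarray:
    """Nested ellipse shells; parameters drift smoothly with section index."""
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    t = s / max(cfg.n_sections - 1, 1)
    # gentle drift of the shell geometry through the stack
    d = cfg.anatomy_drift
    ay = 0.30 * h * (1.0 + d * np.sin(1.5 * np.pi * t))
    ax = 0.40 * w * (1.0 + d * np.cos(1.2 * np.pi * t))
    tilt = 2.0 * d * np.sin(np.pi * t)
    dy, dx = (yy - cy) / ay, (xx - cx) / ax
    ry = dy * np.cos(tilt) + dx * np.sin(tilt)
    rx = dx * np.cos(tilt) - dy * np.sin(tilt)
    r = np.sqrt(ry ** 2 + rx ** 2)
    # fixed angular modulation breaks rotational symmetry so rigid
    # registration of sections is well posed
    phi = np.arctan2(ry, rx)
    r = r / (1.0 + 0.18 * np.cos(2.0 * phi + 0.5)
             + 0.10 * np.cos(3.0 * phi - 1.0))
    labels = np.zeros((h, w), dtype=np.int32)
    edges = np.linspace(1.0, 0.0, cfg.n_labels + 1)
    for k in range(cfg.n_labels):
        labels[r <= edges[k]] = k + 1
    return labels


def _render(labels: np.ndarray, palette: np.ndarray, texture_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    for k in range(palette.shape[0]):
        img[labels == k + 1] = palette[k]
    if texture_sd > 0:
        img = img + rng.normal(0.0, texture_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _place_rect(rng: np.random.Generator, tissue: np.ndarray,
                rh: int, rw: int) -> tuple[int, int] | None:
    """Top-left corner of an rh x rw rectangle fully inside the tissue."""
    h, w = tissue.shape
    for _ in range(200):
        r0 = rng.integers(1, max(h - rh - 1, 2))
        c0 = rng.integers(1, max(w - rw - 1, 2))
        if tissue[r0:r0 + rh, c0:c0 + rw].all():
            return int(r0), int(c0)
    return None


def _inject_artifacts(img: np.ndarray, labels: np.ndarray, cfg: HistologyConfig,
                      s: int, rng: np.random.Generator,
                      log: list[InjectionRecord]) -> tuple[np.ndarray, np.ndarray]:
    out = img.astype(float).copy()
    mask = np.zeros(labels.shape, dtype=bool)
    tissue = labels > 0

    # tears: thin strips of exactly tear_size_px pixels erased to white
    strip_h = max(int(round(np.sqrt(cfg.tear_size_px / 5.0))), 1)
    strip_w = int(np.ceil(cfg.tear_size_px / strip_h))
    for _ in range(cfg.tears_per_section):
        if rng.random() >= cfg.artifact_rate:
            continue
        pos = _place_rect(rng, tissue, strip_h, strip_w)
        if pos is None:
            continue
        r0, c0 = pos
        region = np.zeros_like(mask)
        region[r0:r0 + strip_h, c0:c0 + strip_w] = True
        # trim to the exact requested pixel count
        extra = region.sum() - cfg.tear_size_px
        if extra > 0:
            rr, cc = np.nonzero(region)
            region[rr[-extra:], cc[-extra:]] = False
        out[region] = BACKGROUND_RGB
        mask |= region
        log.append(InjectionRecord(s, "tear", int(region.sum()),
                                   (r0, c0, r0 + strip_h, c0 + strip_w)))

    # folds: duplicate a nearby patch, darkened, over the target square
    fs = cfg.fold_size_px
    for _ in range(cfg.folds_per_section):
        if rng.random() >= cfg.artifact_rate:
            continue
        pos = _place_rect(rng, tissue, fs, fs)
        if pos is None:
            continue
        r0, c0 = pos
        sr = np.clip(r0 + rng.integers(-fs, fs + 1), 0, labels.shape[0] - fs)
        sc = np.clip(c0 + rng.integers(-fs, fs + 1), 0, labels.shape[1] - fs)
        out[r0:r0 + fs, c0:c0 + fs] = 0.55 * out[sr:sr + fs, sc:sc + fs]
        mask[r0:r0 + fs, c0:c0 + fs] = True
        log.append(InjectionRecord(s, "fold", fs * fs, (r0, c0, r0 + fs, c0 + fs)))

    # stain shifts: rotate hue inside a disc
    rad = cfg.stain_region_px // 2
    for _ in range(cfg.stain_shifts_per_section):
        if rng.random() >= cfg.artifact_rate:
            continue
        pos = _place_rect(rng, tissue, 2 * rad + 1, 2 * rad + 1)
        if pos is None:
            continue
        r0, c0 = pos
        yy, xx = np.mgrid[0:2 * rad + 1, 0:2 * rad + 1]
        disc = (yy - rad) ** 2 + (xx - rad) ** 2 <= rad ** 2
        patch = out[r0:r0 + 2 * rad + 1, c0:c0 + 2 * rad + 1] / 255.0
        hsv = skcolor.rgb2hsv(patch)
        hsv[..., 0] = (hsv[..., 0] + 0.35) % 1.0
        shifted = skcolor.hsv2rgb(hsv) * 255.0
        patch_out = out[r0:r0 + 2 * rad + 1, c0:c0 + 2 * rad + 1]
        patch_out[disc] = shifted[disc]
        mask[r0:r0 + 2 * rad + 1, c0:c0 + 2 * rad + 1] |= disc
        log.append(InjectionRecord(s, "stain", int(disc.sum()),
                                   (r0, c0, r0 + 2 * rad + 1, c0 + 2 * rad + 1)))

    return np.clip(out, 0, 255).astype(np.uint8), mask


def gen_histology_stack(cfg: HistologyConfig, seed: int) -> HistologySimTruth:
    """Generate a clean stack plus a misaligned, artifact-corrupted copy.

    The corrupted stack is ``artifacts(transform(clean))``: each section is
    first displaced by a random rigid transform (recorded in
    ``true_transforms``; inverting it recovers clean geometry), then
    artifacts are injected and recorded in ``artifact_masks`` and the
    injection log.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    palette = _label_palette(cfg.n_labels, rng)

    clean_imgs, clean_lbls = [], []
    corr_imgs, corr_lbls = [], []
    masks, transforms = [], []
    log: list[InjectionRecord] = []

    for s in range(cfg.n_sections):
        labels = _section_labels(cfg, s, rng)
        img = _render(labels, palette, cfg.texture_sd, rng)
        clean_imgs.append(img)
        clean_lbls.append(labels)

        center = image_center(labels.shape)
        rot = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        tx = rng.uniform(-cfg.max_translation_px, cfg.max_translation_px)
        ty = rng.uniform(-cfg.max_translation_px, cfg.max_translation_px)
        tf = RigidTransform2D.from_params(rot, tx, ty, center)
        transforms.append(tf)

        moved_img = tf.apply_image(img, order=1, cval=255.0)
        moved_lbl = tf.apply_image(labels, order=0, cval=0)
        corr_img, mask = _inject_artifacts(moved_img, moved_lbl, cfg, s, rng, log)
        corr_imgs.append(corr_img)
        corr_lbls.append(moved_lbl)
        masks.append(mask)

    clean = SectionStackData(np.stack(clean_imgs), np.stack(clean_lbls))
    corrupted = SectionStackData(np.stack(corr_imgs), np.stack(corr_lbls))
    return HistologySimTruth(clean, corrupted, np.stack(masks), transforms,
                             log, palette)
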