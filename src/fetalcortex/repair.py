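"""Detect-and-repair of stained histological sections.

A label-conditioned appearance model predicts what each section should look
like from its anatomical annotation alone.  Pixels whose hue and saturation
deviate robustly from that prediction (median-absolute-deviation outlier
score above a threshold theta) are flagged as artifacts — tears, folds,
stain defects — and replaced with the prediction via Poisson image editing,
which matches gradients inside the mask while pinning boundary values to the
original, giving a seamless, intensity-matched repair.

The appearance model here is a parametric per-label Gaussian colour model
behind a pluggable synthesizer interface; any callable mapping a label patch
to an RGB patch can be substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from skimage import color as skcolor

from .synthetic.histology import ConfigurationError

logger = logging.getLogger(__name__)

MAD_FLOOR = 1e-6


@dataclass
class RepairConfig:
    """Tunable parameters of the detect-and-repair stage.

    ``theta`` is the robust z-score threshold on hue/saturation deviation:
    lowering it marks more pixels as outliers.  ``outlier_rule`` selects the
    formalisation of the thresholding rule: ``robust_z`` flags
    ``|d - median(d)| / MAD(d) > theta``; ``raw_gt_theta_mad`` flags raw
    differences exceeding ``theta * MAD``.
    """
    theta: float = 2.5
    blur_kernel: int = 5
    opening_width: int = 3
    opening_iterations: int = 3
    patch_size: int = 256
    patch_overlap: int = 8
    outlier_rule: str = "robust_z"

    def validate(self) -> None:
        if self.theta <= 0:
            raise ConfigurationError("theta must be > 0")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ConfigurationError("blur_kernel must be odd and >= 1")
        if self.patch_overlap >= self.patch_size:
            raise ConfigurationError("overlap must be smaller than patch size")
        if self.outlier_rule not in ("robust_z", "raw_gt_theta_mad"):
            raise ConfigurationError(f"unknown outlier_rule {self.outlier_rule!r}")


@dataclass
class LabelStats:
    mean: np.ndarray            # (3,) RGB
    cov: np.ndarray             # (3, 3)
    n_pixels: int


@dataclass
class AppearanceModel:
    """Per-label RGB colour statistics fitted from annotated sections."""
    stats: dict[int, LabelStats]
    global_stats: LabelStats
    errors: list[str] = field(default_factory=list)

    def get(self, label: int, fallback: bool = True) -> LabelStats:
        if label in self.stats:
            return self.stats[label]
        if fallback:
            return self.global_stats
        raise KeyError(f"label {label} not present in appearance model")


def fit_label_appearance(images: np.ndarray, labels: np.ndarray,
                         exclusion_masks: np.ndarray | None = None,
                         min_pixels: int = 100) -> AppearanceModel:
    """Fit per-label mean/covariance from non-excluded pixels.

    ``images``: (S, H, W, 3) uint8; ``labels``: (S, H, W) int;
    ``exclusion_masks``: (S, H, W) bool, True where pixels must be ignored
    (e.g. known artifacts).  Labels observed in fewer than ``min_pixels``
    valid pixels fall back to global statistics and are reported in
    ``errors``.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.ndim == 3:        # single section
        images, labels = images[None], labels[None]
        if exclusion_masks is not None:
            exclusion_masks = np.asarray(exclusion_masks)[None]
    valid = np.ones(labels.shape, dtype=bool)
    if exclusion_masks is not None:
        valid &= ~np.asarray(exclusion_masks, dtype=bool)

    pix = images[valid].reshape(-1, 3).astype(float)
    lab = labels[valid].ravel()
    gmean = pix.mean(axis=0)
    gcov = np.cov(pix.T) if len(pix) > 1 else np.zeros((3, 3))
    global_stats = LabelStats(gmean, np.atleast_2d(gcov), len(pix))

    stats: dict[int, LabelStats] = {}
    errors: list[str] = []
    for value in np.unique(lab):
        sel = pix[lab == value]
        if len(sel) < min_pixels:
            errors.append(f"label {int(value)}: only {len(sel)} pixels, "
                          "falling back to global statistics")
            continue
        cov = np.cov(sel.T) if len(sel) > 1 else np.zeros((3, 3))
        stats[int(value)] = LabelStats(sel.mean(axis=0), np.atleast_2d(cov),
                                       len(sel))
    return AppearanceModel(stats, global_stats, errors)


def synthesize_section(labels: np.ndarray, model: AppearanceModel, seed: int,
                       fallback: bool = True) -> np.ndarray:
    """Draw an RGB prediction for a label raster from the appearance model."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = np.zeros((*labels.shape, 3), dtype=float)
    # one normal draw per pixel, transformed per label via Cholesky so the
    # output is deterministic per seed and independent of label ordering
    z = rng.standard_normal((*labels.shape, 3))
    for value in np.unique(labels):
        st = model.get(int(value), fallback=fallback)
        cov = st.cov + 1e-12 * np.eye(3)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(cov)
            chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        sel = labels == value
        out[sel] = st.mean + z[sel] @ chol.T
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def tile_and_stitch(image: np.ndarray, cfg: RepairConfig, fn) -> np.ndarray:
    """Apply ``fn`` to overlapping patches and blend with linear feathering.

    Patches are ``patch_size`` squares with ``patch_overlap`` pixels shared
    between neighbours; overlapping outputs are combined with weights that
    ramp linearly across the overlap, so any ``fn`` acting identically on
    overlapping content stitches seamlessly.
    """
    cfg.validate()
    image = np.asarray(image)
    h, w = image.shape[:2]
    p, o = cfg.patch_size, cfg.patch_overlap
    step = p - o

    def starts(extent: int) -> list[int]:
        if extent <= p:
            return [0]
        s = list(range(0, extent - p, step))
        s.append(extent - p)
        return s

    # probe fn's output channel count on the first patch
    r0s, c0s = starts(h), starts(w)
    acc = None
    weight = np.zeros((h, w), dtype=float)

    ramp = np.ones(p)
    if o > 0:
        ramp[:o] = np.linspace(1.0 / (o + 1), 1.0, o, endpoint=False)
        ramp[-o:] = ramp[:o][::-1]
    for r0 in r0s:
        for c0 in c0s:
            r1, c1 = min(r0 + p, h), min(c0 + p, w)
            patch = image[r0:r1, c0:c1]
            ph, pw = patch.shape[:2]
            pad_h, pad_w = p - ph, p - pw
            if pad_h or pad_w:
                pads = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (patch.ndim - 2)
                patch = np.pad(patch, pads, mode="edge")
            out = np.asarray(fn(patch), dtype=float)[:ph, :pw]
            wr = ramp.copy()
            wc = ramp.copy()
            if r0 == 0:
                wr[:o] = 1.0
            if r1 == h:
                wr[-o if o else p:] = 1.0
            if c0 == 0:
                wc[:o] = 1.0
            if c1 == w:
                wc[-o if o else p:] = 1.0
            wpatch = np.outer(wr[:ph], wc[:pw])
            if acc is None:
                out_ch = out.shape[2:] if out.ndim > 2 else ()
                acc = np.zeros((h, w, *out_ch), dtype=float)
            if out.ndim > 2:
                acc[r0:r1, c0:c1] += out * wpatch[..., None]
            else:
                acc[r0:r1, c0:c1] += out * wpatch
            weight[r0:r1, c0:c1] += wpatch
    wview = weight[..., None] if acc.ndim > 2 else weight
    return acc / wview


def n_patches(extent: int, patch_size: int, overlap: int) -> int:
    """Number of tiles along one axis (tiling arithmetic helper)."""
    if extent <= patch_size:
        return 1
    return math.ceil((extent - overlap) / (patch_size - overlap))


def _circular_hue_distance(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    d = np.abs(h1 - h2)
    return np.minimum(d, 1.0 - d)


def _channel_outliers(d: np.ndarray, theta: float, rule: str) -> np.ndarray:
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    mad = max(mad, MAD_FLOOR)
    if rule == "robust_z":
        score = np.abs(d - med) / mad
        return score > theta
    return d > theta * mad


def detect_artifacts(original: np.ndarray, synthetic: np.ndarray,
                     cfg: RepairConfig) -> np.ndarray:
    """Flag pixels whose hue and saturation deviate robustly from prediction.

    Both rasters are converted to HSV (all channels in [0, 1]) and blurred
    with a box filter; hue differences use circular distance.  A pixel is an
    outlier when it exceeds ``theta`` on *both* hue and saturation; the
    joint mask is cleaned with a morphological opening (elliptical element).
    """
    cfg.validate()
    if original.shape != synthetic.shape:
        raise ValueError("original and synthetic shapes differ")
    hsv_o = skcolor.rgb2hsv(np.asarray(original, dtype=float) / 255.0)
    hsv_s = skcolor.rgb2hsv(np.asarray(synthetic, dtype=float) / 255.0)
    k = cfg.blur_kernel
    for arr in (hsv_o, hsv_s):
        for c in range(3):
            arr[..., c] = ndi.uniform_filter(arr[..., c], size=k)

    d_h = _circular_hue_distance(hsv_o[..., 0], hsv_s[..., 0])
    d_s = np.abs(hsv_o[..., 1] - hsv_s[..., 1])
    if (np.median(np.abs(d_h - np.median(d_h))) < MAD_FLOOR
            and np.median(np.abs(d_s - np.median(d_s))) < MAD_FLOOR
            and d_h.max() < MAD_FLOOR and d_s.max() < MAD_FLOOR):
        logger.warning("difference maps are flat; returning empty mask")
        return np.zeros(original.shape[:2], dtype=bool)

    flag_h = _channel_outliers(d_h, cfg.theta, cfg.outlier_rule)
    flag_s = _channel_outliers(d_s, cfg.theta, cfg.outlier_rule)
    mask = flag_h & flag_s

    if mask.any() and cfg.opening_iterations > 0:
        r = cfg.opening_width // 2
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        ellipse = (yy ** 2 + xx ** 2) <= r ** 2 + 1e-9
        mask = ndi.binary_opening(mask, structure=ellipse,
                                  iterations=cfg.opening_iterations)
    return mask


def robust_outlier_scores(d: np.ndarray) -> np.ndarray:
    """|d - median| / MAD with the MAD floored; exposed for auditing."""
    med = np.median(d)
    mad = max(np.median(np.abs(d - med)), MAD_FLOOR)
    return np.abs(d - med) / mad


def _solve_component(channel_o: np.ndarray, channel_s: np.ndarray,
                     comp: np.ndarray) -> np.ndarray:
    """Solve the discrete Poisson equation on one mask component.

    Laplacian(u) = Laplacian(synthetic) inside the component, u = original on
    the boundary (Dirichlet).  5-point stencil, sparse direct solve.
    """
    idx = -np.ones(comp.shape, dtype=int)
    rr, cc = np.nonzero(comp)
    idx[rr, cc] = np.arange(len(rr))
    n = len(rr)
    lap_s = (-4.0 * channel_s[rr, cc]
             + channel_s[rr - 1, cc] + channel_s[rr + 1, cc]
             + channel_s[rr, cc - 1] + channel_s[rr, cc + 1])
    rows, cols, vals = [], [], []
    b = lap_s.copy()
    for k, (r, c) in enumerate(zip(rr, cc)):
        rows.append(k); cols.append(k); vals.append(-4.0)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            j = idx[r + dr, c + dc]
            if j >= 0:
                rows.append(k); cols.append(j); vals.append(1.0)
            else:
                b[k] -= channel_o[r + dr, c + dc]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        x = spla.spsolve(A, b)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("non-finite Poisson solution")
    except Exception:
        logger.warning("Poisson system singular; falling back to direct "
                       "pixel replacement")
        x = channel_s[rr, cc]
    return x


def poisson_repair(original: np.ndarray, synthetic: np.ndarray,
                   mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by gradient-domain blending of the prediction.

    Outside the mask the output equals ``original`` exactly.  The mask's
    one-pixel image border is cleared so Dirichlet boundary data always
    exists.  Channels and mask connected components are solved
    independently.
    """
    original = np.asarray(original)
    mask = np.asarray(mask, dtype=bool).copy()
    if mask.shape != original.shape[:2]:
        raise ValueError("mask shape does not match image")
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        return original.copy()

    out = original.astype(float).copy()
    labeled, n_comp = ndi.label(mask)
    single = original.ndim == 2
    channels = 1 if single else original.shape[2]
    for comp_id in range(1, n_comp + 1):
        comp = labeled == comp_id
        rr, cc = np.nonzero(comp)
        for ch in range(channels):
            co = original[..., ch].astype(float) if not single else original.astype(float)
            cs = synthetic[..., ch].astype(float) if not single else synthetic.astype(float)
            x = _solve_component(co, cs, comp)
            if single:
                out[rr, cc] = x
            else:
                out[rr, cc, ch] = x
    out = np.clip(out, 0, 255)
    if np.issubdtype(original.dtype, np.integer):
        out = np.rint(out).astype(original.dtype)
    return out


def repair_section(image: np.ndarray, labels: np.ndarray,
                   model: AppearanceModel, cfg: RepairConfig,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Full single-section repair: synthesize, detect, Poisson-blend.

    Returns ``(repaired_image, artifact_mask)``; labels are never modified.
    """
    cfg.validate()

    def synth_patch(lbl_patch: np.ndarray) -> np.ndarray:
        return synthesize_section(lbl_patch.astype(int), model, seed)

    synthetic = tile_and_stitch(labels, cfg, synth_patch)
    synthetic = np.clip(synthetic, 0, 255).astype(np.uint8)
    mask = detect_artifacts(image, synthetic, cfg)
    repaired = poisson_repair(image, synthetic, mask)
    return repaired, mask
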