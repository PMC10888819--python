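"""Slice-to-volume reconstruction of serial sections.

Sections are brought into register by estimating pairwise rigid transforms
between nearby sections, building a directed graph of candidate transforms
pointing toward a reference section (the middle one by default), and
composing the Dijkstra shortest-cost chain of transforms for every section.
A prior-constrained affine refinement then registers each aligned slice to
the matching slice of a 3D shape reference, smoothing the affine parameters
along the stack axis to suppress the cumulative "z-shift" distortion
characteristic of serial-section reconstructions.

In situ hybridisation (ISH) sections, available only for a sparse subset of
planes, are projected into the reconstructed geometry via their nearest
stained section; missing planes are carried as explicitly flagged blanks
(NaN), never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize
from skimage import color as skcolor
from skimage import transform as sktf
from skimage.registration import phase_cross_correlation

from .transforms import RigidTransform2D, image_center

BACKGROUND_LEVEL = 0.95     # grayscale in [0,1] above this is background


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = skcolor.rgb2gray(image / 255.0 if image.max() > 1.5 else image)
    elif image.max() > 1.5:
        image = image / 255.0
    return image


def tissue_mask(gray: np.ndarray) -> np.ndarray:
    return gray < BACKGROUND_LEVEL


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation of two images over a pixel mask."""
    x, y = a[mask], b[mask]
    if len(x) < 2:
        return 0.0
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 1.0 if np.allclose(a[mask], b[mask]) else 0.0
    return float((x * y).sum() / denom)


def _ncc_for(moving: np.ndarray, fixed: np.ndarray, fixed_mask: np.ndarray,
             tf: RigidTransform2D) -> float:
    # NCC over the *fixed* tissue mask: background carried into the mask by
    # a bad warp is penalised, so the score cannot be gamed by shrinking
    # the overlap region
    warped = tf.apply_image(moving, order=1, cval=1.0)
    if not fixed_mask.any():
        return -1.0
    return masked_ncc(warped, fixed, fixed_mask)


def register_rigid_2d(moving: np.ndarray, fixed: np.ndarray,
                      max_rotation_deg: float = 15.0,
                      min_step_deg: float = 0.25
                      ) -> tuple[RigidTransform2D, float]:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Coarse-to-fine search: rotation candidates on a grid that halves from
    ``max_rotation_deg/4`` down to ``min_step_deg``; at each rotation the
    translation is proposed by phase correlation (integer pixels) and the
    candidate scored by NCC over the tissue overlap.  A final +/-2 px local
    grid refines the translation.  Returns ``(transform, cost)`` with
    ``cost = 1 - NCC`` in [0, 2].
    """
    mg, fg = _to_gray(moving), _to_gray(fixed)
    if mg.shape != fg.shape:
        raise ValueError("moving and fixed must share shape")
    fmask = tissue_mask(fg)
    if not fmask.any() or not tissue_mask(mg).any():
        raise ValueError("empty tissue mask")
    center = image_center(mg.shape)
    max_shift = 0.1 * mg.shape[1]

    def candidate(rot: float) -> tuple[RigidTransform2D, float]:
        rotated = RigidTransform2D.from_params(rot, 0, 0, center).apply_image(
            mg, order=1, cval=1.0)
        shift, _, _ = phase_cross_correlation(fg, rotated, normalization=None)
        dy, dx = float(np.clip(round(shift[0]), -max_shift, max_shift)), \
            float(np.clip(round(shift[1]), -max_shift, max_shift))
        tf = RigidTransform2D.from_params(rot, dx, dy, center)
        return tf, _ncc_for(mg, fg, fmask, tf)

    best_tf, best_ncc, best_rot = None, -np.inf, 0.0
    step = max_rotation_deg / 4.0
    rots = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, step)
    while True:
        for rot in rots:
            tf, ncc = candidate(float(rot))
            if ncc > best_ncc:
                best_tf, best_ncc, best_rot = tf, ncc, float(rot)
        if step <= min_step_deg:
            break
        step /= 2.0
        rots = best_rot + np.array([-step, step])

    # local translation polish to 1 px
    tx0, ty0 = best_tf.translation(center)
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            tf = RigidTransform2D.from_params(best_rot, tx0 + dx, ty0 + dy,
                                              center)
            ncc = _ncc_for(mg, fg, fmask, tf)
            if ncc > best_ncc:
                best_tf, best_ncc = tf, ncc
    return best_tf, float(1.0 - best_ncc)


@dataclass
class AlignmentGraph:
    n_sections: int
    reference: int
    edges: dict[tuple[int, int], tuple[RigidTransform2D, float]]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_sections))
        for (i, j), (_, cost) in self.edges.items():
            g.add_edge(i, j, weight=cost)
        return g


def neighbor_pairs(n_sections: int, k: int, reference: int
                   ) -> list[tuple[int, int]]:
    """Directed (i, j) pairs with |i-j| <= k and j strictly nearer reference."""
    pairs = []
    for i in range(n_sections):
        if i == reference:
            continue
        direction = 1 if i < reference else -1
        for d in range(1, k + 1):
            j = i + direction * d
            if (direction == 1 and j <= reference) or \
               (direction == -1 and j >= reference):
                pairs.append((i, j))
    return pairs


def build_alignment_graph(images: np.ndarray, k: int = 2,
                          reference: int | None = None) -> AlignmentGraph:
    """Register each section to its up-to-k neighbours toward the reference."""
    if k < 1:
        raise ValueError("neighborhood radius k must be >= 1")
    n = len(images)
    if reference is None:
        reference = n // 2
    edges = {}
    for i, j in neighbor_pairs(n, k, reference):
        tf, cost = register_rigid_2d(images[i], images[j])
        edges[(i, j)] = (tf, cost)
    g = AlignmentGraph(n, reference, edges)
    unreachable = [i for i in range(n)
                   if not nx.has_path(g.graph(), i, reference)]
    if unreachable:
        raise ValueError(f"sections unreachable from reference: {unreachable}")
    return g


def shortest_path_transforms(graph: AlignmentGraph) -> list[RigidTransform2D]:
    """Compose the lowest-cost chain of pairwise transforms per section."""
    g = graph.graph()
    out: list[RigidTransform2D] = []
    for i in range(graph.n_sections):
        if i == graph.reference:
            out.append(RigidTransform2D.identity())
            continue
        path = nx.dijkstra_path(g, i, graph.reference, weight="weight")
        tf = RigidTransform2D.identity()
        for a, b in zip(path[:-1], path[1:]):
            step, _ = graph.edges[(a, b)]
            tf = step @ tf           # apply earlier steps first
        out.append(tf)
    return out


def apply_transforms(images: np.ndarray, labels: np.ndarray | None,
                     transforms: list[RigidTransform2D],
                     background: float = 255.0
                     ) -> tuple[np.ndarray, np.ndarray | None]:
    """Warp images (bilinear) and labels (nearest) by per-section transforms."""
    if len(transforms) != len(images):
        raise ValueError("one transform per section required")
    imgs = np.stack([tf.apply_image(im, order=1, cval=background)
                     for im, tf in zip(images, transforms)])
    lbls = None
    if labels is not None:
        lbls = np.stack([tf.apply_image(lb, order=0, cval=0)
                         for lb, tf in zip(labels, transforms)])
    return imgs, lbls


# ---------------------------------------------------------------------------
# prior-constrained affine refinement

def _affine_from_params(p: np.ndarray, center: tuple[float, float]
                        ) -> sktf.AffineTransform:
    sx, sy, rot, shear, tx, ty = p
    cx, cy = center
    t = sktf.AffineTransform(scale=(sx, sy), rotation=rot, shear=shear)
    shift = sktf.AffineTransform(translation=(-cx, -cy))
    unshift = sktf.AffineTransform(translation=(cx + tx, cy + ty))
    return sktf.AffineTransform(matrix=unshift.params @ t.params @ shift.params)


IDENTITY_AFFINE = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])


def _register_affine(moving: np.ndarray, fixed: np.ndarray
                     ) -> tuple[np.ndarray, float]:
    """6-parameter affine registration by rigid seeding + Powell refinement."""
    mg, fg = _to_gray(moving), _to_gray(fixed)
    fmask = tissue_mask(fg)
    # light blur widens the NCC basin and suppresses texture-noise plateaus
    mg = ndi.gaussian_filter(mg, 2.0)
    fg = ndi.gaussian_filter(fg, 2.0)
    center = image_center(mg.shape)

    def cost(p: np.ndarray) -> float:
        tf = _affine_from_params(p, center)
        warped = sktf.warp(mg, tf.inverse, order=1, cval=1.0,
                           preserve_range=True)
        if not fmask.any():
            return 2.0
        return 1.0 - masked_ncc(warped, fg, fmask)

    if cost(IDENTITY_AFFINE) < 1e-6:    # already perfectly registered
        return IDENTITY_AFFINE.copy(), float(cost(IDENTITY_AFFINE))
    # seed: coarse isotropic-scale grid, each with a rigid search on top
    best_x0, best_c = None, np.inf
    for s in np.geomspace(0.85, 1.18, 9):
        pre = _affine_from_params(np.array([s, s, 0, 0, 0, 0]), center)
        pre_img = sktf.warp(mg, pre.inverse, order=1, cval=1.0,
                            preserve_range=True)
        try:
            rigid, _ = register_rigid_2d(pre_img, fg, max_rotation_deg=12.0,
                                         min_step_deg=0.5)
        except ValueError:
            continue
        tx, ty = rigid.translation(center)
        x = np.array([s, s, np.deg2rad(rigid.rotation_deg), 0.0, tx, ty])
        c = cost(x)
        if c < best_c:
            best_x0, best_c = x, c
    x0 = best_x0 if best_x0 is not None else IDENTITY_AFFINE.copy()
    # optimise in units where a step means a comparable image displacement
    scale = np.array([0.02, 0.02, 0.02, 0.02, 2.0, 2.0])
    res = minimize(lambda u: cost(x0 + u * scale), np.zeros(6),
                   method="Powell",
                   options={"maxiter": 400, "xtol": 1e-3, "ftol": 1e-7})
    c_id = cost(IDENTITY_AFFINE)
    if c_id <= res.fun + 1e-4:      # keep identity unless clearly better
        return IDENTITY_AFFINE.copy(), float(c_id)
    return x0 + res.x * scale, float(res.fun)


def _moving_median(params: np.ndarray, window: int = 5) -> np.ndarray:
    out = np.empty_like(params)
    n = len(params)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(params[lo:hi], axis=0)
    return out


@dataclass
class AffineRefinementResult:
    images: np.ndarray
    labels: np.ndarray | None
    params: np.ndarray              # (S, 6) final composed per-slice params
    cost_history: list[float] = field(default_factory=list)


def shape_prior_affine(images: np.ndarray, labels: np.ndarray | None,
                       prior: np.ndarray, iterations: int = 5,
                       median_window: int = 5) -> AffineRefinementResult:
    """Iteratively register each slice to its prior slice with z-smoothing.

    Each iteration registers every slice to the matching slice of the shape
    prior with a 6-parameter affine, then smooths the six parameters along
    the stack axis with a moving median to suppress slice-to-slice jitter
    (z-shift), and applies the smoothed transforms.
    """
    if len(prior) != len(images):
        raise ValueError("prior and stack slice counts differ")
    cur = np.asarray(images, dtype=float)
    cur_lbl = None if labels is None else np.asarray(labels)
    n = len(cur)
    center = image_center(cur[0].shape)
    composed = np.tile(IDENTITY_AFFINE, (n, 1))
    costs: list[float] = []

    for _ in range(iterations):
        params = np.empty((n, 6))
        iter_costs = []
        for s in range(n):
            p, c = _register_affine(cur[s], prior[s])
            params[s] = p
            iter_costs.append(c)
        costs.append(float(np.mean(iter_costs)))
        params = _moving_median(params, median_window)
        new_imgs, new_lbls = [], []
        for s in range(n):
            tf = _affine_from_params(params[s], center)
            new_imgs.append(sktf.warp(cur[s], tf.inverse, order=1, cval=255.0
                                      if cur[s].max() > 1.5 else 1.0,
                                      preserve_range=True))
            if cur_lbl is not None:
                new_lbls.append(np.rint(sktf.warp(
                    cur_lbl[s].astype(float), tf.inverse, order=0, cval=0,
                    preserve_range=True)).astype(cur_lbl.dtype))
        cur = np.stack(new_imgs)
        if cur_lbl is not None:
            cur_lbl = np.stack(new_lbls)
        # track the composition through parameter concatenation of matrices
        for s in range(n):
            m_new = _affine_from_params(params[s], center).params
            m_old = _affine_from_params(composed[s], center).params
            m = m_new @ m_old
            tf = sktf.AffineTransform(matrix=m)
            # decompose about center
            shift = sktf.AffineTransform(translation=(-center[0], -center[1]))
            unshift = sktf.AffineTransform(translation=center)
            core = sktf.AffineTransform(
                matrix=shift.params @ m @ unshift.params)
            composed[s] = [core.scale[0], core.scale[1], core.rotation,
                           core.shear, core.translation[0],
                           core.translation[1]]
    return AffineRefinementResult(cur, cur_lbl, composed, costs)


# ---------------------------------------------------------------------------
# ISH projection and regional means

def project_ish(ish_sections: list[tuple[int, np.ndarray]],
                aligned_images: np.ndarray,
                transforms: list[RigidTransform2D]) -> tuple[np.ndarray, np.ndarray]:
    """Project sparse ISH sections into the aligned stack geometry.

    Each entry of ``ish_sections`` is ``(nissl_index, rgb_or_intensity)``;
    the red channel is extracted, affine-registered to the (unaligned
    geometry of the) named stained section, then carried into stack space by
    that section's composed transform.  Returns ``(volume, present)`` where
    ``volume`` is (S, H, W) with NaN in absent planes and ``present`` is a
    per-plane boolean vector.
    """
    n, h, w = aligned_images.shape[:3]
    volume = np.full((n, h, w), np.nan)
    present = np.zeros(n, dtype=bool)
    center = image_center((h, w))
    for index, raster in ish_sections:
        if not 0 <= index < n:
            raise ValueError(f"ISH section names index {index} outside stack")
        raster = np.asarray(raster, dtype=float)
        red = raster[..., 0] if raster.ndim == 3 else raster
        if red.max() > 1.5:
            red = red / 255.0
        # register against the aligned stained section brought back to the
        # section's native geometry
        native = transforms[index].inverse().apply_image(
            aligned_images[index], order=1, cval=255.0)
        fixed = native[..., 0] if native.ndim == 3 else native
        p, _ = _register_affine(red, fixed)
        tf = _affine_from_params(p, center)
        moved = sktf.warp(red, tf.inverse, order=1, cval=np.nan,
                          preserve_range=True)
        moved = transforms[index].apply_image(
            np.nan_to_num(moved, nan=0.0), order=1, cval=0.0)
        volume[index] = moved
        present[index] = True
    return volume, present


def regional_ish_means(ish_volume: np.ndarray, present: np.ndarray,
                       label_volume: np.ndarray):
    """Mean ISH intensity per labelled structure over available planes."""
    import pandas as pd
    rows = []
    for value in np.unique(label_volume):
        if value == 0:
            continue
        total, count, n_sections = 0.0, 0, 0
        for s in range(len(ish_volume)):
            if not present[s]:
                continue
            sel = label_volume[s] == value
            vals = ish_volume[s][sel]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                total += float(vals.sum())
                count += len(vals)
                n_sections += 1
        if count == 0:
            rows.append({"structure": int(value), "mean_intensity": np.nan,
                         "n_sections": 0})
        else:
            rows.append({"structure": int(value),
                         "mean_intensity": total / count,
                         "n_sections": n_sections})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# volume export

def stack_to_volume(images: np.ndarray, spacing_um: float,
                    slice_spacing_um: float, voxel_um: float = 150.0
                    ) -> np.ndarray:
    """Resample a section stack to an isotropic-voxel 3D volume."""
    factors = (slice_spacing_um / voxel_um, spacing_um / voxel_um,
               spacing_um / voxel_um)
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 4:       # RGB -> grayscale for the volume
        arr = arr.mean(axis=-1)
    return ndi.zoom(arr, factors, order=1)


def volume_extent_mm(n_voxels: int, voxel_um: float = 150.0) -> float:
    """Physical extent of an axis: voxel count times isotropic voxel size."""
    return n_voxels * voxel_um / 1000.0


def save_volume_nifti(volume: np.ndarray, voxel_um: float, path) -> None:
    import nibabel as nib
    from pathlib import Path
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    vox_mm = voxel_um / 1000.0
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))
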