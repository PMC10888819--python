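"""File I/O for the pipeline's on-disk interchange formats.

Sections are PNG (RGB) with single-channel PNG label maps; stacks and
volumes are NIfTI; expression, metadata, vertex metrics and result tables
are TSV; gene sets are GMT (see :mod:`fetalcortex.synthetic.annotations`).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml


def save_sections(images: np.ndarray, labels: np.ndarray | None,
                  out_dir, prefix: str = "section") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(images):
        iio.imwrite(out / f"{prefix}_{i:03d}.png", np.asarray(img, np.uint8))
    if labels is not None:
        for i, lbl in enumerate(labels):
            iio.imwrite(out / f"{prefix}_{i:03d}_labels.png",
                        np.asarray(lbl, np.uint8))


def load_sections(section_dir, label_dir=None
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    sdir = Path(section_dir)
    paths = sorted(p for p in sdir.glob("*.png")
                   if not p.stem.endswith("_labels"))
    images = np.stack([iio.imread(p) for p in paths])
    labels = None
    ldir = Path(label_dir) if label_dir else sdir
    lpaths = sorted(ldir.glob("*_labels.png"))
    if lpaths:
        labels = np.stack([iio.imread(p).astype(np.int32) for p in lpaths])
    return images, labels


def save_masks(masks: np.ndarray, out_dir, prefix: str = "mask") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(masks):
        iio.imwrite(out / f"{prefix}_{i:03d}.png",
                    (np.asarray(m, bool) * 255).astype(np.uint8))


def save_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_mesh_ply(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    import trimesh
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


def load_mesh_ply(path) -> tuple[np.ndarray, np.ndarray]:
    import trimesh
    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
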