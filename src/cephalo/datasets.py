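"""On-disk dataset layout: PNG images + imglab XML + landmark CSV + meta JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple

import imageio.v3 as iio
import numpy as np

from .annotations import read_landmark_csv, write_imglab_xml, write_landmark_csv
from .core import CropTransform, ImageSpace, LandmarkScheme, LandmarkSet
from .synthetic import SyntheticDataset


def save_dataset(ds: SyntheticDataset, outdir) -> Path:
    """Write a rendered dataset as PNGs + annotations; returns the directory."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(ds.n):
        name = f"images/img{i:04d}.png"
        img8 = np.clip(ds.images[i] / 1.5 * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(outdir / name, img8)
        entries.append((name, ds.gt[i]))
    write_imglab_xml(outdir / "annotations.xml", entries)
    write_landmark_csv(outdir / "annotations.csv", entries)
    space = ds.gt[0].space
    meta = {
        "n": ds.n,
        "input_side": ds.input_side,
        "template_side": space.width_px,
        "mm_per_px": space.mm_per_px,
        "crop_scale": ds.crop.scale,
        "crop_x0": ds.crop.x0,
        "crop_y0": ds.crop.y0,
        "seed": ds.seed,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_dataset(path) -> SyntheticDataset:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    space = ImageSpace(meta["template_side"], meta["template_side"], meta["mm_per_px"])
    crop = CropTransform(scale=meta["crop_scale"], x0=meta["crop_x0"], y0=meta["crop_y0"])
    entries = read_landmark_csv(path / "annotations.csv", space=space, role="ground_truth")
    images = []
    gt: List[LandmarkSet] = []
    for name, ls in entries:
        img = np.asarray(iio.imread(path / name), dtype=float) / 255.0 * 1.5
        images.append(img)
        gt.append(ls)
    return SyntheticDataset(
        images=np.stack(images),
        gt=gt,
        crop=crop,
        input_side=meta["input_side"],
        seed=meta.get("seed", 0),
    )
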