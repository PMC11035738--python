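"""Dataset and heatmap file I/O.

On-disk dataset layout (all plain formats):

    <dir>/manifest.csv           path, identity, split  (one row per image)
    <dir>/images/<name>.png      16-bit grayscale render
    <dir>/images/<name>.json     keypoint sidecar {feature: [[x, y], ...]},
                                 0-based pixel coordinates, x = column

Renders are written as 16-bit grayscale PNG so that quantization
(1/65535 per pixel) is far below the generator's noise floor; externally
supplied 8-bit PNGs load transparently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import FaceSample, SplitDataset


def _sample_name(sample: FaceSample, index: int) -> str:
    return f"id{sample.identity_id:04d}_im{index:04d}"


def save_dataset(dataset: SplitDataset, outdir) -> Path:
    """Write PNGs, keypoint sidecars, and the manifest; returns manifest path."""
    outdir = Path(outdir)
    imgdir = outdir / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[int, int] = {}
    for s in dataset.samples:
        idx = counters.get(s.identity_id, 0)
        counters[s.identity_id] = idx + 1
        name = _sample_name(s, idx)
        arr = np.clip(np.round(s.image.astype(np.float64) * 65535.0),
                      0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(imgdir / f"{name}.png")
        with open(imgdir / f"{name}.json", "w") as fh:
            json.dump({f: [list(p) for p in pts]
                       for f, pts in s.keypoints.items()}, fh)
        rows.append({"path": f"images/{name}.png",
                     "identity": s.identity_id, "split": s.split_tag})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(directory) -> SplitDataset:
    """Read a dataset written by :func:`save_dataset` (or the same layout)."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest)
    samples = []
    for row in df.itertuples():
        png = directory / row.path
        try:
            raw = np.asarray(Image.open(png))
        except Exception as exc:
            raise IOError(f"could not read image {png}: {exc}") from exc
        if raw.ndim == 3:  # externally supplied color image
            raw = raw.mean(axis=2)
        full = 65535.0 if raw.dtype.itemsize > 1 else 255.0
        img = (raw.astype(np.float32) / full)
        with open(png.with_suffix(".json")) as fh:
            kp = {f: [tuple(p) for p in pts] for f, pts in json.load(fh).items()}
        samples.append(FaceSample(image=img, identity_id=int(row.identity),
                                  keypoints=kp, split_tag=str(row.split)))
    n_ident = len({s.identity_id for s in samples})
    return SplitDataset(samples=samples, n_identities=n_ident)


def export_heatmap(heatmap, sample: FaceSample, path_base) -> None:
    """Write a heatmap as an overlay PNG and an auditable CSV grid."""
    path_base = Path(path_base)
    np.savetxt(path_base.with_suffix(".csv"), heatmap.grid,
               delimiter=",", fmt="%.3f")
    gray = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    heat = np.clip(np.round(heatmap.grid), 0, 255).astype(np.uint8)
    rgb = np.stack([np.maximum(gray, heat), gray, gray], axis=-1)
    Image.fromarray(rgb, mode="RGB").save(path_base.with_suffix(".png"))
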