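"""Bi-temporal change-detection dataset I/O, tiling and augmentation.

Datasets live on disk in the common A/B/label layout::

    root/<split>/A/<id>.png       image at time T1
    root/<split>/B/<id>.png       image at time T2
    root/<split>/label/<id>.png   binary change mask (0 / 255 in 8-bit)

Images are read as 8-bit RGB and scaled to [0, 1]; labels are binarized at
>127.  Geometric augmentation applies the *same* transform to T1, T2 and the
mask, drawn independently per transform at the configured probability
(rotation p=0.15 as a right-angle rotation, vertical flip p=0.3, horizontal
flip p=0.5).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .config import AugmentPolicy

SPLITS = ("train", "val", "test")
_SUBDIRS = ("A", "B", "label")
_EXTS = (".png", ".tif", ".tiff")


@dataclass
class BiTemporalSample:
    """One co-registered image pair plus binary change mask."""

    id: str
    t1: np.ndarray      # (H, W, 3) uint8 or float
    t2: np.ndarray      # (H, W, 3)
    mask: np.ndarray    # (H, W) in {0, 1}

    def validate(self) -> None:
        if self.t1.shape != self.t2.shape:
            raise ValueError(
                f"sample {self.id}: t1 {self.t1.shape} != t2 {self.t2.shape}")
        if self.mask.shape != self.t1.shape[:2]:
            raise ValueError(
                f"sample {self.id}: mask {self.mask.shape} does not match "
                f"images {self.t1.shape[:2]}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError(f"sample {self.id}: mask is not binary")


def _read_image(path: str) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _read_mask(path: str) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def _index_dir(d: str) -> dict:
    out = {}
    for name in sorted(os.listdir(d)):
        stem, ext = os.path.splitext(name)
        if ext.lower() in _EXTS:
            out[stem] = os.path.join(d, name)
    return out


def load_dataset(root: str, split: str) -> list[BiTemporalSample]:
    """Load all matched (A, B, label) triples of one split, sorted by id."""
    if split not in SPLITS:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    base = os.path.join(root, split)
    dirs = {}
    for sub in _SUBDIRS:
        d = os.path.join(base, sub)
        if not os.path.isdir(d):
            raise FileNotFoundError(f"missing directory {d}")
        dirs[sub] = _index_dir(d)
    ids = sorted(set().union(*[set(v) for v in dirs.values()]))
    samples = []
    for sid in ids:
        for sub in _SUBDIRS:
            if sid not in dirs[sub]:
                raise FileNotFoundError(
                    f"sample {sid!r}: no counterpart in {split}/{sub}")
        s = BiTemporalSample(
            id=sid,
            t1=_read_image(dirs["A"][sid]),
            t2=_read_image(dirs["B"][sid]),
            mask=_read_mask(dirs["label"][sid]),
        )
        s.validate()
        samples.append(s)
    return samples


def save_sample(root: str, split: str, sample: BiTemporalSample) -> None:
    """Write one triple into the A/B/label layout as 8-bit PNG."""
    for sub, arr in (("A", sample.t1), ("B", sample.t2),
                     ("label", sample.mask * 255)):
        d = os.path.join(root, split, sub)
        os.makedirs(d, exist_ok=True)
        img = np.asarray(arr, dtype=np.uint8)
        Image.fromarray(img).save(os.path.join(d, f"{sample.id}.png"))


def write_manifest(root: str, samples_by_split: dict) -> str:
    """Tab-delimited manifest (id, split, relative paths) next to the data."""
    path = os.path.join(root, "manifest.tsv")
    with open(path, "w") as fh:
        fh.write("id\tsplit\tA\tB\tlabel\n")
        for split, samples in samples_by_split.items():
            for s in samples:
                fh.write(f"{s.id}\t{split}\t{split}/A/{s.id}.png\t"
                         f"{split}/B/{s.id}.png\t{split}/label/{s.id}.png\n")
    return path


def tile_pair(t1: np.ndarray, t2: np.ndarray, mask: np.ndarray,
              size: int, prefix: str = "tile") -> list[BiTemporalSample]:
    """Cut non-overlapping ``size`` x ``size`` tiles in row-major order.

    Remainder rows/columns that do not fill a tile are dropped.  Tile ids
    encode the grid position as ``<prefix>_r<i>_c<j>``.
    """
    h, w = mask.shape[:2]
    if size > h or size > w:
        raise ValueError(f"tile size {size} exceeds image extent {(h, w)}")
    tiles = []
    for i in range(h // size):
        for j in range(w // size):
            sl = (slice(i * size, (i + 1) * size),
                  slice(j * size, (j + 1) * size))
            tiles.append(BiTemporalSample(
                id=f"{prefix}_r{i}_c{j}",
                t1=t1[sl], t2=t2[sl], mask=mask[sl]))
    return tiles


def augment(sample: BiTemporalSample, policy: AugmentPolicy,
            rng: np.random.Generator) -> BiTemporalSample:
    """Jointly transform (t1, t2, mask) under the stochastic policy.

    Each transform is drawn independently; rotation is a right-angle
    rotation (90/180/270, uniform) so masks need no resampling.
    """
    policy.validate()
    t1, t2, mask = sample.t1, sample.t2, sample.mask
    if rng.random() < policy.p_rot:
        k = int(rng.integers(1, 4))
        t1, t2 = np.rot90(t1, k, (0, 1)), np.rot90(t2, k, (0, 1))
        mask = np.rot90(mask, k, (0, 1))
    if rng.random() < policy.p_vflip:
        t1, t2, mask = t1[::-1], t2[::-1], mask[::-1]
    if rng.random() < policy.p_hflip:
        t1, t2, mask = t1[:, ::-1], t2[:, ::-1], mask[:, ::-1]
    return BiTemporalSample(sample.id, np.ascontiguousarray(t1),
                            np.ascontiguousarray(t2),
                            np.ascontiguousarray(mask))


def normalize(image: np.ndarray, mean, std) -> np.ndarray:
    """8-bit (H, W, 3) image -> normalized (3, H, W) float32."""
    x = np.asarray(image, np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    x = (x - np.asarray(mean, np.float32)) / np.asarray(std, np.float32)
    return np.ascontiguousarray(x.transpose(2, 0, 1))
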