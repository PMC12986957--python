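"""Synthetic bi-temporal intertidal scenes.

Each scene is built from a smooth random height field.  Pixels below the
epoch's tide level render as water (blue-grey palette with specular
speckle), so two epochs with different tide levels show large water-extent
differences that are *pseudo-change*: visually dramatic, ecologically
meaningless, and absent from the ground-truth mask.  Mangrove stands are
smooth random polygons with green-textured fill placed on high ground; a
configurable fraction of them exists in exactly one epoch (appearance or
disappearance), and only those pixels are labeled as change.  Independent
illumination noise is added per epoch.

This reproduces the class structure that motivates difference-guided fusion:
with the defaults, unlabeled differing pixels outnumber labeled changed
pixels by well over 2:1, so naive image differencing fails while the labeled
change stays a small (5-20 %) minority class.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .data import BiTemporalSample, save_sample, write_manifest

# palette anchors (RGB in [0,1]); water-vs-mud contrast is deliberately at
# least as strong as canopy-vs-mud contrast so that no single difference
# threshold can separate tidal pseudo-change from genuine vegetation change
_MUD_LOW = np.array([0.52, 0.42, 0.30])
_MUD_HIGH = np.array([0.64, 0.56, 0.42])
_WATER_DEEP = np.array([0.08, 0.14, 0.26])
_WATER_SHALLOW = np.array([0.16, 0.26, 0.42])
_CANOPY = np.array([0.16, 0.38, 0.22])
_ALGAE = np.array([0.22, 0.40, 0.24])


class GenerationError(RuntimeError):
    """Raised when stand placement cannot be satisfied."""


@dataclass
class SceneParams:
    size: int = 256
    n_blobs: int = 6
    tide_t1: float = 0.35
    tide_t2: float = 0.55
    change_rate: float = 0.3
    noise_sd: float = 0.03
    seed: int = 0
    blob_radius: tuple = (0.08, 0.14)   # fraction of tile edge
    max_retries: int = 600

    def validate(self) -> None:
        if self.size % 32:
            raise ValueError(f"size {self.size} not divisible by 32")
        for name in ("tide_t1", "tide_t2", "change_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")


def _height_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Band-limited random terrain, rescaled to [0, 1], tilted toward a
    shoreline so low tide exposes a broad flat."""
    noise = gaussian_filter(rng.normal(size=(size, size)), sigma=size / 10)
    gradient = np.linspace(0.0, 1.0, size)[None, :] * np.ones((size, 1))
    h = 0.6 * gradient + 0.8 * noise
    h -= h.min()
    return h / max(h.max(), 1e-9)


def _blob_mask(size: int, cy: float, cx: float, r0: float,
               rng: np.random.Generator) -> np.ndarray:
    """Smooth random polygon: radius modulated by low-order harmonics."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    radius = np.full_like(theta, r0)
    for k in range(2, 5):
        amp = 0.12 * r0 * rng.uniform(0.3, 1.0)
        radius = radius + amp * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return dist < radius


def _render(height: np.ndarray, tide: float, canopy: np.ndarray,
            texture: np.ndarray, rng: np.random.Generator,
            noise_sd: float) -> np.ndarray:
    """Compose one epoch: terrain, water below tide, canopy, illumination."""
    size = height.shape[0]
    t = height[..., None]
    img = _MUD_LOW + (_MUD_HIGH - _MUD_LOW) * t
    # recently exposed mud stays wet and dark just above the waterline
    wet = ((height >= tide) & (height < tide + 0.06))[..., None]
    img = np.where(wet, img * 0.72, img)
    # patchy algal films on the exposed flat: green-tinted pseudo-change that
    # superficially resembles canopy but follows the tide, not the ecology
    algae_field = gaussian_filter(rng.normal(size=height.shape),
                                  sigma=height.shape[0] / 24)
    algae = ((algae_field > 0.55 * algae_field.std() + algae_field.mean())
             & (height >= tide) & (height < tide + 0.12))[..., None]
    img = np.where(algae, img * 0.55 + _ALGAE[None, None] * 0.45, img)
    water = height < tide
    depth = np.clip((tide - height) / max(tide, 1e-9), 0, 1)[..., None]
    water_col = _WATER_SHALLOW + (_WATER_DEEP - _WATER_SHALLOW) * depth
    # specular sun glint on the water surface
    speckle = (rng.random((size, size)) < 0.025)[..., None] * 0.45
    img = np.where(water[..., None], water_col + speckle, img)
    canopy_col = _CANOPY[None, None] * (0.75 + 0.5 * texture[..., None])
    img = np.where(canopy[..., None], canopy_col, img)
    gain = 1.0 + rng.normal(0.0, 0.04)
    img = img * gain + rng.normal(0.0, noise_sd, img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_scene(params: SceneParams) -> BiTemporalSample:
    """One bi-temporal tile with tide pseudo-change and labeled real change."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.size
    height = _height_field(rng, size)
    high_tide = max(params.tide_t1, params.tide_t2)

    # place non-overlapping stands on ground that stays dry at high tide
    land = height >= high_tide + 0.02
    land_idx = np.flatnonzero(land)
    if land_idx.size < 0.02 * land.size:
        raise GenerationError("almost no dry land above high tide")
    placed: list[tuple] = []   # (cy, cx, r, mask)
    tries = 0
    while len(placed) < params.n_blobs:
        if tries > params.max_retries:
            raise GenerationError(
                f"could not place {params.n_blobs} stands on available land "
                f"after {params.max_retries} retries")
        tries += 1
        # spacing and radius pressure relax as retries accumulate
        spacing = 1.35 if tries < params.max_retries // 3 else 1.0
        lo, hi = params.blob_radius
        if tries > 2 * params.max_retries // 3:
            lo, hi = 0.6 * lo, (lo + hi) / 2
        r0 = rng.uniform(lo, hi) * size
        cy, cx = np.unravel_index(rng.choice(land_idx), land.shape)
        if any(np.hypot(cy - py, cx - px) < spacing * (r0 + pr)
               for py, px, pr, _ in placed):
            continue
        mask = _blob_mask(size, cy, cx, r0, rng) & land
        if mask.sum() < 0.15 * np.pi * r0 ** 2:
            continue
        placed.append((cy, cx, r0, mask))

    n_changed = int(round(params.change_rate * params.n_blobs))
    order = rng.permutation(params.n_blobs)
    changed = set(order[:n_changed].tolist())
    # changed stands exist in exactly one epoch (appearance or disappearance)
    in_t1 = np.zeros((size, size), bool)
    in_t2 = np.zeros((size, size), bool)
    label = np.zeros((size, size), bool)
    for b, (_, _, _, mask) in enumerate(placed):
        if b in changed:
            if rng.random() < 0.5:
                in_t1 |= mask          # stand lost between epochs
            else:
                in_t2 |= mask          # stand gained
            label |= mask
        else:
            in_t1 |= mask
            in_t2 |= mask

    texture = gaussian_filter(rng.random((size, size)), sigma=1.5)
    t1 = _render(height, params.tide_t1, in_t1, texture, rng, params.noise_sd)
    t2 = _render(height, params.tide_t2, in_t2, texture, rng, params.noise_sd)
    sample = BiTemporalSample(id=f"scene_{params.seed:08d}", t1=t1, t2=t2,
                              mask=label.astype(np.uint8))
    sample.validate()
    return sample


@dataclass
class DatasetSpec:
    params: SceneParams = field(default_factory=SceneParams)
    n_train: int = 200
    n_val: int = 50
    n_test: int = 50


def generate_dataset(params: SceneParams, n_train: int, n_val: int,
                     n_test: int, out_root: str,
                     overwrite: bool = False) -> dict:
    """Emit an A/B/label tree plus manifest and generating parameters."""
    params.validate()
    if os.path.isdir(out_root) and os.listdir(out_root) and not overwrite:
        raise FileExistsError(
            f"{out_root} exists and is not empty (pass overwrite=True)")
    os.makedirs(out_root, exist_ok=True)
    counts = {"train": n_train, "val": n_val, "test": n_test}
    by_split: dict = {}
    for si, (split, n) in enumerate(counts.items()):
        samples = []
        for i in range(n):
            p = SceneParams(**{**asdict(params),
                               "seed": _scene_seed(params.seed, si, i)})
            s = generate_scene(p)
            s.id = f"{split}_{i:05d}"
            save_sample(out_root, split, s)
            samples.append(s)
        by_split[split] = samples
    write_manifest(out_root, by_split)
    with open(os.path.join(out_root, "scene_params.yaml"), "w") as fh:
        yaml.safe_dump({"params": asdict(params), "counts": counts}, fh)
    return by_split


def _scene_seed(base: int, split_idx: int, i: int) -> int:
    """Distinct deterministic per-scene seed below 2**31."""
    return (base * 1_000_003 + split_idx * 100_000 + i) % (2 ** 31 - 1)


def generate_split(params: SceneParams, n: int,
                   split_idx: int = 0) -> list[BiTemporalSample]:
    """In-memory split (no disk I/O), same seeding scheme as the tree writer."""
    out = []
    for i in range(n):
        p = SceneParams(**{**asdict(params),
                           "seed": _scene_seed(params.seed, split_idx, i)})
        s = generate_scene(p)
        s.id = f"s{split_idx}_{i:05d}"
        out.append(s)
    return out
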