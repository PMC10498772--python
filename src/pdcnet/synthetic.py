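"""Seeded phantom generator for small, irregular, low-contrast lesions.

Real training data for this problem — brain MRI slices in which the
lesion occupies a tiny fraction of the image, with irregular outline and
weak contrast against surrounding tissue — is private.  This module
generates image/mask pairs that reproduce those regime features so that
training, evaluation and ablation are exercisable end to end with no
download:

* an elliptical "head" region with smooth low-frequency texture on a
  dark background, plus Gaussian pixel noise;
* exactly one star-convex lesion whose boundary radius is perturbed by
  random low-order Fourier modes (irregular outline), placed strictly
  inside the head;
* the lesion is a small intensity offset (``contrast_delta``) on top of
  the local texture — low contrast by construction;
* lesion area is rejection-sampled into ``lesion_area_fraction_range``
  (default 0.5-3% of the image, far less than the background).

Every pair is a pure function of ``(seed, index)``.  Images are
quantized to 8-bit on generation so that a written PNG round-trips
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["PhantomParams", "generate_phantom", "generate_batch", "generate_split"]


@dataclass
class PhantomParams:
    image_size: int = 64
    lesion_area_fraction_range: tuple = (0.005, 0.03)
    contrast_delta: float = 0.12
    noise_sigma: float = 0.05
    irregularity: float = 0.4
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction_range
        if not (0.0 < lo < hi < 0.25):
            raise ValueError(
                f"lesion area fraction range must satisfy 0 < lo < hi < 0.25, got {(lo, hi)}")
        min_area = lo * self.image_size ** 2
        if min_area < 4:
            raise ValueError(
                f"area range infeasible: lo={lo} gives {min_area:.1f} px at "
                f"image_size={self.image_size}; need >= 4 px")


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _lesion_mask(rng, p: PhantomParams, center, r0):
    """Binary star-convex blob: radius r(theta) with random Fourier modes."""
    n = p.image_size
    n_modes = 4
    amps = rng.normal(0.0, 1.0, n_modes) / np.arange(2, 2 + n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - center[0], xx - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for k in range(n_modes):
        pert += amps[k] * np.cos((k + 2) * theta + phases[k])
    radius = r0 * np.clip(1.0 + p.irregularity * pert, 0.35, 2.0)
    return dist <= radius


def generate_phantom(p: PhantomParams, index: int):
    """Generate one (image, mask) pair; deterministic in (p.seed, index).

    image: (H, W) float in [0,1], quantized to 8-bit levels.
    mask:  (H, W) uint8 in {0,1}, a single 4-connected lesion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed & 0x7FFFFFFF, index]))
    n = p.image_size
    lo, hi = p.lesion_area_fraction_range

    # head: ellipse with jittered axes, low-frequency texture
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = n / 2 + rng.uniform(-n * 0.03, n * 0.03, 2)
    ay = n * rng.uniform(0.38, 0.44)
    ax = n * rng.uniform(0.34, 0.40)
    head = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 10.0)
    texture = 0.08 * texture / max(np.abs(texture).max(), 1e-9)
    image = np.where(head, 0.45 + texture, 0.05)

    # lesion: rejection-sample until area fraction in range, single blob,
    # fully inside the head
    mask = None
    for _ in range(200):
        frac = rng.uniform(lo, hi)
        r0 = np.sqrt(frac * n * n / np.pi)
        margin = 2.2 * r0
        # uniform position within the eroded head ellipse
        for _ in range(100):
            t = rng.uniform(0, 2 * np.pi)
            u = np.sqrt(rng.uniform())
            ly = cy + u * max(ay - margin, 1.0) * np.sin(t)
            lx = cx + u * max(ax - margin, 1.0) * np.cos(t)
            if 0 < ly < n - 1 and 0 < lx < n - 1:
                break
        cand = _lesion_mask(rng, p, (ly, lx), r0)
        if not cand.any() or not head[cand].all():
            continue
        f = cand.mean()
        if not (lo <= f <= hi):
            continue
        _, ncomp = ndimage.label(cand, structure=_FOUR_CONN)
        if ncomp != 1:
            continue
        mask = cand
        break
    if mask is None:
        raise RuntimeError(
            f"could not place a lesion within area fraction {(lo, hi)} "
            f"at image_size={n}; parameters are infeasible")

    image = image + p.contrast_delta * mask
    image = image + rng.normal(0.0, p.noise_sigma, (n, n))
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 255.0) / 255.0  # 8-bit quantization
    return image, mask.astype(np.uint8)


def generate_batch(p: PhantomParams, indices):
    """Stack phantoms for the given indices into (N,1,H,W) images and
    (N,H,W) masks."""
    images, masks = [], []
    for i in indices:
        img, msk = generate_phantom(p, i)
        images.append(img)
        masks.append(msk)
    return np.stack(images)[:, None, :, :], np.stack(masks)


# disjoint index streams per split
_SPLIT_BASE = {"train": 0, "val": 1_000_000, "test": 2_000_000}


def generate_split(p: PhantomParams, n_train: int, n_val: int, n_test: int,
                   out_dir, overwrite: bool = False):
    """Write a train/val/test phantom dataset of paired PNGs to disk.

    Layout: <out_dir>/{train,val,test}/{images,masks}/NNNN.png plus a
    manifest.json recording filenames and generator parameters.  Each
    split draws from a disjoint (seed, index) stream.  Counts default to
    the 3:1:1 train/val/test ratio at whatever scale is requested.
    """
    from PIL import Image  # local import keeps the core numpy-only

    if min(n_train, n_val, n_test) < 1:
        raise ValueError("all split sizes must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is non-empty; pass overwrite=True to replace")

    manifest = {"params": asdict(p), "splits": {}}
    counts = {"train": n_train, "val": n_val, "test": n_test}
    for split, count in counts.items():
        img_dir = out_dir / split / "images"
        msk_dir = out_dir / split / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for i in range(count):
            index = _SPLIT_BASE[split] + i
            image, mask = generate_phantom(p, index)
            name = f"{i:04d}.png"
            Image.fromarray(np.round(image * 255.0).astype(np.uint8)).save(img_dir / name)
            Image.fromarray((mask * 255).astype(np.uint8)).save(msk_dir / name)
            files.append({"file": name, "index": index,
                          "foreground_fraction": float(mask.mean())})
        manifest["splits"][split] = files
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
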