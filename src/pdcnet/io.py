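"""Image/mask reading and writing, prediction export, figure panels.

PNG is the canonical raster format (lossless — masks must never go
through a lossy codec).  Images load as floats in [0,1]; masks load as
{0,1}.  A read-only NIfTI slice import is offered as a convenience for
real MRI data.  Coordinate convention: row-major, origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .metrics import evaluate_all
from .network import load_checkpoint

__all__ = [
    "load_image",
    "load_mask",
    "load_pair",
    "save_image",
    "save_mask",
    "load_dataset",
    "pad_to_multiple",
    "predict_to_file",
    "render_panel",
]


def load_image(path) -> np.ndarray:
    """Load a grayscale image as (H, W) floats in [0,1].  RGB inputs are
    converted to single-channel luminance."""
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "F"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def load_mask(path) -> np.ndarray:
    """Load a binary mask as (H, W) uint8 {0,1}.

    The file is expected to be two-valued (e.g. {0,255}); anything else
    triggers a warning and midpoint binarization.
    """
    import warnings

    arr = np.asarray(Image.open(path).convert("L"))
    values = np.unique(arr)
    if len(values) > 2:
        warnings.warn(
            f"mask {path} has {len(values)} distinct values; binarizing at the midpoint",
            RuntimeWarning, stacklevel=2)
    mid = (int(arr.max()) + int(arr.min())) / 2.0 if arr.max() != arr.min() else 0.5
    return (arr > mid).astype(np.uint8) if len(values) > 1 else \
        (arr > 127).astype(np.uint8)


def load_pair(image_path, mask_path):
    """Load an (image, mask) pair, checking dimensions agree."""
    image = load_image(image_path)
    mask = load_mask(mask_path)
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} dimensions differ "
            f"({image_path} / {mask_path})")
    return image, mask


def save_image(path, image):
    """Write an (H, W) [0,1] float image as 8-bit grayscale PNG."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.round(np.clip(image, 0, 1) * 255.0).astype(np.uint8)).save(path)


def save_mask(path, mask):
    """Write an (H, W) binary mask as a {0,255} PNG."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(path)


def load_dataset(root) -> dict:
    """Load a generated split directory back into memory.

    Returns {split: (images (N,1,H,W), masks (N,H,W))} for every split
    listed in the manifest.
    """
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    data = {}
    for split, files in manifest["splits"].items():
        images, masks = [], []
        for rec in files:
            img, msk = load_pair(root / split / "images" / rec["file"],
                                 root / split / "masks" / rec["file"])
            images.append(img)
            masks.append(msk)
        data[split] = (np.stack(images)[:, None], np.stack(masks))
    return data


def load_nifti_slice(path, index=None, axis=2):
    """Read-only convenience: extract one 2-D slice from a NIfTI volume,
    min-max normalized to [0,1]."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim == 2:
        sl = vol
    else:
        if index is None:
            index = vol.shape[axis] // 2
        sl = np.take(vol, index, axis=axis)
    lo, hi = sl.min(), sl.max()
    return (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)


def pad_to_multiple(image, multiple, mode="reflect"):
    """Pad an (H, W) image on the bottom/right to the next multiple.

    Returns (padded, (H, W)) so the caller can crop back exactly.
    """
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image, (h, w)
    np_mode = "reflect" if mode == "reflect" else "constant"
    return np.pad(image, ((0, ph), (0, pw)), mode=np_mode), (h, w)


def predict_to_file(checkpoint_path, image_path, out_path,
                    threshold=0.5, save_probmap=None, pad_mode="reflect"):
    """Segment one image with a saved checkpoint and write the binary
    mask PNG at the original resolution.

    Inputs whose size is not divisible by the model's pooling factor are
    padded (reflect or zero) and the output cropped back.  Optionally
    also writes the probability map.  Returns the probability map.
    """
    model, _ = load_checkpoint(checkpoint_path)
    image = load_image(image_path)
    factor = 2 ** (model.cfg.depth - 1)
    padded, orig = pad_to_multiple(image, factor, mode=pad_mode)
    prob = model.predict(padded)[:orig[0], :orig[1]]
    save_mask(out_path, (prob >= threshold).astype(np.uint8))
    if save_probmap is not None:
        save_image(save_probmap, prob)
    return prob


# ---------------------------------------------------------------------------
# figure panels
# ---------------------------------------------------------------------------

_GUTTER = 2
_HEADER = 14


def render_panel(rows, out_path, column_labels=None):
    """Montage of (image, truth, prediction...) rows into one PNG.

    ``rows`` is a list of tuples of equally sized (H, W) arrays in
    [0,1]; every row must have the same number of entries.  The first
    two columns are labeled original/label and subsequent columns take
    ``column_labels`` (or generic names).  Output bytes are a
    deterministic function of the inputs.
    """
    if not rows:
        raise ValueError("render_panel needs at least one row")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError("all rows must have the same number of entries")
    h, w = np.asarray(rows[0][0]).shape
    for r in rows:
        for entry in r:
            if np.asarray(entry).shape != (h, w):
                raise ValueError("all panel entries must share one size")

    labels = ["original", "label"] + list(
        column_labels or [f"prediction {i + 1}" for i in range(ncols - 2)])
    labels = labels[:ncols]

    width = ncols * w + (ncols + 1) * _GUTTER
    height = _HEADER + len(rows) * h + (len(rows) + 1) * _GUTTER
    canvas = np.full((height, width), 255, dtype=np.uint8)
    for ri, row in enumerate(rows):
        y0 = _HEADER + _GUTTER + ri * (h + _GUTTER)
        for ci, entry in enumerate(row):
            x0 = _GUTTER + ci * (w + _GUTTER)
            tile = np.round(np.clip(np.asarray(entry, dtype=np.float64), 0, 1) * 255)
            canvas[y0:y0 + h, x0:x0 + w] = tile.astype(np.uint8)

    img = Image.fromarray(canvas)
    draw = ImageDraw.Draw(img)
    for ci, label in enumerate(labels):
        x0 = _GUTTER + ci * (w + _GUTTER)
        draw.text((x0 + 1, 1), label[:max(w // 6, 4)], fill=0)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    img.save(out_path)
    return out_path
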