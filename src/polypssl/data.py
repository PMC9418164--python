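"""Image/mask dataset handling.

Datasets are directories of RGB images (PNG/JPEG) with, for labeled data, a
parallel directory of single-channel binary masks matched by file stem.
Loading normalises images to [0, 1] floats, resizes to the network
resolution (bilinear for images, nearest-neighbour for masks so binarity is
preserved), and binarises masks at 0.5.  Splitting into train/val/test and
labeled/unlabeled partitions is driven entirely by an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as sk_resize

__all__ = [
    "ImageSample",
    "DatasetSplit",
    "load_dataset",
    "split_dataset",
    "save_dataset",
    "write_manifest",
]

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class ImageSample:
    """One image with optional mask and provenance metadata.

    ``oracle_mask`` holds the hidden ground truth of an unlabeled sample; it
    exists solely so that pseudo-label quality can be scored against truth in
    evaluation code, and is never read by training code.
    """

    id: str
    image: np.ndarray                       # H,W,3 float in [0,1]
    mask: np.ndarray | None = None          # H,W uint8 in {0,1}
    source_path: str = ""
    original_size: tuple[int, int] = (0, 0)
    oracle_mask: np.ndarray | None = field(default=None, repr=False)


@dataclass
class DatasetSplit:
    labeled: list[ImageSample]
    unlabeled: list[ImageSample]
    val: list[ImageSample]
    test: list[ImageSample]
    seed: int


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def _read_image(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable image file: {path} ({exc})") from exc
    arr = _to_float01(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def _read_mask(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable mask file: {path} ({exc})") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return _to_float01(arr)


def load_dataset(image_dir, mask_dir=None, target_size: tuple[int, int] = (256, 256)) -> list[ImageSample]:
    """Load a directory dataset, resized to ``target_size``, sorted by id."""
    image_dir = Path(image_dir)
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory does not exist: {image_dir}")
    paths = sorted(
        (p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
        key=lambda p: p.stem,
    )
    if not paths:
        raise ValueError(f"no PNG/JPEG images found in {image_dir}")
    mask_index: dict[str, Path] = {}
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        if not mask_dir.is_dir():
            raise FileNotFoundError(f"mask directory does not exist: {mask_dir}")
        for p in sorted(mask_dir.iterdir()):
            if p.suffix.lower() in _IMAGE_EXTS:
                mask_index.setdefault(p.stem, p)

    samples = []
    for p in paths:
        img = _read_image(p)
        original = img.shape[:2]
        if original != tuple(target_size):
            img = sk_resize(img, target_size, order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True).astype(np.float32)
        mask = None
        if mask_dir is not None:
            if p.stem not in mask_index:
                raise FileNotFoundError(f"no mask found for image stem {p.stem!r} in {mask_dir}")
            m = _read_mask(mask_index[p.stem])
            if m.shape != tuple(target_size):
                m = sk_resize(m, target_size, order=0, mode="edge",
                              anti_aliasing=False, preserve_range=True)
            mask = (m >= 0.5).astype(np.uint8)
        samples.append(ImageSample(
            id=p.stem, image=np.clip(img, 0.0, 1.0), mask=mask,
            source_path=str(p), original_size=(int(original[0]), int(original[1])),
        ))
    return samples


def split_dataset(samples: list[ImageSample], ratios: tuple[float, float, float],
                  n_labeled: int, seed: int) -> DatasetSplit:
    """Seeded train/val/test split; the train pool becomes labeled + unlabeled.

    Unlabeled samples have their mask moved to ``oracle_mask`` so training
    code cannot see it while evaluation code can score pseudo-labels.
    """
    if abs(float(np.sum(ratios)) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    for s in samples:
        if s.mask is None:
            raise ValueError(f"sample {s.id!r} lacks a mask; cannot split")
    n = len(samples)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    if n_labeled > n_train:
        raise ValueError(f"n_labeled={n_labeled} exceeds the train pool of {n_train} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [samples[i] for i in order]
    train_pool = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    labeled = train_pool[:n_labeled]
    unlabeled = [
        ImageSample(id=s.id, image=s.image, mask=None, source_path=s.source_path,
                    original_size=s.original_size, oracle_mask=s.mask)
        for s in train_pool[n_labeled:]
    ]
    return DatasetSplit(labeled=labeled, unlabeled=unlabeled, val=val, test=test, seed=seed)


def save_dataset(samples: list[ImageSample], image_dir, mask_dir=None) -> None:
    """Write samples as 8-bit PNG image/mask pairs (masks as 0/255)."""
    image_dir = Path(image_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        iio.imwrite(image_dir / f"{s.id}.png",
                    (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8))
        if mask_dir is not None:
            if s.mask is None:
                raise ValueError(f"sample {s.id!r} has no mask to save")
            iio.imwrite(mask_dir / f"{s.id}.png", (s.mask * 255).astype(np.uint8))


def write_manifest(split: DatasetSplit, path) -> None:
    """Plain-text table (id, role, image path, mask path) for reproducibility."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["id\trole\timage_path\tmask_path"]
    for role in ("labeled", "unlabeled", "val", "test"):
        for s in getattr(split, role):
            has_mask = s.mask is not None
            lines.append(f"{s.id}\t{role}\t{s.source_path}\t{s.source_path if has_mask else '-'}")
    path.write_text("\n".join(lines) + "\n")
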