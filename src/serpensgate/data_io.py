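"""YOLO-format dataset reading/writing, deterministic splits, letterboxing
and training-time augmentation.

A label file holds one ``class cx cy w h`` line per object with coordinates
normalised to [0, 1]. A dataset directory follows the usual layout::

    root/
      data.yaml        # names: [...]
      images/*.png
      labels/*.txt
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

PAD_VALUE = 114  # neutral gray used for letterbox / affine fill


class LabelParseError(ValueError):
    def __init__(self, path, line_no: int, line: str):
        super().__init__(f"{path}:{line_no}: malformed label line {line!r}")
        self.line_no = line_no


@dataclass
class Annotation:
    """One ground-truth box: class id + normalised centre/size."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def to_xyxy(self, width: int, height: int) -> np.ndarray:
        """Pixel corner box on an image of the given size."""
        return np.array([(self.cx - self.w / 2) * width,
                         (self.cy - self.h / 2) * height,
                         (self.cx + self.w / 2) * width,
                         (self.cy + self.h / 2) * height])

    @classmethod
    def from_xyxy(cls, class_id: int, box, width: int, height: int) -> "Annotation":
        x1, y1, x2, y2 = box
        return cls(class_id, (x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
                   (x2 - x1) / width, (y2 - y1) / height)


@dataclass
class DatasetIndex:
    items: list[tuple[Path, Path]]            # (image path, label path)
    class_names: list[str]
    splits: dict[str, list[int]] = field(default_factory=dict)

    def split_items(self, name: str) -> list[tuple[Path, Path]]:
        return [self.items[i] for i in self.splits[name]]


def read_yolo_labels(path) -> list[Annotation]:
    """Parse a label file; out-of-range boxes are clipped with a warning and
    boxes left empty by clipping are dropped."""
    anns: list[Annotation] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(path, ln, line)
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:])
        except ValueError as e:
            raise LabelParseError(path, ln, line) from e
        if cid < 0:
            raise LabelParseError(path, ln, line)
        x1, y1 = cx - w / 2, cy - h / 2
        x2, y2 = cx + w / 2, cy + h / 2
        if min(x1, y1) < 0 or max(x2, y2) > 1:
            # overshoot beyond printing precision is worth a warning; the
            # rounding of a 6-decimal writer is not
            if min(x1, y1) < -1e-5 or max(x2, y2) > 1 + 1e-5:
                warnings.warn(f"{path}:{ln}: box out of range, clipping",
                              stacklevel=2)
            x1, y1, x2, y2 = (np.clip([x1, y1, x2, y2], 0.0, 1.0))
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            warnings.warn(f"{path}:{ln}: empty box after clipping, dropped",
                          stacklevel=2)
            continue
        anns.append(Annotation(cid, (x1 + x2) / 2, (y1 + y2) / 2,
                               x2 - x1, y2 - y1)
                    if (x1, y1, x2, y2) != (cx - w / 2, cy - h / 2,
                                            cx + w / 2, cy + h / 2)
                    else Annotation(cid, cx, cy, w, h))
    return anns


def write_yolo_labels(path, anns: list[Annotation]) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in anns]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_image(path) -> np.ndarray:
    """RGB uint8 HxWx3."""
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(image.astype(np.uint8)).save(path)


def index_dataset(root) -> DatasetIndex:
    """Scan a YOLO dataset directory; class names come from data.yaml."""
    root = Path(root)
    with open(root / "data.yaml") as fh:
        doc = yaml.safe_load(fh)
    names = doc["names"]
    if isinstance(names, dict):
        names = [names[k] for k in sorted(names)]
    items = []
    for img in sorted((root / "images").iterdir()):
        if img.suffix.lower() in (".png", ".jpg", ".jpeg"):
            items.append((img, root / "labels" / (img.stem + ".txt")))
    return DatasetIndex(items, list(names))


def split_dataset(items: list, ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0, class_names: list[str] | None = None
                  ) -> DatasetIndex:
    """Deterministic train/val/test split.

    Train gets floor(r_train * n); the remainder is divided as evenly as
    possible between val and test, val receiving the extra item when odd.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must be positive")
    n = len(items)
    if n < 3:
        raise ValueError(f"cannot split {n} items three ways")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * ratios[0] / sum(ratios)))
    rem = n - n_train
    n_val = (rem + 1) // 2
    order = perm.tolist()
    splits = {"train": order[:n_train],
              "val": order[n_train:n_train + n_val],
              "test": order[n_train + n_val:]}
    return DatasetIndex(list(items), class_names or [], splits)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class LetterboxTransform:
    """Exact mapping between original and letterboxed pixel frames."""

    scale: float
    pad_x: float
    pad_y: float

    def apply_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        out = boxes * self.scale
        out[:, [0, 2]] += self.pad_x
        out[:, [1, 3]] += self.pad_y
        return out

    def invert_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
        boxes[:, [0, 2]] -= self.pad_x
        boxes[:, [1, 3]] -= self.pad_y
        return boxes / self.scale


def letterbox(image: np.ndarray, target: int = 640
              ) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize onto a target x target canvas with symmetric
    gray padding."""
    h, w = image.shape[:2]
    scale = min(target / h, target / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if (nh, nw) != (h, w):
        resized = np.asarray(Image.fromarray(image.astype(np.uint8))
                             .resize((nw, nh), Image.BILINEAR))
    else:
        resized = image
    canvas = np.full((target, target, 3), PAD_VALUE, dtype=np.uint8)
    top, left = (target - nh) // 2, (target - nw) // 2
    canvas[top:top + nh, left:left + nw] = resized
    return canvas, LetterboxTransform(scale, float(left), float(top))


def _clip_annotations(boxes: np.ndarray, classes: list[int], size: int,
                      min_side: float = 2.0) -> list[Annotation]:
    anns = []
    for (x1, y1, x2, y2), c in zip(boxes, classes):
        x1, x2 = np.clip([x1, x2], 0, size)
        y1, y2 = np.clip([y1, y2], 0, size)
        if x2 - x1 >= min_side and y2 - y1 >= min_side:
            anns.append(Annotation.from_xyxy(c, (x1, y1, x2, y2), size, size))
    return anns


def mosaic_augment(samples: list[tuple[np.ndarray, list[Annotation]]],
                   seed: int, enabled: bool = True, target: int = 640,
                   flip_p: float = 0.5, translate: float = 0.1,
                   scale_jitter: float = 0.5
                   ) -> tuple[np.ndarray, list[Annotation]]:
    """2x2 mosaic collage with flip/translate/scale jitter.

    With `enabled` false (the close-mosaic phase of training) the first sample
    is simply letterboxed and flipped with probability `flip_p`.
    """
    rng = np.random.default_rng(seed)
    if not enabled:
        img, anns = samples[0]
        canvas, tf = letterbox(img, target)
        boxes = (tf.apply_boxes(np.array([a.to_xyxy(img.shape[1], img.shape[0])
                                          for a in anns]).reshape(-1, 4)))
        classes = [a.class_id for a in anns]
        out = _clip_annotations(boxes, classes, target)
        if rng.random() < flip_p:
            canvas = canvas[:, ::-1].copy()
            out = [Annotation(a.class_id, 1 - a.cx, a.cy, a.w, a.h) for a in out]
        return canvas, out
    if len(samples) < 4:
        raise ValueError("mosaic needs 4 samples")
    cx = int(rng.uniform(0.25, 0.75) * target)
    cy = int(rng.uniform(0.25, 0.75) * target)
    canvas = np.full((target, target, 3), PAD_VALUE, dtype=np.uint8)
    boxes_all, classes_all = [], []
    regions = [(0, 0, cx, cy), (cx, 0, target, cy),
               (0, cy, cx, target), (cx, cy, target, target)]
    for (x1, y1, x2, y2), (img, anns) in zip(regions, samples):
        rw, rh = x2 - x1, y2 - y1
        if rw < 2 or rh < 2:
            continue
        h, w = img.shape[:2]
        resized = np.asarray(Image.fromarray(img.astype(np.uint8))
                             .resize((rw, rh), Image.BILINEAR))
        canvas[y1:y2, x1:x2] = resized
        sx, sy = rw / w, rh / h
        for a in anns:
            bx = a.to_xyxy(w, h)
            boxes_all.append([bx[0] * sx + x1, bx[1] * sy + y1,
                              bx[2] * sx + x1, bx[3] * sy + y1])
            classes_all.append(a.class_id)
    boxes_all = np.array(boxes_all).reshape(-1, 4)
    # affine jitter: scale then translate, gray fill
    s = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
    tx = rng.uniform(-translate, translate) * target
    ty = rng.uniform(-translate, translate) * target
    nw = max(2, int(round(target * s)))
    scaled = np.asarray(Image.fromarray(canvas).resize((nw, nw), Image.BILINEAR))
    out_img = np.full((target, target, 3), PAD_VALUE, dtype=np.uint8)
    ox, oy = int(round((target - nw) / 2 + tx)), int(round((target - nw) / 2 + ty))
    sx1, sy1 = max(0, -ox), max(0, -oy)
    dx1, dy1 = max(0, ox), max(0, oy)
    cw = min(nw - sx1, target - dx1)
    ch = min(nw - sy1, target - dy1)
    if cw > 0 and ch > 0:
        out_img[dy1:dy1 + ch, dx1:dx1 + cw] = scaled[sy1:sy1 + ch, sx1:sx1 + cw]
    factor = nw / target
    boxes_all = boxes_all * factor
    boxes_all[:, [0, 2]] += ox
    boxes_all[:, [1, 3]] += oy
    anns = _clip_annotations(boxes_all, classes_all, target)
    if rng.random() < flip_p:
        out_img = out_img[:, ::-1].copy()
        anns = [Annotation(a.class_id, 1 - a.cx, a.cy, a.w, a.h) for a in anns]
    return out_img, anns
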