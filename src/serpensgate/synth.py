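"""Synthetic multi-class leaf/lesion detection scenes.

The generator emulates the traits that make in-field plant-disease imagery
hard: elongated, curved lesions on leaf surfaces, several objects per image
at varying scale, cluttered textured backgrounds, global lighting variation
and partial occlusion by foreground strips. It is fully deterministic per
seed and records per-object provenance, so label consistency is guaranteed by
construction (an oracle reading the provenance scores a perfect mAP).

Default palette: six classes — three *lesion* classes drawn as thick curved
strokes with class-specific colour and curve style (0 rust-brown arc, 1 dark
necrotic snake, 2 chlorotic streak) and three *healthy leaf* classes with
distinct shapes and greens (3 round, 4 elongated, 5 lobed). Lesion paths are
constant-curvature random walks with a total turn of 2.2-4.5 rad, so their
arc-length / chord ratio exceeds 1.2 on average — the curved geometry snake
convolutions are meant to follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import Annotation, DatasetIndex, save_image, split_dataset, \
    write_yolo_labels

N_CLASSES = 6
CLASS_NAMES = ["rust_arc_lesion", "necrotic_snake_lesion", "chlorotic_streak",
               "healthy_round_leaf", "healthy_elongated_leaf", "healthy_lobed_leaf"]

_LESION_COLORS = np.array([[150, 84, 38],    # rust brown
                           [64, 34, 66],     # dark necrotic purple
                           [208, 196, 66]],  # chlorotic yellow
                          dtype=np.float32)
_LEAF_GREENS = np.array([[66, 138, 52],
                         [96, 168, 72],
                         [44, 110, 70]], dtype=np.float32)


@dataclass
class SceneConfig:
    size: int = 640
    num_classes: int = N_CLASSES
    leaves: tuple[int, int] = (1, 4)          # leaf polygons per scene
    lesions: tuple[int, int] = (1, 3)         # lesions per diseased leaf
    p_healthy: float = 0.5
    leaf_radius: tuple[float, float] = (0.14, 0.30)   # fraction of canvas
    lesion_width: tuple[float, float] = (0.05, 0.09)  # stroke width fraction
    occluder_prob: float = 0.5
    max_occlusion: float = 0.25               # strip width fraction
    lighting: tuple[float, float] = (0.7, 1.25)

    def validate(self) -> None:
        if self.size < 32:
            raise ValueError("canvas too small")
        if self.leaf_radius[1] >= 0.5:
            raise ValueError("leaf larger than image")
        if self.leaves[0] < 0 or self.lesions[0] < 0:
            raise ValueError("object counts must be nonnegative")


def desk_profile() -> SceneConfig:
    """256x256 profile for fast CPU experiments."""
    return SceneConfig(size=256)


@dataclass
class ObjectProvenance:
    class_id: int
    control_points: np.ndarray      # lesion path or leaf outline samples (pixel)
    occlusion_fraction: float
    box: np.ndarray                 # tight pixel xyxy bound, pre-occlusion


@dataclass
class SyntheticScene:
    image: np.ndarray
    annotations: list[Annotation]
    seed: int
    lighting_gain: float = 1.0
    objects: list[ObjectProvenance] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rasterisation helpers (pure numpy)
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, size: int, cells: int,
                  lo: float, hi: float) -> np.ndarray:
    """Bilinearly upsampled random grid — cheap cloudy texture."""
    grid = rng.uniform(lo, hi, size=(cells, cells, 3)).astype(np.float32)
    idx = np.linspace(0, cells - 1, size)
    i0 = np.floor(idx).astype(int)
    i1 = np.minimum(i0 + 1, cells - 1)
    f = (idx - i0).astype(np.float32)
    rows = grid[i0] * (1 - f)[:, None, None] + grid[i1] * f[:, None, None]
    cols = (rows[:, i0] * (1 - f)[None, :, None]
            + rows[:, i1] * f[None, :, None])
    return cols


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    base = _smooth_noise(rng, size, 6, 40, 150)
    base[..., 1] *= rng.uniform(1.0, 1.4)     # greenish soil/foliage clutter
    fine = rng.normal(0, 9, size=(size, size, 3)).astype(np.float32)
    return np.clip(base + fine, 0, 255)


def _leaf_mask(rng: np.random.Generator, size: int, cx: float, cy: float,
               r: float, kind: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask of a wavy leaf shape + sampled outline points."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    theta = np.arctan2(yy - cy, xx - cx)
    rot = rng.uniform(0, 2 * np.pi)
    aspect = {3: 1.0, 4: 0.45, 5: 0.85}.get(kind, rng.uniform(0.5, 1.0))
    lobes = {3: 0, 4: 0, 5: 5}.get(kind, 0)
    wob_amp = 0.25 if lobes else rng.uniform(0.03, 0.10)
    phase = rng.uniform(0, 2 * np.pi)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(rot) + dy * np.sin(rot)
    v = -dx * np.sin(rot) + dy * np.cos(rot)
    rad = np.sqrt((u / 1.0) ** 2 + (v / aspect) ** 2)
    ang = np.arctan2(v / aspect, u)
    boundary = r * (1 + wob_amp * np.cos((lobes or 3) * ang + phase))
    mask = rad < boundary
    ts = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    br = r * (1 + wob_amp * np.cos((lobes or 3) * ts + phase))
    ox = cx + br * np.cos(ts) * np.cos(rot) - br * np.sin(ts) * aspect * np.sin(rot)
    oy = cy + br * np.cos(ts) * np.sin(rot) + br * np.sin(ts) * aspect * np.cos(rot)
    return mask, np.stack([ox, oy], axis=1)


def _curve_path(rng: np.random.Generator, start: np.ndarray, length: float,
                n_steps: int = 64) -> np.ndarray:
    """Constant-curvature random walk with heading noise (a snake path)."""
    total_turn = rng.uniform(2.2, 4.5) * rng.choice([-1.0, 1.0])
    heading = rng.uniform(0, 2 * np.pi)
    step = length / n_steps
    pts = [start.astype(np.float64)]
    for _ in range(n_steps):
        heading += total_turn / n_steps + rng.normal(0, 0.06)
        pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    return np.array(pts)


def arc_chord_ratio(path: np.ndarray) -> float:
    seg = np.diff(path, axis=0)
    arc = np.sqrt((seg ** 2).sum(1)).sum()
    chord = np.sqrt(((path[-1] - path[0]) ** 2).sum())
    return float(arc / max(chord, 1e-9))


def _stamp_path(img: np.ndarray, path: np.ndarray, width: float,
                color: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Paint disks along a path; returns the painted boolean mask."""
    size = img.shape[0]
    mask = np.zeros(img.shape[:2], dtype=bool)
    rad = max(1.5, width / 2)
    ir = int(np.ceil(rad)) + 1
    for px, py in path:
        x0, x1 = int(px) - ir, int(px) + ir + 1
        y0, y1 = int(py) - ir, int(py) + ir + 1
        x0c, y0c = max(0, x0), max(0, y0)
        x1c, y1c = min(size, x1), min(size, y1)
        if x1c <= x0c or y1c <= y0c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        mask[y0c:y1c, x0c:x1c] |= (xx - px) ** 2 + (yy - py) ** 2 < rad ** 2
    shade = 1.0 + rng.normal(0, 0.05, size=3).astype(np.float32)
    img[mask] = np.clip(color * shade, 0, 255)
    return mask


def _tight_box(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1],
                    dtype=np.float64)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_leaf_scene(seed: int, params: SceneConfig | None = None
                        ) -> SyntheticScene:
    """One deterministic scene: background, leaves, lesions, lighting,
    occluders; boxes are tight bounds of each rendered object pre-occlusion."""
    cfg = params or SceneConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    size = cfg.size
    img = _background(rng, size)
    objects: list[ObjectProvenance] = []
    n_leaves = int(rng.integers(cfg.leaves[0], cfg.leaves[1] + 1))
    for _ in range(n_leaves):
        r = rng.uniform(*cfg.leaf_radius) * size
        cx = rng.uniform(r * 0.8, size - r * 0.8)
        cy = rng.uniform(r * 0.8, size - r * 0.8)
        healthy = rng.random() < cfg.p_healthy
        kind = int(rng.integers(3, 6)) if healthy else -1
        mask, outline = _leaf_mask(rng, size, cx, cy, r, kind)
        if not mask.any():
            continue
        green = _LEAF_GREENS[(kind - 3) if healthy else rng.integers(0, 3)]
        shade = _smooth_noise(rng, size, 4, 0.75, 1.1)[..., :1]
        img[mask] = np.clip(green * shade[mask], 0, 255)
        if healthy:
            objects.append(ObjectProvenance(kind, outline, 0.0, _tight_box(mask)))
            continue
        n_les = int(rng.integers(cfg.lesions[0], cfg.lesions[1] + 1))
        for _ in range(n_les):
            lc = int(rng.integers(0, 3))
            ang = rng.uniform(0, 2 * np.pi)
            start = np.array([cx + rng.uniform(-0.4, 0.4) * r * np.cos(ang),
                              cy + rng.uniform(-0.4, 0.4) * r * np.sin(ang)])
            length = rng.uniform(0.9, 1.6) * r
            path = _curve_path(rng, start, length)
            path = np.clip(path, 2, size - 3)
            width = rng.uniform(*cfg.lesion_width) * size
            if lc == 0:       # rust arc: blobby dotted stroke
                keep = rng.random(len(path)) < 0.8
                keep[0] = keep[-1] = True
                path_draw = path[keep]
            else:
                path_draw = path
            lmask = _stamp_path(img, path_draw, width, _LESION_COLORS[lc], rng)
            if not lmask.any():
                continue
            objects.append(ObjectProvenance(lc, path, 0.0, _tight_box(lmask)))
    # global illumination: gain x linear gradient
    gain = rng.uniform(*cfg.lighting)
    gdir = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size
    grad = 1.0 + 0.2 * ((xx - 0.5) * np.cos(gdir) + (yy - 0.5) * np.sin(gdir))
    img = np.clip(img * gain * grad[..., None], 0, 255)
    # occluding foreground strips (after boxes were captured)
    if rng.random() < cfg.occluder_prob and objects:
        w = rng.uniform(0.05, cfg.max_occlusion) * size
        x0 = rng.uniform(0, size - w)
        tilt = rng.uniform(-0.3, 0.3)
        yy2 = np.arange(size)[:, None]
        xx2 = np.arange(size)[None, :]
        strip = np.abs(xx2 - (x0 + tilt * yy2) - w / 2) < w / 2
        img[strip] = np.clip(_LEAF_GREENS[2] * rng.uniform(0.4, 0.8), 0, 255)
        area = strip.astype(np.float64)
        for ob in objects:
            x1, y1, x2, y2 = ob.box.astype(int)
            patch = area[y1:y2, x1:x2]
            ob.occlusion_fraction = float(patch.mean()) if patch.size else 0.0
    anns = [Annotation.from_xyxy(ob.class_id, ob.box, size, size)
            for ob in objects]
    return SyntheticScene(img.astype(np.uint8), anns, seed, gain, objects)


def expected_class_distribution(cfg: SceneConfig | None = None) -> np.ndarray:
    """Analytic expected per-object class mixture of the generator.

    A leaf is healthy with probability p (one object, uniform over the three
    leaf classes) or diseased (E[lesions] objects, uniform over the three
    lesion classes).
    """
    cfg = cfg or SceneConfig()
    p = cfg.p_healthy
    e_les = (cfg.lesions[0] + cfg.lesions[1]) / 2
    w_dis = (1 - p) * e_les
    probs = np.empty(6)
    probs[:3] = w_dis / 3
    probs[3:] = p / 3
    return probs / probs.sum()


def generate_dataset(n: int, seed: int, out, cfg: SceneConfig | None = None,
                     ratios: tuple[int, int, int] = (8, 1, 1)) -> DatasetIndex:
    """Write `n` scenes in YOLO layout (images/, labels/, data.yaml) and
    return a deterministic split index."""
    cfg = cfg or SceneConfig()
    out = Path(out)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    items = []
    for i in range(n):
        scene = generate_leaf_scene(seed * 1_000_003 % (2**31) + i, cfg)
        img_path = out / "images" / f"scene_{i:05d}.png"
        lbl_path = out / "labels" / f"scene_{i:05d}.txt"
        save_image(img_path, scene.image)
        write_yolo_labels(lbl_path, scene.annotations)
        items.append((img_path, lbl_path))
    names = CLASS_NAMES[:cfg.num_classes]
    with open(out / "data.yaml", "w") as fh:
        yaml.safe_dump({"names": names, "nc": len(names)}, fh)
    index = split_dataset(items, ratios, seed, class_names=names)
    return index
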