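"""Procedural rendering of labeled face scenes for the four health states.

The generator is the test bed for the whole pipeline: it draws 2-D
parametric blob composites — not photorealistic animals — whose
appearance encodes the four facial archetypes used in the field:

* **Normal** — bright clear eyes, moist glossy snout, mouth closed.
* **Cold**   — dull eyes, reduced snout gloss, mouth half open to aid
  breathing, discharge streaks under the eyes.
* **Cough**  — mouth wide open, moderate eyes, foam-dulled snout.
* **Fever**  — dull sunken eyes, dry cracked (matte) snout, reddish hue.

The class parameterizations are pairwise separated by at least 0.25 in
one coordinate, which makes the classes statistically separable from
pixel statistics alone.  Each face also carries an identity-linked base
hue and speckle texture so animal-ID-aware splitting can be exercised,
and face scale is drawn log-uniformly so that both the small-target and
large-target detection paths see data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.draw import disk, ellipse

from .types import NUM_CLASSES, BBox, ImageRecord


@dataclass(frozen=True)
class ArchetypeParams:
    eye_brightness: float
    snout_gloss: float
    mouth_aperture: float
    discharge_streak: bool
    hue_shift: float  # degrees


ARCHETYPES: Dict[int, ArchetypeParams] = {
    0: ArchetypeParams(0.85, 0.85, 0.10, False, 0.0),    # Normal
    1: ArchetypeParams(0.55, 0.60, 0.50, True, -20.0),   # Cold
    2: ArchetypeParams(0.70, 0.50, 0.90, False, 10.0),   # Cough
    3: ArchetypeParams(0.35, 0.15, 0.30, False, 30.0),   # Fever
}


def archetype_separation() -> float:
    """Minimum over class pairs of the max per-coordinate separation."""
    vecs = [np.array([a.eye_brightness, a.snout_gloss, a.mouth_aperture])
            for a in ARCHETYPES.values()]
    worst = np.inf
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            worst = min(worst, np.abs(vecs[i] - vecs[j]).max())
    return float(worst)


@dataclass
class SceneSpec:
    canvas_size: int = 96
    n_faces: int = 2
    class_mix: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    scale_range: Tuple[float, float] = (0.25, 0.45)
    clutter_level: float = 0.3
    animal_pool: int = 40

    def __post_init__(self):
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError("class_mix must sum to 1")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("scale_range must lie within (0, 0.5]")


def _hsv_to_rgb(h, s, v):
    h = (h % 1.0) * 6.0
    i = int(h)
    f = h - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i % 6]


def _identity_style(animal_idx: int) -> Tuple[float, int]:
    """Stable per-identity base hue and texture seed."""
    digest = hashlib.sha256(f"pig{animal_idx}".encode()).digest()
    hue = int.from_bytes(digest[:4], "little") / 2 ** 32
    tex_seed = int.from_bytes(digest[4:8], "little") % (2 ** 31)
    return 0.05 + 0.08 * hue, tex_seed  # pinkish-brown band


def _draw_face(img: np.ndarray, cx: float, cy: float, size: float,
               class_id: int, animal_idx: int) -> None:
    h, w = img.shape[:2]
    params = ARCHETYPES[class_id]
    base_hue, tex_seed = _identity_style(animal_idx)
    hue = base_hue + params.hue_shift / 360.0
    head_rgb = np.array(_hsv_to_rgb(hue, 0.35, 0.65))

    rr, cc = ellipse(cy, cx, 0.5 * size, 0.46 * size, shape=(h, w))
    tex_rng = np.random.default_rng(tex_seed)
    speckle = 1.0 + 0.08 * tex_rng.standard_normal(len(rr))
    img[rr, cc] = np.clip(head_rgb[None, :] * speckle[:, None], 0, 1)

    for side in (-1, 1):  # eyes
        ex, ey = cx + side * 0.20 * size, cy - 0.16 * size
        rr, cc = disk((ey, ex), 0.10 * size, shape=(h, w))
        img[rr, cc] = params.eye_brightness
        if params.discharge_streak:
            rr, cc = ellipse(ey + 0.16 * size, ex, 0.10 * size, 0.025 * size,
                             shape=(h, w))
            img[rr, cc] = (0.25, 0.3, 0.35)

    sx, sy = cx, cy + 0.16 * size  # snout
    rr, cc = ellipse(sy, sx, 0.11 * size, 0.17 * size, shape=(h, w))
    img[rr, cc] = (0.75, 0.5, 0.5)
    rr, cc = disk((sy - 0.03 * size, sx - 0.05 * size), 0.045 * size, shape=(h, w))
    img[rr, cc] = 0.4 + 0.6 * params.snout_gloss  # specular highlight

    my = cy + 0.36 * size  # mouth
    rr, cc = ellipse(my, cx, (0.015 + 0.10 * params.mouth_aperture) * size,
                     0.14 * size, shape=(h, w))
    img[rr, cc] = (0.12, 0.08, 0.08)


def eye_patch_stat(record: ImageRecord, ann_index: int = 0) -> float:
    """Mean intensity over the two eye discs of one annotated face.

    The eye positions are fixed fractions of the face box, so the
    statistic is computable from the annotation geometry alone.
    """
    cid, box = record.annotations[ann_index]
    h, w = record.pixels.shape[:2]
    size = box.h * h / 1.04  # box adds a 2% margin per side
    cx, cy = box.xc * w, box.yc * h
    vals = []
    for side in (-1, 1):
        ex, ey = cx + side * 0.20 * size, cy - 0.16 * size
        rr, cc = disk((ey, ex), 0.08 * size, shape=(h, w))
        vals.append(record.pixels[rr, cc].mean())
    return float(np.mean(vals))


def render_scene(spec: SceneSpec, rng: np.random.Generator,
                 classes: Optional[List[int]] = None,
                 animal_idx: Optional[int] = None,
                 name: str = "") -> ImageRecord:
    """Render one scene; annotation boxes tightly enclose each face.

    ``classes`` pins the per-face classes (otherwise drawn from
    ``class_mix``); ``animal_idx`` pins the identity.  Placement retries
    until face boxes overlap by at most 50% IoU; an impossible request
    raises.
    """
    s = spec.canvas_size
    img = np.empty((s, s, 3), dtype=np.float64)
    img[...] = (0.45, 0.50, 0.42)
    img += 0.02 * rng.standard_normal((s, s, 3))
    n_clutter = int(round(8 * spec.clutter_level))
    for _ in range(n_clutter):  # class-independent background clutter
        ccx, ccy = rng.uniform(0, s, 2)
        ax_ = rng.uniform(0.03, 0.10) * s
        rr, cc = ellipse(ccy, ccx, ax_, ax_ * rng.uniform(0.5, 1.5), shape=(s, s))
        img[rr, cc] = rng.uniform(0.2, 0.8, 3)

    if animal_idx is None:
        animal_idx = int(rng.integers(spec.animal_pool))
    if classes is None:
        classes = [int(rng.choice(NUM_CLASSES, p=spec.class_mix))
                   for _ in range(spec.n_faces)]
    elif len(classes) != spec.n_faces:
        raise ValueError("classes must have one entry per face")

    annotations = []
    placed: List[Tuple[float, float, float, float]] = []
    lo, hi = spec.scale_range
    for cid in classes:
        # log-uniform scale: exercises small- and large-target paths
        scale = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        size = scale * s
        ok = False
        for _ in range(50):
            cx = rng.uniform(0.55 * size, s - 0.55 * size)
            cy = rng.uniform(0.55 * size, s - 0.55 * size)
            x1, y1 = cx - 0.52 * size, cy - 0.52 * size
            x2, y2 = cx + 0.52 * size, cy + 0.52 * size
            if all(_iou((x1, y1, x2, y2), p) <= 0.5 for p in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"cannot place {spec.n_faces} faces without >50% overlap")
        placed.append((x1, y1, x2, y2))
        _draw_face(img, cx, cy, size, cid, animal_idx)
        annotations.append((cid, BBox.from_xyxy(x1, y1, x2, y2, size=s)))

    np.clip(img, 0.0, 1.0, out=img)
    return ImageRecord(pixels=img.astype(np.float32),
                       animal_id=f"pig{animal_idx:03d}",
                       annotations=annotations, name=name)


def _iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def generate_dataset(n_images: int, spec: SceneSpec, seed: int
                     ) -> Tuple[List[ImageRecord], List[dict]]:
    """Deterministically generate ``n_images`` scenes plus a manifest.

    Face classes are drawn by a quota sampler that tracks ``class_mix``
    deficits, keeping realized class balance within one face of the
    requested mix (and hence within ±2% for any reasonably sized set).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    mix = np.asarray(spec.class_mix, dtype=np.float64)
    counts = np.zeros(NUM_CLASSES)
    records, manifest = [], []
    for i in range(n_images):
        classes = []
        for _ in range(spec.n_faces):
            total = counts.sum() + 1
            deficit = mix * total - counts
            cid = int(np.argmax(deficit))
            counts[cid] += 1
            classes.append(cid)
        # shuffle within the image so class order carries no signal
        rng.shuffle(classes)
        rec = render_scene(spec, rng, classes=classes, name=f"scene{i:05d}")
        records.append(rec)
        manifest.append({"name": rec.name, "animal_id": rec.animal_id,
                         "classes": rec.classes})
    return records, manifest


def manifest_hash(manifest: List[dict]) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
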