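"""Annotation I/O, preprocessing, augmentation, and leakage-free splitting.

File conventions
----------------
A dataset directory holds ``images/<name>.png``, and either
``labels/<name>.txt`` (YOLO dialect: one ``class xc yc w h`` line per
box, normalized center format) or ``annotations.json`` (COCO detection
dialect, pixel ``[x, y, w, h]`` boxes).  The animal identity comes from
a sidecar ``animals.tsv`` (``<image file><TAB><animal id>``); when the
sidecar is missing, the filename prefix before the first underscore is
used.

Preprocessing follows resize -> wavelet denoise -> Z-score: images are
resized to a common square resolution, denoised by a single-level db2
decomposition with soft universal thresholding (sigma estimated from the
median absolute deviation of the finest diagonal detail band), and
standardized per channel with statistics fitted on the training split
only.

Partitioning is animal-ID-aware: whole identity groups are greedily
assigned to the split with the largest remaining per-class quota
deficit, so no identity ever crosses splits and per-class proportions
track the requested fractions to within one group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pywt
from PIL import Image
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from .types import CLASS_NAMES, NUM_CLASSES, BBox, ImageRecord

logger = logging.getLogger(__name__)

DIALECTS = ("yolo_txt", "coco_json")


@dataclass
class NormalizerStats:
    """Per-channel standardization statistics (training split only)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.std = np.asarray(self.std, dtype=np.float64).reshape(3)
        if (self.std < 0).any():
            raise ValueError("std must be non-negative")


@dataclass
class SplitResult:
    train: List[ImageRecord]
    val: List[ImageRecord]
    test: List[ImageRecord]
    seed: int
    per_class_counts: np.ndarray  # (NUM_CLASSES, 3)

    @property
    def splits(self) -> Dict[str, List[ImageRecord]]:
        return {"train": self.train, "val": self.val, "test": self.test}


@dataclass
class AugmentPolicy:
    rotation_deg: float = 15.0
    flip_p: float = 0.5
    jitter: float = 0.2  # photometric factors drawn from [1-j, 1+j]

    def __post_init__(self):
        if not 0 <= self.rotation_deg <= 15:
            raise ValueError("rotation bound must lie in [0, 15] degrees")
        if not 0 <= self.flip_p <= 1 or not 0 <= self.jitter <= 0.2:
            raise ValueError("flip_p in [0,1], jitter in [0, 0.2]")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _animal_map(root: Path) -> Dict[str, str]:
    tsv = root / "animals.tsv"
    if not tsv.exists():
        return {}
    out = {}
    for line in tsv.read_text().splitlines():
        if not line.strip():
            continue
        try:
            fname, aid = line.split("\t")
        except ValueError as e:
            raise ValueError(f"{tsv}: malformed sidecar line {line!r}") from e
        out[fname] = aid
    return out


def _animal_id_for(fname: str, sidecar: Dict[str, str]) -> str:
    if fname in sidecar:
        return sidecar[fname]
    stem = Path(fname).stem
    return stem.split("_")[0]


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return arr


def read_annotations(path, dialect: str = "yolo_txt") -> List[ImageRecord]:
    """Read a dataset directory into validated records."""
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(root)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    if dialect == "yolo_txt":
        return _read_yolo(root)
    return _read_coco(root)


def _read_yolo(root: Path) -> List[ImageRecord]:
    sidecar = _animal_map(root)
    records = []
    img_dir, lbl_dir = root / "images", root / "labels"
    for img_path in sorted(img_dir.glob("*.png")):
        pixels = _load_image(img_path)
        lbl_path = lbl_dir / (img_path.stem + ".txt")
        annotations = []
        if lbl_path.exists():
            for ln, line in enumerate(lbl_path.read_text().splitlines(), 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ValueError(f"{lbl_path}:{ln}: expected 5 fields, "
                                     f"got {len(parts)}: {line!r}")
                try:
                    cid = int(parts[0])
                    xc, yc, w, h = map(float, parts[1:])
                except ValueError as e:
                    raise ValueError(f"{lbl_path}:{ln}: malformed line {line!r}") from e
                if cid not in range(NUM_CLASSES):
                    raise ValueError(
                        f"{lbl_path}:{ln}: unknown class {cid}; vocabulary: "
                        f"{dict(enumerate(CLASS_NAMES))}")
                annotations.append((cid, BBox(xc, yc, w, h)))
        records.append(ImageRecord(pixels=pixels,
                                   animal_id=_animal_id_for(img_path.name, sidecar),
                                   annotations=annotations,
                                   name=img_path.stem))
    return records


def _read_coco(root: Path) -> List[ImageRecord]:
    js = root / "annotations.json"
    if not js.exists():
        raise FileNotFoundError(js)
    doc = json.loads(js.read_text())
    cats = {c["id"]: c["name"] for c in doc.get("categories", [])}
    name_to_cid = {n: i for i, n in enumerate(CLASS_NAMES)}
    sidecar = _animal_map(root)
    by_image: Dict[int, list] = {}
    for ann in doc.get("annotations", []):
        by_image.setdefault(ann["image_id"], []).append(ann)
    records = []
    for im in sorted(doc["images"], key=lambda d: d["id"]):
        pixels = _load_image(root / "images" / im["file_name"])
        H, W = pixels.shape[:2]
        annotations = []
        for ann in by_image.get(im["id"], []):
            cat_name = cats.get(ann["category_id"])
            if cat_name not in name_to_cid:
                raise ValueError(
                    f"{js}: unknown category {ann['category_id']!r} "
                    f"({cat_name!r}); vocabulary: {list(CLASS_NAMES)}")
            x, y, w, h = ann["bbox"]
            annotations.append((name_to_cid[cat_name],
                                BBox((x + w / 2) / W, (y + h / 2) / H, w / W, h / H)))
        aid = im.get("animal_id") or _animal_id_for(im["file_name"], sidecar)
        records.append(ImageRecord(pixels=pixels, animal_id=aid,
                                   annotations=annotations,
                                   name=Path(im["file_name"]).stem))
    return records


def write_annotations(records: Sequence[ImageRecord], path,
                      dialect: str = "yolo_txt") -> int:
    """Write records so that reading them back reproduces the input."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    root = Path(path)
    try:
        (root / "images").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {root}: {e}") from e
    names = []
    for i, rec in enumerate(records):
        names.append(rec.name or f"{rec.animal_id}_{i:05d}")
    sidecar_lines = []
    for rec, name in zip(records, names):
        arr = np.clip(rec.pixels, 0, 1)
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(
            root / "images" / f"{name}.png")
        sidecar_lines.append(f"{name}.png\t{rec.animal_id}")
    (root / "animals.tsv").write_text("\n".join(sidecar_lines) + ("\n" if sidecar_lines else ""))
    if dialect == "yolo_txt":
        (root / "labels").mkdir(exist_ok=True)
        for rec, name in zip(records, names):
            lines = [f"{cid} {b.xc:.6f} {b.yc:.6f} {b.w:.6f} {b.h:.6f}"
                     for cid, b in rec.annotations]
            (root / "labels" / f"{name}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else ""))
    else:
        images, annotations = [], []
        ann_id = 1
        for img_id, (rec, name) in enumerate(zip(records, names), start=1):
            H, W = rec.pixels.shape[:2]
            images.append({"id": img_id, "file_name": f"{name}.png",
                           "width": W, "height": H, "animal_id": rec.animal_id})
            for cid, b in rec.annotations:
                x1, y1, x2, y2 = b.to_xyxy()
                annotations.append({
                    "id": ann_id, "image_id": img_id, "category_id": cid + 1,
                    "bbox": [x1 * W, y1 * H, (x2 - x1) * W, (y2 - y1) * H],
                    "area": (x2 - x1) * W * (y2 - y1) * H, "iscrowd": 0})
                ann_id += 1
        doc = {"images": images, "annotations": annotations,
               "categories": [{"id": i + 1, "name": n}
                              for i, n in enumerate(CLASS_NAMES)]}
        (root / "annotations.json").write_text(json.dumps(doc, indent=1))
    return len(records)


def records_equal(a: ImageRecord, b: ImageRecord, *, box_tol: float = 1e-5,
                  pixel_tol: float = 1.5 / 255) -> bool:
    """Round-trip equality: identity, labels, boxes, and quantized pixels."""
    if a.animal_id != b.animal_id or len(a.annotations) != len(b.annotations):
        return False
    for (ca, ba), (cb, bb) in zip(a.annotations, b.annotations):
        if ca != cb or not ba.approx_equal(bb, tol=box_tol):
            return False
    if a.pixels.shape != b.pixels.shape:
        return False
    return bool(np.abs(a.pixels - b.pixels).max() <= pixel_tol)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def wavelet_denoise(pixels: np.ndarray, wavelet: str = "db2") -> np.ndarray:
    """Single-level soft-threshold wavelet shrinkage, per channel.

    The noise scale sigma is the median absolute deviation of the finest
    diagonal detail band divided by 0.6745; the universal threshold
    sigma * sqrt(2 log N) is applied softly to all detail bands.  A
    noise-free piecewise-constant image passes through essentially
    unchanged because its detail coefficients are (near) zero.
    """
    out = np.empty_like(pixels, dtype=np.float64)
    h, w = pixels.shape[:2]
    n = h * w
    for ch in range(pixels.shape[2]):
        x = pixels[..., ch].astype(np.float64)
        cA, (cH, cV, cD) = pywt.dwt2(x, wavelet, mode="symmetric")
        sigma = np.median(np.abs(cD)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        if thr > 0:
            cH, cV, cD = (pywt.threshold(c, thr, mode="soft")
                          for c in (cH, cV, cD))
        den = pywt.idwt2((cA, (cH, cV, cD)), wavelet, mode="symmetric")
        out[..., ch] = den[:h, :w]
    return out.astype(pixels.dtype)


def fit_normalizer(train_records: Sequence[ImageRecord]) -> NormalizerStats:
    """Per-channel mean/std over every training pixel (two-pass exact)."""
    if len(train_records) == 0:
        raise ValueError("cannot fit a normalizer on an empty training split")
    total = np.zeros(3)
    count = 0
    for rec in train_records:
        total += rec.pixels.reshape(-1, 3).sum(axis=0, dtype=np.float64)
        count += rec.pixels.shape[0] * rec.pixels.shape[1]
    mean = total / count
    ssq = np.zeros(3)
    for rec in train_records:
        d = rec.pixels.reshape(-1, 3).astype(np.float64) - mean
        ssq += (d * d).sum(axis=0)
    return NormalizerStats(mean=mean, std=np.sqrt(ssq / count))


def standardize(pixels: np.ndarray, stats: NormalizerStats) -> np.ndarray:
    """(x - mean) / std per channel; constant channels map to all zeros."""
    out = np.empty_like(pixels, dtype=np.float32)
    for ch in range(3):
        if stats.std[ch] == 0:
            logger.warning("channel %d has zero variance; output set to zero", ch)
            out[..., ch] = 0.0
        else:
            out[..., ch] = (pixels[..., ch] - stats.mean[ch]) / stats.std[ch]
    return out


def preprocess(record: ImageRecord, target_size: int = 640,
               stats: Optional[NormalizerStats] = None,
               denoise: bool = True) -> ImageRecord:
    """Resize to target_size x target_size, denoise, then standardize.

    Boxes are stored normalized, so resizing leaves them unchanged.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    px = record.pixels
    if px.shape[:2] != (target_size, target_size):
        px = sktransform.resize(px, (target_size, target_size), order=1,
                                anti_aliasing=px.shape[0] > target_size,
                                preserve_range=True)
    if denoise:
        px = wavelet_denoise(px)
    if stats is not None:
        px = standardize(px, stats)
    return ImageRecord(pixels=px.astype(np.float32), animal_id=record.animal_id,
                       annotations=list(record.annotations), name=record.name)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rotate_boxes(annotations, angle_deg: float, shape) -> List[Tuple[int, BBox]]:
    """Axis-aligned hull of the rotated corners, clipped to the frame.

    Boxes whose clipped area falls below 10% of the original are dropped.
    """
    h, w = shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # image content rotates CCW by angle; in row-down pixel coordinates a
    # content point maps through the matching coordinate rotation
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    out = []
    dropped = 0
    for cid, b in annotations:
        x1, y1, x2, y2 = b.to_xyxy()
        corners = np.array([[x1 * w, y1 * h], [x2 * w, y1 * h],
                            [x1 * w, y2 * h], [x2 * w, y2 * h]])
        rel = corners - (cx, cy)
        new = rel @ rot.T + (cx, cy)
        nx1, ny1 = new.min(axis=0)
        nx2, ny2 = new.max(axis=0)
        orig_area = (nx2 - nx1) * (ny2 - ny1)
        nx1, ny1 = max(nx1, 0.0), max(ny1, 0.0)
        nx2, ny2 = min(nx2, float(w)), min(ny2, float(h))
        if nx2 <= nx1 or ny2 <= ny1 or \
                (nx2 - nx1) * (ny2 - ny1) < 0.10 * orig_area:
            dropped += 1
            continue
        out.append((cid, BBox.from_xyxy(nx1 / w, ny1 / h, nx2 / w, ny2 / h)))
    if dropped:
        logger.warning("augmentation dropped %d box(es) rotated out of frame",
                       dropped)
    return out


def augment(record: ImageRecord, rng: np.random.Generator,
            policy: AugmentPolicy = AugmentPolicy()) -> ImageRecord:
    """Random rotation, horizontal flip, and photometric jitter.

    Class labels are never changed; boxes follow the geometry (clipped
    hulls under rotation, xc -> 1-xc under flip).  The transform is
    deterministic for a given generator state.
    """
    px = record.pixels.astype(np.float64)
    anns = list(record.annotations)

    angle = float(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
    if abs(angle) > 1e-9:
        px = sktransform.rotate(px, angle, resize=False, mode="edge")
        anns = _rotate_boxes(anns, angle, px.shape)

    if rng.random() < policy.flip_p:
        px = px[:, ::-1].copy()
        anns = [(cid, BBox(1.0 - b.xc, b.yc, b.w, b.h)) for cid, b in anns]

    j = policy.jitter
    if j > 0:
        f_sat, f_bright, f_contrast = rng.uniform(1 - j, 1 + j, size=3)
        hsv = rgb2hsv(np.clip(px, 0, 1))
        hsv[..., 1] = np.clip(hsv[..., 1] * f_sat, 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * f_bright, 0, 1)
        px = hsv2rgb(hsv)
        px = np.clip((px - px.mean()) * f_contrast + px.mean(), 0, 1)

    return ImageRecord(pixels=px.astype(np.float32), animal_id=record.animal_id,
                       annotations=anns, name=record.name)


def expand_dataset(records: Sequence[ImageRecord], rng: np.random.Generator,
                   policy: AugmentPolicy = AugmentPolicy(),
                   factor: int = 2) -> List[ImageRecord]:
    """Offline augmentation: originals plus ``factor - 1`` perturbed copies.

    The alternative to on-the-fly augmentation — a fixed expanded dataset
    (e.g. factor 2 doubles the collection) that is then partitioned once.
    Copies keep their source's animal_id so identity-aware splitting
    still keeps every derived image with its original.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = list(records)
    for k in range(1, factor):
        for rec in records:
            aug = augment(rec, rng, policy)
            aug.name = f"{rec.name or rec.animal_id}_aug{k}"
            out.append(aug)
    return out


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _primary_class(rec: ImageRecord) -> Optional[int]:
    return rec.annotations[0][0] if rec.annotations else None


def partition_dataset(records: Sequence[ImageRecord],
                      fractions: Sequence[float],
                      seed: int = 42) -> SplitResult:
    """Animal-ID-exclusive stratified split into train/val/test.

    Whole identity groups are assigned, in seeded shuffle order, to the
    split with the largest remaining relative per-class quota deficit;
    per-class counts therefore track ``fractions`` to within one group,
    and identical seeds reproduce identical memberships.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.size != 3 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be three values summing to 1")
    if any(rec.animal_id == "" for rec in records):
        raise ValueError("every record needs an animal_id")

    groups: Dict[str, List[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.animal_id, []).append(i)

    # class totals and per-class distinct-animal support
    class_totals = np.zeros(NUM_CLASSES)
    animals_per_class: Dict[int, set] = {c: set() for c in range(NUM_CLASSES)}
    for rec in records:
        pc = _primary_class(rec)
        if pc is not None:
            class_totals[pc] += 1
            animals_per_class[pc].add(rec.animal_id)
    n_active = int((fractions > 0).sum())
    if len(groups) == 1:
        logger.warning("all records share one animal_id; identity exclusivity "
                       "forces a single non-empty split")
    else:
        for c in range(NUM_CLASSES):
            if class_totals[c] > 0 and len(animals_per_class[c]) < n_active:
                raise ValueError(
                    f"class {CLASS_NAMES[c]!r} has only "
                    f"{len(animals_per_class[c])} distinct animal(s) for "
                    f"{n_active} splits")

    quotas = fractions[:, None] * class_totals[None, :]  # (3, C)
    counts = np.zeros_like(quotas)
    assignment: Dict[str, int] = {}
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)
    for aid in order:
        gvec = np.zeros(NUM_CLASSES)
        unlabeled = 0
        for i in groups[aid]:
            pc = _primary_class(records[i])
            if pc is None:
                unlabeled += 1
            else:
                gvec[pc] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            rel_deficit = np.where(quotas > 0, (quotas - counts) / quotas, 0.0)
        score = (rel_deficit * gvec[None, :]).sum(axis=1)
        if gvec.sum() == 0:  # background-only group: balance by image count
            score = fractions - counts.sum(axis=1) / max(1, counts.sum())
        score = np.where(fractions > 0, score, -np.inf)
        s = int(np.argmax(score))
        assignment[aid] = s
        counts[s] += gvec

    splits: List[List[ImageRecord]] = [[], [], []]
    for i, rec in enumerate(records):
        splits[assignment[rec.animal_id]].append(rec)
    result = SplitResult(train=splits[0], val=splits[1], test=splits[2],
                         seed=seed, per_class_counts=counts.T.astype(int))
    _assert_no_leakage(result)
    return result


def _assert_no_leakage(split: SplitResult) -> None:
    ids = [set(r.animal_id for r in s) for s in (split.train, split.val, split.test)]
    for i in range(3):
        for j in range(i + 1, 3):
            common = ids[i] & ids[j]
            if common:
                raise AssertionError(f"animal leakage across splits: {common}")
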