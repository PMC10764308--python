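"""Image, mask, and manifest I/O plus retina geometry estimation.

Every geometric quantity downstream (ROI side, initial contour radius, line
profile length) is expressed as a fraction of the retina diameter ``D``, so
the geometry estimate is the reference frame for the whole pipeline.

Conventions: 0-based (row, col) coordinates; rectangular windows are
half-open ``[r0, r1) x [c0, c1)``; images are float64 RGB in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu

from .errors import FormatError, GeometryError, ImageIOError, ValidationError

LABELS = ("edematous", "non_edematous")

MASK_ROLES = ("vessel", "od_groundtruth", "od_predicted", "roi")


@dataclass
class FundusImage:
    """RGB fundus photograph with channel values in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3) float64
    path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError("FundusImage requires an (H, W, 3) array")
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise FormatError(f"image too small: {h}x{w} (minimum 64x64)")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise FormatError("channel values must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class RetinaGeometry:
    """Estimated retina center (row, col) and diameter D in pixels."""

    center: tuple[float, float]
    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise GeometryError("retina diameter must be positive")


@dataclass
class BinaryMask:
    """H x W {0,1} mask with a declared role."""

    pixels: np.ndarray
    role: str = "roi"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError("mask must be 2-D")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("mask values must be 0/1")
        self.pixels = self.pixels.astype(np.uint8)
        if self.role not in MASK_ROLES:
            raise FormatError(f"unknown mask role {self.role!r}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ManifestRecord:
    image_path: str
    label: str
    mask_path: str | None = None

    def __post_init__(self):
        if not self.image_path:
            raise ValidationError("empty image path in manifest")
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def load_image(path) -> FundusImage:
    """Read a PNG/TIFF/JPEG file as an RGB FundusImage in [0, 1].

    16-bit inputs are rescaled by the maximum representable value.
    Single-channel images are rejected: the pipeline needs color.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
            mode = im.mode
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageIOError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 2 or mode in ("L", "I", "I;16", "F", "1", "P"):
        raise FormatError(f"{path}: single-channel image; pipeline requires color")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float64) / 65535.0
    else:
        pixels = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return FundusImage(pixels=pixels, path=str(path))


def save_image(img: FundusImage, path) -> None:
    arr = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def save_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit PNG with values 0/255."""
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(path)


def load_mask(path, role: str = "od_groundtruth") -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot decode {path}: {exc}") from exc
    return BinaryMask(pixels=(arr > 127).astype(np.uint8), role=role)


def _min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Welzl's algorithm on the convex hull vertices of ``points``.

    ``points`` is (n, 2) float. Returns (center, radius).
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) == 0:
        raise GeometryError("no points for enclosing circle")
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear points: Welzl handles them directly

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, np.linalg.norm(a - c)

    def circle_three(a, b, c):
        # circumcircle; falls back to the widest pair if degenerate
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            pairs = [(a, b), (a, c), (b, c)]
            cands = [circle_two(p, q) for p, q in pairs]
            return max(cands, key=lambda cr: cr[1])
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        return center, np.linalg.norm(a - center)

    def in_circle(p, center, r):
        return np.linalg.norm(p - center) <= r + 1e-9

    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    shuffled = pts[order]

    center, r = shuffled[0], 0.0
    for i in range(1, len(shuffled)):
        p = shuffled[i]
        if in_circle(p, center, r):
            continue
        center, r = p, 0.0
        for j in range(i):
            q = shuffled[j]
            if in_circle(q, center, r):
                continue
            center, r = circle_two(p, q)
            for k in range(j):
                s = shuffled[k]
                if in_circle(s, center, r):
                    continue
                center, r = circle_three(p, q, s)
    return center, r


def estimate_retina_geometry(img: FundusImage) -> RetinaGeometry:
    """Estimate retina center and diameter D.

    Otsu-threshold the max-channel image, take the largest foreground
    component; center = its centroid, diameter = diameter of its minimum
    enclosing circle, capped at min(H, W).
    """
    maxchan = img.pixels.max(axis=2)
    if maxchan.max() <= 1e-6:
        raise GeometryError("all-dark image: no retina foreground")
    if maxchan.max() - maxchan.min() < 1e-6:
        fg = np.ones_like(maxchan, dtype=bool)
    else:
        thr = threshold_otsu(maxchan)
        fg = maxchan > thr
    if not fg.any():
        raise GeometryError("empty foreground after thresholding")
    labels, nlab = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, nlab + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    center = ndimage.center_of_mass(comp)
    # circle from the component boundary pixels only (cheap hull input)
    boundary = comp & ~ndimage.binary_erosion(comp)
    pts = np.argwhere(boundary).astype(np.float64)
    _, radius = _min_enclosing_circle(pts)
    h, w = comp.shape
    diameter = min(2.0 * radius + 1.0, float(min(h, w)))
    return RetinaGeometry(center=(float(center[0]), float(center[1])), diameter=diameter)


def read_manifest(path) -> DatasetManifest:
    """Read a CSV manifest with columns ``image,label[,mask]``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read manifest {path}: {exc}") from exc
    if "image" not in df.columns or "label" not in df.columns:
        raise ValidationError("manifest needs columns image,label[,mask]")
    records = []
    for _, row in df.iterrows():
        mask = row.get("mask")
        if mask is not None and (pd.isna(mask) or mask == ""):
            mask = None
        records.append(ManifestRecord(str(row["image"]), str(row["label"]), mask))
    return DatasetManifest(records=records)


def write_manifest(manifest: DatasetManifest, path) -> None:
    rows = [
        {"image": r.image_path, "label": r.label, "mask": r.mask_path or ""}
        for r in manifest.records
    ]
    pd.DataFrame(rows, columns=["image", "label", "mask"]).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as CSV, plus a JSON sidecar with the same rows."""
    path = Path(path)
    table.to_csv(path, index=False)
    json_path = path.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(table.to_dict(orient="records"), fh, indent=2, default=float)
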