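"""The 27 features separating edematous from non-edematous disks.

Four groups, computed on the contrast-enhanced ROI (texture and color), the
ROI-frame vessel and OD masks (vessel structure), and the full image (line
profile):

* 10 GLCM texture features (autocorrelation, contrast, correlation, cluster
  prominence, cluster shade, dissimilarity, energy, entropy, homogeneity,
  maximum probability) from a symmetric, offset-averaged gray-level
  co-occurrence matrix;
* 6 vessel features: the count of disjoint vessel components in the ROI
  (VDI) and within the segmented OD (VDIP), the largest and mean vessel
  component areas, and the standard deviation and kurtosis of the ROI
  intensity distribution — edema fragments vessels and flattens intensity
  statistics;
* 7 color features: gradient-norm sharpness, mean H/S/V, mean gray
  intensity, and mean a*/b* chromaticity;
* 4 intensity line-profile features: mean/min/max/std of the gray values
  along a horizontal segment of length D/2 through the OD center.

GLCM level indices are 1-based so autocorrelation does not degenerate at
level 0; entropy uses the natural log with 0*log0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

from .errors import FeatureError, RoiError
from .localization import ODLocation, VesselMap
from .preprocess import ROIPatch
from .retina_io import BinaryMask, FundusImage, RetinaGeometry

GLCM_FEATURE_NAMES = (
    "autoc", "contr", "corrp", "cprom", "cshad",
    "dissi", "energy", "entro", "homop", "maxpr",
)
VESSEL_FEATURE_NAMES = (
    "vdi", "vdip", "largest_vessel_area", "mean_vessel_area", "sigma", "kurtosis",
)
COLOR_FEATURE_NAMES = (
    "sharpness", "hue", "saturation", "brightness", "mean_intensity", "a_star", "b_star",
)
PROFILE_FEATURE_NAMES = ("profile_mean", "profile_min", "profile_max", "profile_std")

FEATURE_NAMES: tuple[str, ...] = (
    GLCM_FEATURE_NAMES + VESSEL_FEATURE_NAMES + COLOR_FEATURE_NAMES + PROFILE_FEATURE_NAMES
)
assert len(FEATURE_NAMES) == 27

#: ITU-R 601 luma weights, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class GLCMSpec:
    levels: int = 8
    offsets: tuple = ((0, 1), (1, 0), (1, 1), (1, -1))  # the 4 distance-1 directions
    symmetric: bool = True
    averaged: bool = True  # features averaged over offsets

    def __post_init__(self):
        if self.levels < 2:
            raise FeatureError("GLCM needs at least 2 gray levels")
        if any(dr == 0 and dc == 0 for dr, dc in self.offsets):
            raise FeatureError("zero offset is not a co-occurrence")


@dataclass
class GLCMatrix:
    """Normalized co-occurrence matrix with marginal moments (1-based levels)."""

    p: np.ndarray

    @property
    def _levels(self):
        return np.arange(1, self.p.shape[0] + 1, dtype=np.float64)

    @property
    def mu_x(self):
        return float(self._levels @ self.p.sum(axis=1))

    @property
    def mu_y(self):
        return float(self._levels @ self.p.sum(axis=0))

    @property
    def sigma_x(self):
        px = self.p.sum(axis=1)
        return float(np.sqrt(((self._levels - self.mu_x) ** 2) @ px))

    @property
    def sigma_y(self):
        py = self.p.sum(axis=0)
        return float(np.sqrt(((self._levels - self.mu_y) ** 2) @ py))


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of [0,1] values: floor(v*levels) capped at levels-1."""
    img = np.asarray(img, dtype=np.float64)
    return np.minimum((img * levels).astype(np.int64), levels - 1)


def compute_glcm(img: np.ndarray, spec: GLCMSpec, offset: tuple[int, int]) -> GLCMatrix:
    """Co-occurrence counts over all in-bounds pixel pairs at one offset."""
    q = quantize(img, spec.levels)
    h, w = q.shape
    dr, dc = offset
    if h <= abs(dr) or w <= abs(dc):
        raise FeatureError(f"image too small for offset {offset}")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((spec.levels, spec.levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise FeatureError("no pixel pairs for GLCM")
    return GLCMatrix(p=counts / total)


def glcm_features(G: GLCMatrix, names: tuple[str, ...] = GLCM_FEATURE_NAMES) -> dict[str, float]:
    """The requested co-occurrence statistics, with 1-based level indices.

    Correlation is undefined when a marginal variance vanishes (constant
    image); it raises rather than returning a silent zero.
    """
    p = G.p
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)[:, None]
    j = np.arange(1, n + 1, dtype=np.float64)[None, :]
    mu_x, mu_y = G.mu_x, G.mu_y
    sx, sy = G.sigma_x, G.sigma_y
    absdiff = np.abs(i - j)
    out = {}
    out["autoc"] = float(np.sum(i * j * p))
    out["contr"] = float(np.sum(absdiff**2 * p))
    if "corrp" in names:
        if sx * sy == 0:
            raise FeatureError("correlation undefined: zero marginal variance",
                               feature="corrp")
        out["corrp"] = float((np.sum(i * j * p) - mu_x * mu_y) / (sx * sy))
    out["cprom"] = float(np.sum((i + j - mu_x - mu_y) ** 4 * p))
    out["cshad"] = float(np.sum((i + j - mu_x - mu_y) ** 3 * p))
    out["dissi"] = float(np.sum(absdiff * p))
    out["energy"] = float(np.sum(p**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(p), 0.0)
    out["entro"] = float(-np.sum(p * logs))
    out["homop"] = float(np.sum(p / (1.0 + (i - j) ** 2)))
    out["maxpr"] = float(p.max())
    return {k: out[k] for k in names if k in out}


def glcm_feature_vector(img: np.ndarray, spec: GLCMSpec | None = None,
                        names: tuple[str, ...] = GLCM_FEATURE_NAMES) -> dict[str, float]:
    """GLCM features averaged over the configured offsets (or the first only)."""
    spec = spec or GLCMSpec()
    offsets = spec.offsets if spec.averaged else spec.offsets[:1]
    acc = {k: 0.0 for k in names}
    for off in offsets:
        feats = glcm_features(compute_glcm(img, spec, off), names)
        for k in names:
            acc[k] += feats[k]
    return {k: v / len(offsets) for k, v in acc.items()}


_S8 = ndimage.generate_binary_structure(2, 2)


def vessel_features(vm: VesselMap, od_mask: BinaryMask, roi_gray: np.ndarray) -> dict[str, float]:
    """Vessel-fragmentation counts plus ROI intensity sigma and kurtosis.

    Components are 8-connected. Kurtosis is the population fourth
    standardized moment (3 for a Gaussian); a constant ROI makes it
    undefined and raises.
    """
    vmask = vm.mask.pixels.astype(bool)
    if vmask.shape != od_mask.pixels.shape or vmask.shape != roi_gray.shape:
        raise FeatureError("vessel mask, OD mask and ROI must share the ROI frame")
    _, vdi = ndimage.label(vmask, _S8)
    _, vdip = ndimage.label(vmask & od_mask.pixels.astype(bool), _S8)
    labels, nlab = ndimage.label(vmask, _S8)
    if nlab:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, nlab + 1))
        largest = float(sizes.max())
        mean_area = float(vmask.sum() / nlab)
    else:
        largest = 0.0
        mean_area = 0.0
    x = np.asarray(roi_gray, dtype=np.float64).ravel()
    mu = x.mean()
    sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
    if sigma == 0:
        raise FeatureError("kurtosis undefined on a constant image", feature="kurtosis")
    kurt = float(np.mean((x - mu) ** 4) / sigma**4)
    return {
        "vdi": float(vdi),
        "vdip": float(vdip),
        "largest_vessel_area": largest,
        "mean_vessel_area": mean_area,
        "sigma": sigma,
        "kurtosis": kurt,
    }


def _gradient_sym(gray: np.ndarray):
    """Central-difference gradient with symmetric (reflective) borders."""
    padded = np.pad(gray, 1, mode="symmetric")
    gr = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gc = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return gr, gc


def color_features(roi_enhanced: ROIPatch) -> dict[str, float]:
    """Sharpness, HSV means, mean intensity, and a*/b* chroma means."""
    rgb = roi_enhanced.pixels
    gray = rgb @ _LUMA
    gr, gc = _gradient_sym(gray)
    sharpness = float(np.hypot(gr, gc).mean())
    hsv = color.rgb2hsv(rgb)
    lab = color.rgb2lab(rgb)
    return {
        "sharpness": sharpness,
        "hue": float(hsv[:, :, 0].mean()),
        "saturation": float(hsv[:, :, 1].mean()),
        "brightness": float(hsv[:, :, 2].mean()),
        "mean_intensity": float(gray.mean()),
        "a_star": float(lab[:, :, 1].mean()),
        "b_star": float(lab[:, :, 2].mean()),
    }


def line_profile_features(img: FundusImage, loc: ODLocation,
                          geom: RetinaGeometry) -> dict[str, float]:
    """Stats along a horizontal segment of length round(D/2) through the OD."""
    h, w = img.pixels.shape[:2]
    r, c = loc.center
    if not (0 <= r < h and 0 <= c < w):
        raise RoiError(f"OD location {loc.center} outside image")
    length = int(round(geom.diameter / 2.0))
    row = int(round(r))
    c0 = int(round(c - length / 2.0))
    cols = np.arange(c0, c0 + length)
    cols = cols[(cols >= 0) & (cols < w)]
    if cols.size == 0:
        raise RoiError("line profile entirely outside image")
    gray = img.pixels[row] @ _LUMA
    vals = gray[cols]
    return {
        "profile_mean": float(vals.mean()),
        "profile_min": float(vals.min()),
        "profile_max": float(vals.max()),
        "profile_std": float(vals.std()),  # population std
    }


@dataclass
class FeatureVector27:
    """The 27 named features in fixed order."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = [k for k in FEATURE_NAMES if k not in self.values]
        if missing:
            raise FeatureError(f"missing features: {missing}")
        bad = [k for k in FEATURE_NAMES if not np.isfinite(self.values[k])]
        if bad:
            raise FeatureError(f"non-finite features: {bad}", feature=bad[0])

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=np.float64)


def extract_all(img: FundusImage, geom: RetinaGeometry, loc: ODLocation,
                roi_enhanced: ROIPatch, od_mask: BinaryMask, vm: VesselMap,
                glcm_spec: GLCMSpec | None = None) -> FeatureVector27:
    """Assemble the full 27-vector; any undefined feature raises by name.

    GLCM and color features use the contrast-enhanced ROI (grayscale for
    GLCM); vessel features use ROI-frame masks with sigma/kurtosis on the ROI
    grayscale; line-profile features use the full image.
    """
    gray_roi = roi_enhanced.pixels @ _LUMA
    out: dict[str, float] = {}
    undefined: list[str] = []
    for compute in (
        lambda: glcm_feature_vector(np.clip(gray_roi, 0.0, 1.0), glcm_spec),
        lambda: vessel_features(vm, od_mask, gray_roi),
        lambda: color_features(roi_enhanced),
        lambda: line_profile_features(img, loc, geom),
    ):
        try:
            out.update(compute())
        except FeatureError as exc:
            undefined.append(exc.feature or str(exc))
    if undefined:
        raise FeatureError(
            f"undefined features on this input: {', '.join(undefined)}",
            feature=undefined[0],
        )
    return FeatureVector27(values=out)
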