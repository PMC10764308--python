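"""ROI extraction, contrast enhancement, and vessel removal.

The segmenter operates on a square region of interest (ROI) of side D/3
centered on the localized OD — wide enough to hold even a swollen disk whose
diameter exceeds the canonical D/6. Contrast is equalized adaptively on the
L channel of L*a*b*, and vessels are erased from the green channel by
harmonic inpainting: the masked pixels are replaced by the solution of the
discrete Laplace equation with the surrounding pixels as Dirichlet data,
which interpolates the disk surface smoothly through the vessel shadows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage import color, exposure

from .errors import FillError, RoiError
from .localization import ODLocation
from .retina_io import BinaryMask, FundusImage, RetinaGeometry

CLAHE_CLIP_LIMIT = 0.01
CLAHE_TILES = 8  # tile grid 8x8
VESSEL_SMOOTH_SIGMA = 1.5


@dataclass
class ROIPatch:
    """A square crop of the fundus image, with its placement recorded."""

    pixels: np.ndarray  # (h, w, 3) float64
    offset: tuple[int, int]  # (row0, col0) in the full image
    width_px: int  # requested side length round(D/3) before clipping
    clipped: bool = False

    @property
    def shape(self):
        return self.pixels.shape


def extract_roi(img: FundusImage, loc: ODLocation, geom: RetinaGeometry) -> ROIPatch:
    """Square window of side round(D/3) centered at the OD location.

    Windows extending past the image are clipped to its bounds and flagged.
    """
    h, w = img.pixels.shape[:2]
    r, c = loc.center
    if not (0 <= r < h and 0 <= c < w):
        raise RoiError(f"OD location {loc.center} outside image {h}x{w}")
    side = int(round(geom.diameter / 3.0))
    r0 = int(round(r - side / 2.0))
    c0 = int(round(c - side / 2.0))
    r1, c1 = r0 + side, c0 + side
    cr0, cc0 = max(r0, 0), max(c0, 0)
    cr1, cc1 = min(r1, h), min(c1, w)
    clipped = (cr0, cc0, cr1, cc1) != (r0, c0, r1, c1)
    return ROIPatch(
        pixels=img.pixels[cr0:cr1, cc0:cc1].copy(),
        offset=(cr0, cc0),
        width_px=side,
        clipped=clipped,
    )


def enhance_contrast(
    roi: ROIPatch, clip_limit: float = CLAHE_CLIP_LIMIT, tiles: int = CLAHE_TILES
) -> ROIPatch:
    """CLAHE on the L channel of L*a*b* (D65), back to RGB.

    Output shape equals input shape; a flat field passes through unchanged
    up to 8-bit quantization.
    """
    lab = color.rgb2lab(roi.pixels)
    L = lab[:, :, 0] / 100.0
    h, w = L.shape
    kernel = (max(1, h // tiles), max(1, w // tiles))
    if L.max() - L.min() < 1e-6:
        Leq = L  # flat field: equalization is the identity
    else:
        Leq = exposure.equalize_adapthist(
            np.clip(L, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
        )
    lab_eq = lab.copy()
    lab_eq[:, :, 0] = Leq * 100.0
    rgb = np.clip(color.lab2rgb(lab_eq), 0.0, 1.0)
    return ROIPatch(pixels=rgb, offset=roi.offset, width_px=roi.width_px, clipped=roi.clipped)


def fill_laplace(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by the discrete harmonic interpolant.

    Solves the 5-point Laplace equation on ``mask`` with the unmasked
    pixels as Dirichlet boundary (direct sparse solve). Masked pixels on the
    image border use only their in-bounds neighbors (reflecting boundary),
    which preserves the discrete maximum principle.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise FillError("mask and image shapes differ")
    if mask.all():
        raise FillError("mask covers the whole patch: no Dirichlet data")
    if not mask.any():
        return values.copy()
    h, w = values.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    rows, cols, data = [], [], []
    b = np.zeros(n)
    for k, (r, c) in enumerate(zip(ys, xs)):
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            if 0 <= r + dr < h and 0 <= c + dc < w
        ]
        rows.append(k)
        cols.append(k)
        data.append(float(len(nbrs)))
        for rr, cc in nbrs:
            j = idx[rr, cc]
            if j >= 0:
                rows.append(k)
                cols.append(j)
                data.append(-1.0)
            else:
                b[k] += values[rr, cc]
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    x = spsolve(A.tocsc(), b)
    out = values.copy()
    out[ys, xs] = x
    return out


def remove_vessels(roi: ROIPatch, vessels: BinaryMask) -> np.ndarray:
    """Vessel-free green channel of the ROI.

    The green channel is Gaussian-smoothed, the vessel mask is dilated by
    one pixel to cover anti-aliased vessel edges, and the masked region is
    harmonically filled from its surround.
    """
    green = roi.pixels[:, :, 1]
    if vessels.shape != green.shape:
        raise FillError("vessel mask must be cropped to the ROI frame")
    vmask = vessels.pixels.astype(bool)
    smoothed = ndimage.gaussian_filter(green, VESSEL_SMOOTH_SIGMA)
    if not vmask.any():
        return smoothed
    dilated = ndimage.binary_dilation(vmask, iterations=1)
    if dilated.all():
        raise FillError("dilated vessel mask covers the entire patch")
    return fill_laplace(smoothed, dilated)
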