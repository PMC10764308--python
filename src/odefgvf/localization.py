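"""Hybrid optic-disk localization from the vascular network (HLM).

The vessel tree is segmented with a multiscale Hessian ridge filter, then the
network's structural completeness decides the localizer: a *complete* network
drapes the main vessels in a horizontal parabola whose vertex marks the OD;
an *incomplete* network is a set of broken lines whose fitted straight lines
converge on the OD. A brightest-region centroid fallback (flagged, never
silent) keeps the pipeline total when both fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.morphology import skeletonize

from .errors import AssessmentError, ConvergenceError, FitError
from .retina_io import BinaryMask, FundusImage, RetinaGeometry

#: hysteresis thresholds on the [0,1]-normalized vesselness (ridge) response
VESSELNESS_LOW = 0.20
VESSELNESS_HIGH = 0.35
#: hysteresis thresholds on darkness below the local background (green channel)
DARKNESS_LOW = 0.06
DARKNESS_HIGH = 0.15
#: Gaussian scales: light denoise for width, heavier for the ridge detector,
#: and the large-scale background estimate the darkness is measured against
DENOISE_SIGMA = 0.4
RIDGE_PRESMOOTH_SIGMA = 1.5
BACKGROUND_SIGMA = 12.0
#: a network is complete when its largest skeleton component spans at least
#: this fraction of the retina diameter horizontally
COMPLETENESS_THRESHOLD = 0.5
#: segments shorter than this are dropped before line fitting
MIN_SEGMENT_LEN = 10


@dataclass
class VesselMap:
    mask: BinaryMask
    skeleton: BinaryMask
    segments: list = field(default_factory=list)  # list of [(row, col), ...]

    @property
    def empty(self) -> bool:
        return int(self.mask.pixels.sum()) == 0


@dataclass
class NetworkAssessment:
    status: str  # "complete" | "incomplete"
    largest_component_span_frac: float


@dataclass
class ODLocation:
    center: tuple[float, float]
    method_used: str  # "parabola" | "convergence" | "fallback"
    warning: bool = False


_S8 = ndimage.generate_binary_structure(2, 2)


def _skeleton_segments(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Split a skeleton into chains at branch points and return pixel chains."""
    nb = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), dtype=np.uint8),
                          mode="constant") - skel
    branch = skel & (nb >= 3)
    body = skel & ~branch
    labels, n = ndimage.label(body, _S8)
    segments = []
    for i in range(1, n + 1):
        pts = np.argwhere(labels == i)
        if len(pts) < 2:
            continue
        # order the chain by greedy nearest-neighbor walk from an endpoint
        pts_set = {tuple(p) for p in pts}
        deg = {}
        for p in pts_set:
            deg[p] = sum(
                (p[0] + dr, p[1] + dc) in pts_set
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
        start = min(pts_set, key=lambda p: (deg[p], p))
        chain = [start]
        seen = {start}
        cur = start
        while True:
            nxt = [
                (cur[0] + dr, cur[1] + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0) and (cur[0] + dr, cur[1] + dc) in pts_set
                and (cur[0] + dr, cur[1] + dc) not in seen
            ]
            if not nxt:
                break
            cur = min(nxt)
            chain.append(cur)
            seen.add(cur)
        segments.append(chain)
    return segments


def segment_vessels(img: FundusImage, geometry: RetinaGeometry) -> VesselMap:
    """Multiscale Hessian ridge vessel segmentation on the green channel.

    Vessel centerlines come from a Sato (dark-ridge) filter at scales
    {1, 2, 4} px, normalized by its 99.5th percentile inside the retina and
    hysteresis-thresholded; vessel *width* comes from a darkness test against
    a large-scale Gaussian background estimate, gated to lie near a detected
    ridge. The mask is thinned to a skeleton and split into chains at branch
    points.
    """
    green = img.pixels[:, :, 1]
    h, w = green.shape
    rr, cc = np.ogrid[:h, :w]
    retina = (rr - geometry.center[0]) ** 2 + (cc - geometry.center[1]) ** 2 <= (
        0.985 * geometry.diameter / 2.0
    ) ** 2

    response = sato(
        ndimage.gaussian_filter(green, RIDGE_PRESMOOTH_SIGMA),
        sigmas=(1, 2, 4), black_ridges=True, mode="reflect",
    )
    response[~retina] = 0.0
    scale = np.quantile(response[retina], 0.995) if retina.any() else 0.0
    if scale <= 0:
        empty = np.zeros((h, w), dtype=np.uint8)
        return VesselMap(BinaryMask(empty, "vessel"), BinaryMask(empty.copy(), "vessel"), [])
    ridge = apply_hysteresis_threshold(response / scale, VESSELNESS_LOW, VESSELNESS_HIGH)
    ridge &= retina

    smooth = ndimage.gaussian_filter(green, DENOISE_SIGMA)
    darkness = ndimage.gaussian_filter(smooth, BACKGROUND_SIGMA) - smooth
    dark = apply_hysteresis_threshold(darkness, DARKNESS_LOW, DARKNESS_HIGH)
    mask = dark & ndimage.binary_dilation(ridge, iterations=2) & retina
    if not mask.any():
        empty = np.zeros((h, w), dtype=np.uint8)
        return VesselMap(BinaryMask(empty, "vessel"), BinaryMask(empty.copy(), "vessel"), [])
    skel = skeletonize(mask)
    segments = _skeleton_segments(skel)
    return VesselMap(
        mask=BinaryMask(mask.astype(np.uint8), "vessel"),
        skeleton=BinaryMask(skel.astype(np.uint8), "vessel"),
        segments=segments,
    )


def assess_network(vm: VesselMap, geometry: RetinaGeometry) -> NetworkAssessment:
    """Complete iff the largest skeleton component spans >= half of D."""
    skel = vm.skeleton.pixels.astype(bool)
    if not skel.any():
        raise AssessmentError("empty skeleton: nothing to assess")
    labels, n = ndimage.label(skel, _S8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    cols = np.argwhere(comp)[:, 1]
    span = float(cols.max() - cols.min() + 1)
    frac = min(span / geometry.diameter, 1.0)
    status = "complete" if frac >= COMPLETENESS_THRESHOLD else "incomplete"
    return NetworkAssessment(status=status, largest_component_span_frac=frac)


def fit_parabola(skeleton_points) -> tuple[float, float]:
    """Least-squares fit of a horizontally opening parabola.

    Fits col = a*(row - k)^2 + h over the given (row, col) points and
    returns the vertex (k, h). The opening sign is free (nasal or temporal
    side). Exact on noiseless parabolic data.
    """
    pts = np.asarray(list(skeleton_points), dtype=np.float64)
    if len(pts) < 3:
        raise FitError("parabola fit needs at least 3 points")
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([r**2, r, np.ones_like(r)])
    gram = A.T @ A
    if np.linalg.cond(gram) > 1e12:
        raise FitError("degenerate normal equations (collinear rows?)")
    alpha, beta, gamma = np.linalg.solve(gram, A.T @ c)
    if abs(alpha) < 1e-12:
        raise FitError("points are collinear: no parabola vertex")
    k = -beta / (2.0 * alpha)
    hh = gamma - beta**2 / (4.0 * alpha)
    return (float(k), float(hh))


def _fit_parabola_robust(points, n_trials=400, inlier_tol=2.5, seed=0):
    """RANSAC parabola fit: the main arcade is the longest coherent parabola.

    Straight daughter branches violate the parabola model, so a plain least
    squares over the whole skeleton drags the vertex off the disk. Random
    3-point exact fits are scored by inlier count (|residual| <= inlier_tol
    px); the consensus set gets a final least-squares refinement. Seeded, so
    the result is deterministic.
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if len(pts) < 3:
        raise FitError("parabola fit needs at least 3 points")
    rng = np.random.default_rng(seed)
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([r**2, r, np.ones_like(r)])
    best_inliers = None
    best_count = -1
    for _ in range(n_trials):
        idx = rng.choice(len(pts), size=3, replace=False)
        sub = A[idx]
        try:
            coef = np.linalg.solve(sub, c[idx])
        except np.linalg.LinAlgError:
            continue
        resid = np.abs(A @ coef - c)
        inliers = resid <= inlier_tol
        n = int(inliers.sum())
        if n <= best_count:
            continue
        # a horizontal arcade has support on both sides of its vertex row
        if abs(coef[0]) > 1e-12:
            k = -coef[1] / (2.0 * coef[0])
            rin = r[inliers]
            above = int((rin > k).sum())
            if min(above, n - above) < 0.2 * n:
                continue
        best_count, best_inliers = n, inliers
    if best_inliers is None or best_count < 3:
        return fit_parabola(pts)
    # two refinement rounds on the consensus set
    current = best_inliers
    for _ in range(2):
        coef = np.linalg.lstsq(A[current], c[current], rcond=None)[0]
        resid = np.abs(A @ coef - c)
        new = resid <= inlier_tol
        if new.sum() < 3:
            break
        current = new
    return fit_parabola(pts[current])


def fit_line_convergence(segments) -> tuple[float, float]:
    """Point minimizing the sum of squared distances to per-segment TLS lines.

    Each segment gets a total-least-squares line (principal direction of its
    points); the minimizer solves the closed-form normal equations
    ``sum(n_i n_i^T) x = sum(n_i n_i^T p_i)`` with n_i the unit normal and
    p_i the segment centroid. Segments shorter than MIN_SEGMENT_LEN pixels
    are discarded first.
    """
    usable = [np.asarray(s, dtype=np.float64) for s in segments if len(s) >= 2]
    usable = [s for s in usable if len(s) >= MIN_SEGMENT_LEN] or usable
    if len(usable) < 2:
        raise ConvergenceError("need at least 2 segments")
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for pts in usable:
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]  # unit normal of the TLS line
        nn = np.outer(normal, normal)
        A += nn
        b += nn @ centroid
    if np.linalg.det(A) < 1e-8 * max(np.trace(A) ** 2, 1e-30):
        raise ConvergenceError("all lines (nearly) parallel: no convergence point")
    x = np.linalg.solve(A, b)
    return (float(x[0]), float(x[1]))


def _main_vessel_points(vessel_map: VesselMap) -> np.ndarray:
    """Skeleton points of the main (widest-caliber) vessels.

    The arcade whose vertex marks the OD is the thickest vessel in the
    network, so the parabola is fitted to the skeleton points of the largest
    connected component whose local caliber (twice the distance transform of
    the mask) is above the component's 60th caliber percentile. Falls back to
    the whole component if the width distribution is flat.
    """
    skel = vessel_map.skeleton.pixels.astype(bool)
    if not skel.any():
        raise FitError("empty skeleton")
    labels, n = ndimage.label(skel, _S8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    pts = np.argwhere(comp)
    width = 2.0 * ndimage.distance_transform_edt(vessel_map.mask.pixels.astype(bool))
    wvals = width[pts[:, 0], pts[:, 1]]
    thr = np.quantile(wvals, 0.6)
    main = pts[wvals >= thr]
    return main if len(main) >= 30 else pts


def _brightest_centroid(img: FundusImage, geometry: RetinaGeometry) -> tuple[float, float]:
    """Adaptive-threshold style fallback: centroid of the brightest region."""
    gray = img.pixels.max(axis=2)
    h, w = gray.shape
    rr, cc = np.ogrid[:h, :w]
    retina = (rr - geometry.center[0]) ** 2 + (cc - geometry.center[1]) ** 2 <= (
        0.95 * geometry.diameter / 2.0
    ) ** 2
    vals = gray[retina]
    thr = np.quantile(vals, 0.995)
    bright = (gray >= thr) & retina
    labels, n = ndimage.label(bright)
    if n == 0:
        return geometry.center
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    r0, c0 = ndimage.center_of_mass(comp)
    return (float(r0), float(c0))


def _clamp_to_retina(point, geometry: RetinaGeometry):
    r0, c0 = geometry.center
    v = np.array([point[0] - r0, point[1] - c0])
    rmax = 0.98 * geometry.diameter / 2.0
    n = np.linalg.norm(v)
    if n > rmax:
        v *= rmax / n
    return (float(r0 + v[0]), float(c0 + v[1]))


def localize_od(
    img: FundusImage, geometry: RetinaGeometry, vessel_map: VesselMap | None = None
) -> ODLocation:
    """Locate the OD: parabola vertex if the network is complete, line
    convergence if fragmented, brightest-centroid fallback otherwise."""
    if vessel_map is None:
        vessel_map = segment_vessels(img, geometry)
    try:
        assessment = assess_network(vessel_map, geometry)
        if assessment.status == "complete":
            comp_pts = _main_vessel_points(vessel_map)
            point = _fit_parabola_robust(comp_pts)
            method = "parabola"
        else:
            point = fit_line_convergence(vessel_map.segments)
            method = "convergence"
        return ODLocation(center=_clamp_to_retina(point, geometry), method_used=method)
    except (AssessmentError, FitError, ConvergenceError):
        point = _brightest_centroid(img, geometry)
        return ODLocation(center=_clamp_to_retina(point, geometry),
                          method_used="fallback", warning=True)
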