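"""Synthetic fundus phantoms with known optic-disk (OD) geometry.

A phantom is a dark frame holding a circular retina, a bright OD, and a
vessel tree converging on the OD. The two classes differ the way edematous
and non-edematous disks differ in real fundus photographs:

* non-edematous — a sharp, bright OD whose diameter is one-sixth of the
  retina diameter, a brighter central cup, grainy disk texture, and a
  complete vessel tree (one connected skeleton) shaped as a horizontal
  parabola with radial branches whose vertex sits on the OD;
* edematous — a larger OD with a Gaussian-blurred margin, reduced contrast
  against the retina, a smoother (lower-noise) surface, no visible cup, and
  a fragmented vessel tree (random gaps cut into the skeleton).

These contrasts are exactly what the downstream texture, vessel, color and
line-profile features are designed to pick up, so each stage of the pipeline
can be exercised and scored against the known masks without any downloads.
All randomness flows through one seeded generator per phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .retina_io import (
    BinaryMask,
    DatasetManifest,
    FundusImage,
    ManifestRecord,
    RetinaGeometry,
    save_image,
    save_mask,
    write_manifest,
)

# surface colors (RGB in [0,1])
_BACKGROUND = np.array([0.04, 0.03, 0.03])
_RETINA = np.array([0.58, 0.29, 0.11])
_OD_NORMAL = np.array([0.96, 0.83, 0.50])
_RIM = np.array([0.86, 0.58, 0.30])  # neuroretinal rim: redder than the disk
_CUP = np.array([1.00, 0.93, 0.64])
_VESSEL = np.array([0.25, 0.09, 0.05])


@dataclass
class PhantomSpec:
    """Parameters of one phantom; defaults give a non-edematous disk."""

    size: tuple[int, int] = (384, 384)
    retina_diameter_frac: float = 0.92
    od_center: tuple[float, float] | None = None  # default: retina center
    od_radius_frac: float = 1.0 / 12.0  # of retina diameter D (OD diameter D/6)
    edge_blur_sigma: float = 0.0
    od_contrast: float = 1.0  # 1 = full disk/retina contrast, <1 washed out
    noise_sigma: float = 0.035
    texture_amp: float = 0.055  # retina background micro-texture
    od_texture_amp: float = 0.10  # disk surface texture (cup rim, striations)
    vessel_completeness: float = 1.0
    illumination_tilt: float = 0.0  # peak fractional brightness tilt across D
    n_branches: int = 10
    class_label: str = "non_edematous"
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.size
        if h < 64 or w < 64:
            raise SpecError("phantom must be at least 64x64")
        if not 0 < self.retina_diameter_frac <= 1:
            raise SpecError("retina_diameter_frac must be in (0, 1]")
        if not 0 <= self.vessel_completeness <= 1:
            raise SpecError("vessel_completeness must be in [0, 1]")
        d = self.retina_diameter_frac * min(h, w)
        center = self.od_center or (h / 2.0, w / 2.0)
        rc = np.hypot(center[0] - h / 2.0, center[1] - w / 2.0)
        if rc + self.od_radius_frac * d > d / 2.0:
            raise SpecError("OD lies (partly) outside the retina")


def edematous_spec(**kwargs) -> PhantomSpec:
    """A PhantomSpec with edematous defaults (larger, blurred, washed out)."""
    defaults = dict(
        od_radius_frac=0.14,
        edge_blur_sigma=4.0,
        od_contrast=0.55,
        noise_sigma=0.025,
        texture_amp=0.03,
        od_texture_amp=0.04,
        vessel_completeness=0.4,
        illumination_tilt=0.14,
        class_label="edematous",
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@dataclass
class Phantom:
    image: FundusImage
    geometry: RetinaGeometry
    od_mask: BinaryMask
    vessel_mask: BinaryMask
    vessel_skeleton: BinaryMask
    od_center: tuple[float, float]
    label: str
    spec: PhantomSpec = field(repr=False, default=None)


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _oriented_texture(shape, rng, amp, sigma_along, sigma_across, angle_deg):
    """Anisotropically smoothed noise: a cheap oriented micro-texture."""
    noise = rng.standard_normal(shape)
    smoothed = ndimage.gaussian_filter(noise, (sigma_across, sigma_along))
    if angle_deg:
        smoothed = ndimage.rotate(smoothed, angle_deg, reshape=False, order=1, mode="reflect")
    s = smoothed.std()
    return amp * smoothed / (s if s > 0 else 1.0)


def _trace_chain(param_fn, t0, t1, step=0.35):
    """Rasterize a parametric curve into a deduplicated 8-connected pixel chain."""
    ts = np.arange(t0, t1 + step, step)
    pts = np.array([param_fn(t) for t in ts])
    pix = np.rint(pts).astype(int)
    chain, seen = [], set()
    for p in map(tuple, pix):
        if p not in seen:
            seen.add(p)
            chain.append(p)
    return chain


def _vessel_skeleton_chains(spec: PhantomSpec, geom: RetinaGeometry, od_center, rng):
    """Main horizontal parabola through the OD plus radial daughter branches.

    Branch start points lie exactly on the parabola so the full skeleton is a
    single connected component; each branch runs along the ray from the OD
    center through its start point, which is the convergence structure the
    hybrid localizer assumes for fragmented networks.
    """
    h, w = spec.size
    d = geom.diameter
    r0, c0 = od_center
    retina_r = d / 2.0 - 3.0
    rc, cc = geom.center
    # open toward the image side with more room; deep enough that the arcade
    # spans well over half the retina horizontally, as real arcades do
    a = (3.6 / d) * (1.0 if c0 <= cc else -1.0)

    def inside(p):
        return np.hypot(p[0] - rc, p[1] - cc) <= retina_r

    chains = []  # paired with per-chain caliber below; arcade first
    span = 0.42 * d
    para = _trace_chain(lambda t: (r0 + t, c0 + a * t * t), -span, span)
    para = [p for p in para if inside(p)]
    chains.append(para)

    # radial branches rooted on the parabola
    ts = np.linspace(-0.85 * span, 0.85 * span, spec.n_branches)
    ts += rng.uniform(-0.03, 0.03, size=len(ts)) * span
    for t in ts:
        start = np.array([r0 + t, c0 + a * t * t])
        direction = start - np.array([r0, c0])
        n = np.linalg.norm(direction)
        if n < 1.0:
            ang = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.sin(ang), np.cos(ang)])
        else:
            direction = direction / n
        length = rng.uniform(0.22, 0.45) * d
        br = _trace_chain(lambda s: tuple(start + s * direction), 0.0, length)
        chains.append([p for p in br if inside(p)])

    # nasal branches: rays rooted near the vertex, running opposite the
    # arcade's opening, as the nasal radial vessels do in a real fundus
    for _ in range(4):
        t = rng.uniform(-0.08, 0.08) * d
        start = np.array([r0 + t, c0 + a * t * t])
        ang = np.deg2rad(rng.uniform(-35.0, 35.0))
        direction = np.array([np.sin(ang), -np.sign(a) * np.cos(ang)])
        length = rng.uniform(0.25, 0.45) * d
        br = _trace_chain(lambda s: tuple(start + s * direction), 0.0, length)
        chains.append([p for p in br if inside(p)])
    return [c for c in chains if len(c) >= 2]


def _cut_gaps(chains, completeness, rng):
    """Delete (1 - completeness) of the skeleton pixels as random gaps."""
    if completeness >= 1.0:
        return chains
    total = sum(len(c) for c in chains)
    to_remove = int(round((1.0 - completeness) * total))
    keep = [np.ones(len(c), dtype=bool) for c in chains]
    removed = 0
    guard = 0
    while removed < to_remove and guard < 10_000:
        guard += 1
        i = int(rng.integers(len(chains)))
        n = len(chains[i])
        gap = int(rng.integers(5, 16))
        start = int(rng.integers(0, max(1, n - gap)))
        seg = keep[i][start : start + gap]
        removed += int(seg.sum())
        seg[:] = False
    out = []
    for c, k in zip(chains, keep):
        run = []
        for p, flag in zip(c, k):
            if flag:
                run.append(p)
            elif run:
                out.append(run)
                run = []
        if run:
            out.append(run)
    return [c for c in out if len(c) >= 2]


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom; bit-identical for identical spec (seed included)."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size
    d = spec.retina_diameter_frac * min(h, w)
    retina_center = (h / 2.0, w / 2.0)
    od_center = spec.od_center or retina_center
    od_radius = spec.od_radius_frac * d

    retina = _disk((h, w), retina_center, d / 2.0)
    od = _disk((h, w), od_center, od_radius)

    img = np.empty((h, w, 3))
    img[:] = _BACKGROUND
    img[retina] = _RETINA

    # retina micro-texture (horizontal grain)
    tex_bg = _oriented_texture((h, w), rng, spec.texture_amp, 3.0, 0.8, 0.0)
    img[retina] += tex_bg[retina, None]

    # OD layer via soft alpha so the edematous margin blurs smoothly
    alpha = od.astype(np.float64)
    if spec.edge_blur_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, spec.edge_blur_sigma)
    od_color = _RETINA + spec.od_contrast * (_OD_NORMAL - _RETINA)
    tex_od = _oriented_texture((h, w), rng, spec.od_texture_amp, 0.8, 0.8, 45.0)
    disk_layer = od_color[None, None, :] + tex_od[:, :, None]
    if spec.edge_blur_sigma > 0:
        # hyperemic mottling: smooth low-frequency brightness blotches over
        # the swollen disk (the stylized counterpart of congestion and
        # peripapillary hemorrhage), splitting its surface into a few gentle
        # intensity patches instead of one flat plateau
        blotch = ndimage.gaussian_filter(rng.standard_normal((h, w)), 10.0)
        blotch = blotch / max(blotch.std(), 1e-12)
        disk_layer = disk_layer * (1.0 + 0.16 * blotch)[:, :, None]
    img = img * (1 - alpha[:, :, None]) + disk_layer * alpha[:, :, None]

    if spec.edge_blur_sigma == 0:
        # healthy disk zonation: a redder neuroretinal rim around a very
        # bright central cup — the landmark structure edema obliterates
        rr2, cc2 = np.ogrid[:h, :w]
        dist = np.hypot(rr2 - od_center[0], cc2 - od_center[1]) / max(od_radius, 1.0)
        rim = (dist >= 0.65) & (dist <= 1.0)
        img[rim] = _RIM + tex_od[rim, None]
        cup = dist <= 0.55
        img[cup] = _CUP + tex_od[cup, None]

    geom = RetinaGeometry(center=retina_center, diameter=d)
    raw_chains = _vessel_skeleton_chains(spec, geom, od_center, rng)
    arcade_chains = _cut_gaps(raw_chains[:1], spec.vessel_completeness, rng)
    branch_chains = _cut_gaps(raw_chains[1:], spec.vessel_completeness, rng)
    chains = arcade_chains + branch_chains
    n_arcade = len(arcade_chains)

    # the main arcade is the thickest vessel (caliber ~4 px); daughter and
    # nasal branches are thinner (~2 px), as in a real fundus
    skel = np.zeros((h, w), dtype=np.uint8)
    arcade = np.zeros((h, w), dtype=bool)
    branches = np.zeros((h, w), dtype=bool)
    for ci, chain in enumerate(chains):
        target = arcade if ci < n_arcade else branches
        for r, cc_ in chain:
            if 0 <= r < h and 0 <= cc_ < w:
                skel[r, cc_] = 1
                target[r, cc_] = True
    s8 = ndimage.generate_binary_structure(2, 2)
    vessel = ndimage.binary_dilation(arcade, s8, iterations=2) | ndimage.binary_dilation(
        branches, s8, iterations=1
    )
    vessel &= retina
    vimg = img.copy()
    vimg[vessel] = _VESSEL
    # slightly feather vessel edges into the scene
    va = ndimage.gaussian_filter(vessel.astype(float), 0.6)[:, :, None]
    img = img * (1 - va) + vimg * va

    if spec.illumination_tilt:
        # uneven exposure, common in poor-quality edema photographs: a smooth
        # brightness tilt across the frame in a random direction
        ang = rng.uniform(0.0, 2 * np.pi)
        rr3, cc3 = np.mgrid[:h, :w].astype(np.float64)
        coord = ((rr3 - h / 2) * np.sin(ang) + (cc3 - w / 2) * np.cos(ang)) / d
        img *= (1.0 + spec.illumination_tilt * coord)[:, :, None]

    img += rng.normal(0.0, spec.noise_sigma, size=(h, w, 3))
    np.clip(img, 0.0, 1.0, out=img)

    return Phantom(
        image=FundusImage(pixels=img, path=f"phantom(seed={spec.rng_seed})"),
        geometry=geom,
        od_mask=BinaryMask((od & retina).astype(np.uint8), role="od_groundtruth"),
        vessel_mask=BinaryMask(vessel.astype(np.uint8), role="vessel"),
        vessel_skeleton=BinaryMask(skel, role="vessel"),
        od_center=tuple(map(float, od_center)),
        label=spec.class_label,
        spec=spec,
    )


# uniform ranges the edematous cohort draws from
EDEMA_RADIUS_FRAC_RANGE = (0.125, 0.155)
EDEMA_BLUR_RANGE = (3.0, 5.0)
EDEMA_CONTRAST_RANGE = (0.45, 0.65)
EDEMA_COMPLETENESS_RANGE = (0.25, 0.50)


def generate_cohort(
    n_edema: int, n_normal: int, seed: int, size: tuple[int, int] = (384, 384)
) -> tuple[list[Phantom], DatasetManifest]:
    """A reproducible cohort: per-phantom seeds derive from the cohort seed.

    Edematous phantoms draw radius/blur/contrast/fragmentation from the
    module-level uniform ranges; non-edematous disks keep the canonical
    D/6 diameter with a complete vessel tree. OD centers jitter a little
    around the retina center, as real disks sit near but not on it.
    """
    if n_edema < 0 or n_normal < 0:
        raise SpecError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = size
    d = 0.92 * min(h, w)
    phantoms = []
    records = []

    def jitter_center():
        dr = rng.uniform(-0.04, 0.04) * d
        dc = rng.uniform(-0.10, 0.10) * d
        return (h / 2.0 + dr, w / 2.0 + dc)

    for i in range(n_edema):
        sub = int(rng.integers(0, 2**31 - 1))
        spec = edematous_spec(
            size=size,
            od_center=jitter_center(),
            od_radius_frac=float(rng.uniform(*EDEMA_RADIUS_FRAC_RANGE)),
            edge_blur_sigma=float(rng.uniform(*EDEMA_BLUR_RANGE)),
            od_contrast=float(rng.uniform(*EDEMA_CONTRAST_RANGE)),
            vessel_completeness=float(rng.uniform(*EDEMA_COMPLETENESS_RANGE)),
            rng_seed=sub,
        )
        phantoms.append(generate_phantom(spec))
        records.append(ManifestRecord(f"edema_{i:03d}.png", "edematous", f"edema_{i:03d}_mask.png"))
    for i in range(n_normal):
        sub = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(size=size, od_center=jitter_center(), rng_seed=sub)
        phantoms.append(generate_phantom(spec))
        records.append(
            ManifestRecord(f"normal_{i:03d}.png", "non_edematous", f"normal_{i:03d}_mask.png")
        )
    return phantoms, DatasetManifest(records=records)


def write_cohort(phantoms, manifest, out_dir) -> Path:
    """Persist a cohort: images, OD masks, vessel masks, and manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ph, rec in zip(phantoms, manifest.records):
        save_image(ph.image, out / rec.image_path)
        save_mask(ph.od_mask, out / rec.mask_path)
        save_mask(ph.vessel_mask, out / (Path(rec.image_path).stem + "_vessels.png"))
    write_manifest(manifest, out / "manifest.csv")
    return out / "manifest.csv"
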