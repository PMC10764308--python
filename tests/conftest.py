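"""Shared fixtures: phantoms and pipeline stage outputs, computed once."""

import numpy as np
import pytest

from odefgvf.localization import ODLocation, VesselMap
from odefgvf.preprocess import extract_roi, remove_vessels
from odefgvf.retina_io import BinaryMask
from odefgvf.synth import PhantomSpec, edematous_spec, generate_phantom


def dice(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def roi_stage(phantom):
    """ROI, its offset, the cropped masks, and the vessel-free channel."""
    loc = ODLocation(center=phantom.od_center, method_used="parabola")
    roi = extract_roi(phantom.image, loc, phantom.geometry)
    r0, c0 = roi.offset
    hh, ww = roi.pixels.shape[:2]
    vessels = BinaryMask(phantom.vessel_mask.pixels[r0:r0 + hh, c0:c0 + ww], "vessel")
    skel = BinaryMask(phantom.vessel_skeleton.pixels[r0:r0 + hh, c0:c0 + ww], "vessel")
    od_gt = BinaryMask(phantom.od_mask.pixels[r0:r0 + hh, c0:c0 + ww], "od_groundtruth")
    vessel_free = remove_vessels(roi, vessels)
    seed_in_roi = (phantom.od_center[0] - r0, phantom.od_center[1] - c0)
    return {
        "roi": roi,
        "loc": loc,
        "vessels": vessels,
        "vessel_map": VesselMap(vessels, skel, []),
        "od_gt": od_gt,
        "vessel_free": vessel_free,
        "seed_in_roi": seed_in_roi,
    }


@pytest.fixture(scope="session")
def sharp_phantom():
    return generate_phantom(PhantomSpec(rng_seed=0))


@pytest.fixture(scope="session")
def blur_phantom():
    return generate_phantom(edematous_spec(rng_seed=0))


@pytest.fixture(scope="session")
def sharp_stage(sharp_phantom):
    return roi_stage(sharp_phantom)


@pytest.fixture(scope="session")
def blur_stage(blur_phantom):
    return roi_stage(blur_phantom)


@pytest.fixture(scope="session")
def fgvf_suite_results():
    """FGVF runs on 10 sharp + 10 blurred phantoms (shared by several tests)."""
    from odefgvf.fgvf import segment_od

    results = {"sharp": [], "blur": []}
    for kind, make in (("sharp", PhantomSpec), ("blur", edematous_spec)):
        for seed in range(10):
            ph = generate_phantom(make(rng_seed=seed))
            st = roi_stage(ph)
            mask, contour, diag = segment_od(st["vessel_free"], st["seed_in_roi"])
            results[kind].append({
                "dice": dice(mask, st["od_gt"].pixels),
                "diag": diag,
                "mask": mask,
            })
    return results
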