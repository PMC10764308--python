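"""End-to-end runner: localize -> ROI -> enhance -> vessel-remove -> FGVF ->
features -> (optionally) predict; plus the cohort-level experiment."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, evaluate
from .config import PipelineConfig
from .errors import OdefgvfError, PipelineError
from .features import GLCMSpec, FeatureVector27, extract_all
from .fgvf import segment_od
from .localization import ODLocation, VesselMap, localize_od, segment_vessels
from .preprocess import enhance_contrast, extract_roi, remove_vessels
from .retina_io import (
    BinaryMask,
    DatasetManifest,
    FundusImage,
    estimate_retina_geometry,
    load_image,
    load_mask,
)


@dataclass
class CaseResult:
    image_path: str
    od_location: tuple[float, float]
    localization_method: str
    od_mask: BinaryMask  # full-image frame
    features: FeatureVector27
    predicted_label: str | None
    decision_value: float | None
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    segmentation_diagnostics: dict = field(default_factory=dict)
    config_hash: str = ""


def _stage(name, fn, timings):
    t0 = time.perf_counter()
    try:
        out = fn()
    except OdefgvfError as exc:
        raise PipelineError(name, exc) from exc
    timings[name] = time.perf_counter() - t0
    return out


def run_case(
    image: FundusImage | str | Path,
    config: PipelineConfig | None = None,
    model: classify.TrainedModel | None = None,
) -> CaseResult:
    """Run the full per-image pipeline; any stage error names its stage."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    warnings: list[str] = []

    if not isinstance(image, FundusImage):
        image = _stage("load", lambda: load_image(image), timings)
    img = image

    geom = _stage("geometry", lambda: estimate_retina_geometry(img), timings)
    vm = _stage("vessels", lambda: segment_vessels(img, geom), timings)
    loc = _stage("localize", lambda: localize_od(img, geom, vm), timings)
    if loc.warning:
        warnings.append("localization fell back to brightest-region centroid")

    roi = _stage("roi", lambda: extract_roi(img, loc, geom), timings)
    if roi.clipped:
        warnings.append("ROI clipped at image boundary")
    roi_enh = _stage(
        "enhance",
        lambda: enhance_contrast(roi, config.clahe_clip_limit, config.clahe_tiles),
        timings,
    )
    r0, c0 = roi.offset
    hh, ww = roi.pixels.shape[:2]
    vcrop = BinaryMask(vm.mask.pixels[r0 : r0 + hh, c0 : c0 + ww], "vessel")
    vessel_free = _stage("vessel_removal", lambda: remove_vessels(roi, vcrop), timings)

    seed_in_roi = (loc.center[0] - r0, loc.center[1] - c0)
    mask_roi, contour, diag = _stage(
        "segment", lambda: segment_od(vessel_free, seed_in_roi, config.fgvf), timings
    )
    if not diag.get("converged", False):
        warnings.append("FGVF hit max_iters before contour convergence")
    full_mask = np.zeros(img.pixels.shape[:2], dtype=np.uint8)
    full_mask[r0 : r0 + hh, c0 : c0 + ww] = mask_roi
    od_mask = BinaryMask(full_mask, "od_predicted")

    glcm_spec = GLCMSpec(
        levels=config.glcm_levels,
        symmetric=config.glcm_symmetric,
        averaged=config.glcm_averaged,
    )
    vm_roi = VesselMap(mask=vcrop, skeleton=BinaryMask(
        vm.skeleton.pixels[r0 : r0 + hh, c0 : c0 + ww], "vessel"), segments=[])
    fv = _stage(
        "features",
        lambda: extract_all(img, geom, loc,
                            roi_enh, BinaryMask(mask_roi, "od_predicted"), vm_roi,
                            glcm_spec),
        timings,
    )

    predicted = None
    dec = None
    if model is not None:
        predicted, dec = _stage("predict", lambda: classify.predict(model, fv), timings)

    diag_out = {k: v for k, v in diag.items() if k != "phi"}
    return CaseResult(
        image_path=getattr(img, "path", ""),
        od_location=loc.center,
        localization_method=loc.method_used,
        od_mask=od_mask,
        features=fv,
        predicted_label=predicted,
        decision_value=dec,
        warnings=warnings,
        timings=timings,
        segmentation_diagnostics=diag_out,
        config_hash=config.content_hash(),
    )


@dataclass
class ExperimentReport:
    cases: list[CaseResult]
    failures: list[tuple[str, str]]  # (image, stage)
    localization: evaluate.LocalizationScore | None
    segmentation: dict | None
    classification: classify.CVResult | None
    config_hash: str = ""

    def summary(self) -> dict:
        out: dict = {"n_cases": len(self.cases), "n_failures": len(self.failures),
                     "config_hash": self.config_hash}
        if self.localization:
            out["acc_loc"] = self.localization.acc_loc
        if self.segmentation:
            out["segmentation"] = self.segmentation
        if self.classification:
            out["acc_classify"] = self.classification.pooled_accuracy
            out["fold_accuracies"] = self.classification.fold_accuracies
        return out


def run_experiment(
    manifest: DatasetManifest,
    config: PipelineConfig | None = None,
    seed: int = 0,
    base_dir: str | Path = ".",
    images: list[FundusImage] | None = None,
    gt_masks: list[BinaryMask] | None = None,
) -> ExperimentReport:
    """Per-case pipeline over a manifest, then the three score blocks.

    Images/masks may be passed in-memory (e.g. phantoms); otherwise they are
    loaded from the manifest paths relative to ``base_dir``.
    """
    config = config or PipelineConfig()
    base = Path(base_dir)
    cases: list[CaseResult] = []
    case_labels: list[str] = []
    case_masks: list[BinaryMask | None] = []
    failures: list[tuple[str, str]] = []
    for i, rec in enumerate(manifest.records):
        img = images[i] if images is not None else load_image(base / rec.image_path)
        if gt_masks is not None:
            gt = gt_masks[i]
        elif images is None and rec.mask_path:
            gt = load_mask(base / rec.mask_path)
        else:
            gt = None
        try:
            case = run_case(img, config=config)
        except PipelineError as exc:
            failures.append((rec.image_path, exc.stage))
            continue
        cases.append(case)
        case_labels.append(rec.label)
        case_masks.append(gt)
    if manifest.records and len(failures) > 0.5 * len(manifest.records):
        raise PipelineError("experiment", f"{len(failures)} of {len(manifest.records)} cases failed")

    loc_score = None
    seg_block = None
    have_masks = [m for m in case_masks if m is not None]
    if have_masks and len(have_masks) == len(cases):
        loc_score = evaluate.score_localization(
            [ODLocation(c.od_location, c.localization_method) for c in cases], have_masks
        )
        seg_scores = [
            evaluate.score_segmentation(c.od_mask, m) for c, m in zip(cases, case_masks)
        ]
        seg_block = evaluate.mean_scores(seg_scores)

    cls_result = None
    class_counts = [case_labels.count(l) for l in set(case_labels)]
    if len(set(case_labels)) == 2 and min(class_counts) >= config.cv_folds:
        table = classify.FeatureTable.from_vectors(
            [f"case_{i}" for i in range(len(cases))],
            [c.features for c in cases],
            case_labels,
        )
        cls_result = classify.cross_validate(table, k=config.cv_folds, seed=seed, C=config.svm_c)

    return ExperimentReport(
        cases=cases,
        failures=failures,
        localization=loc_score,
        segmentation=seg_block,
        classification=cls_result,
        config_hash=config.content_hash(),
    )
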