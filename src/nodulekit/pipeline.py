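"""End-to-end orchestration and evaluation metrics.

``run_pipeline`` chains the stages on one or more slices: lobe mask -> ROI
-> FCM nodule mask -> per-candidate features -> benign/malignant prediction,
returning a structured, versioned JSON-able report.  ``evaluate`` computes
the confusion counts and accuracy / sensitivity / specificity with
malignant as the positive class; a ratio whose denominator is zero is
reported as absent (None), never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage import measure

from .fcm import FCMConfig, segment_nodules
from .features import (FilterBankDescriptor, TextureConfig, backbone_features,
                       concat_features, statistical_features, texture_histogram)
from .phantom import PhantomSample
from .preprocess import extract_roi, segment_lobes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "EvalReport", "region_features",
           "feature_table", "run_pipeline", "evaluate", "match_detections"]

REPORT_SCHEMA = "nodulekit-report/1"


@dataclass(frozen=True)
class PipelineConfig:
    """Nested stage configuration; unknown keys are rejected by from_dict."""

    erosion_radius: int = 2
    closing_radius: int = 10
    keep_k: int = 2
    fcm: FCMConfig = field(default_factory=FCMConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    separation_threshold: float = 4.0
    opening_radius: int = 1
    min_region_pixels: int = 9
    iou_threshold: float = 0.3
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        fcm = FCMConfig(**payload.pop("fcm", {}))
        texture = TextureConfig(**payload.pop("texture", {}))
        known = set(cls.__dataclass_fields__) - {"fcm", "texture"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(fcm=fcm, texture=texture, **payload)


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    records: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def region_features(image: np.ndarray, region_mask: np.ndarray,
                    texture: TextureConfig | None = None,
                    backbone=None) -> np.ndarray:
    """Descriptor E of one candidate region.

    Backbone features are computed on the region's bounding-box crop (with
    a 2-px margin); statistical moments over the region's pixel values;
    texture histograms (LTP upper/lower and LOOP) over the region mask.
    """
    texture = texture or TextureConfig()
    backbone = backbone or FilterBankDescriptor()
    region_mask = np.asarray(region_mask) != 0
    if not region_mask.any():
        raise ValueError("empty region mask")
    rows = np.any(region_mask, axis=1).nonzero()[0]
    cols = np.any(region_mask, axis=0).nonzero()[0]
    r0, r1 = max(rows[0] - 2, 0), min(rows[-1] + 3, image.shape[0])
    c0, c1 = max(cols[0] - 2, 0), min(cols[-1] + 3, image.shape[1])
    crop = image[r0:r1, c0:c1]

    f_R = backbone_features(crop, backbone)
    st_R = statistical_features(image[region_mask])
    T_R = np.concatenate([
        texture_histogram(image, region_mask, kind, texture)
        for kind in ("ltp_upper", "ltp_lower", "loop")
    ])
    return concat_features(f_R, st_R, T_R).concatenated


def feature_table(samples: list[PhantomSample],
                  texture: TextureConfig | None = None,
                  backbone=None):
    """Per-nodule feature matrix and labels from ground-truth annotations.

    Returns ``(X, y)`` with y in {'benign', 'malignant'}, one row per
    annotated nodule.
    """
    X, y = [], []
    for sample in samples:
        for nod, label in zip(sample.nodule_masks, sample.labels):
            X.append(region_features(sample.image, nod, texture, backbone))
            y.append(label)
    return np.array(X), np.array(y)


def _segment_sample(image: np.ndarray, config: PipelineConfig):
    lobe = segment_lobes(image, config.erosion_radius, config.closing_radius,
                         config.keep_k)
    roi = extract_roi(image, lobe)
    nodules = segment_nodules(
        roi, lobe, config=config.fcm,
        separation_threshold=config.separation_threshold,
        opening_radius=config.opening_radius,
    )
    return lobe, roi, nodules


def run_pipeline(samples, model=None,
                 config: PipelineConfig | None = None) -> dict:
    """Detect and classify nodules in a batch of slices.

    ``samples`` is a list of 2-D arrays or :class:`PhantomSample` objects.
    Each detected connected component of at least ``min_region_pixels``
    becomes a detection record; when a fitted ``model`` is given, its label
    and malignancy probability are attached.  The run is a pure function of
    (inputs, config, model), so reports are reproducible.
    """
    config = config or PipelineConfig()
    report = {"schema": REPORT_SCHEMA, "images": []}
    for idx, sample in enumerate(samples):
        image = sample.image if isinstance(sample, PhantomSample) else np.asarray(sample)
        try:
            lobe, roi, nodules = _segment_sample(image, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at segmentation for image {idx}") from exc
        detections = []
        labeled = measure.label(nodules, connectivity=2)
        for region in measure.regionprops(labeled):
            if region.area < config.min_region_pixels:
                continue
            region_mask = labeled == region.label
            det = {
                "bbox": [int(v) for v in region.bbox],
                "area": int(region.area),
                "centroid": [float(v) for v in region.centroid],
            }
            if model is not None:
                E = region_features(image, region_mask, config.texture)
                proba = float(model.predict_proba(E[None, :])[0, 1])
                det["probability_malignant"] = proba
                det["label"] = str(model.predict(E[None, :])[0])
            detections.append(det)
        report["images"].append({
            "index": idx,
            "n_detections": len(detections),
            "lung_area": int(np.asarray(lobe).sum()),
            "detections": detections,
        })
    return report


def match_detections(pred_masks, true_masks, iou_threshold: float = 0.3):
    """Greedy IoU matching of predicted to ground-truth masks."""
    pairs = []
    used = set()
    for i, p in enumerate(pred_masks):
        p = np.asarray(p) != 0
        best_j, best_iou = None, iou_threshold
        for j, t in enumerate(true_masks):
            if j in used:
                continue
            t = np.asarray(t) != 0
            inter = np.logical_and(p, t).sum()
            union = np.logical_or(p, t).sum()
            iou = inter / union if union else 0.0
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            used.add(best_j)
            pairs.append((i, best_j, best_iou))
    return pairs


def evaluate(predictions, ground_truth, positive: str = "malignant") -> EvalReport:
    """Confusion counts and accuracy/sensitivity/specificity.

    ``predictions`` and ``ground_truth`` are equal-length aligned label
    sequences; ``positive`` names the positive class.
    """
    predictions = list(predictions)
    ground_truth = list(ground_truth)
    if not predictions or len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground_truth must be equal-length and non-empty")
    pred = np.array([p == positive for p in predictions])
    true = np.array([t == positive for t in ground_truth])
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))

    def ratio(num, den):
        return num / den if den else None

    records = [
        {"prediction": str(p), "truth": str(t)}
        for p, t in zip(predictions, ground_truth)
    ]
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        records=records,
    )
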