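"""End-to-end fracture detection and evaluation.

Orchestrates the full chain — conditioning, bone segmentation,
adaptive windowing, stationary-wavelet edge refinement, Otsu masking,
boundary tracing — aggregates per-window verdicts into per-bone
fracture sites and a slice-level call, and scores predictions against
ground truth.

Aggregation rule: within a bone, fractured windows are merged into
maximal runs over the circular landmark order (fracture *sites*); a
bone is fractured when some site spans at least ``min_consecutive``
windows, and a slice is fractured when any bone is.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import masking, tracing, wavelet, windows as win
from .config import PipelineConfig, config_hash
from .preprocess import denoise, remove_exterior_artifacts, stretch_contrast
from .segmentation import BoneRegion, extract_bone_regions
from .tracing import WindowVerdict

__all__ = [
    "SliceReport",
    "BoneReport",
    "EvalMetrics",
    "detect_fractures",
    "evaluate",
]

SCHEMA_VERSION = 1

log = logging.getLogger(__name__)


@dataclass
class BoneReport:
    bone_index: int
    area: int
    verdicts: list[WindowVerdict]
    fracture_sites: list[dict]  # {"start": lm, "end": lm, "length": n}
    fractured: bool
    region: BoneRegion = field(repr=False, default=None)


@dataclass
class SliceReport:
    bones: list[BoneReport]
    fractured: bool
    config: PipelineConfig
    image_id: str = ""

    def to_dict(self) -> dict:
        """JSON-serializable report (schema-versioned, config-hashed)."""
        return {
            "schema_version": SCHEMA_VERSION,
            "image_id": self.image_id,
            "config_hash": config_hash(self.config),
            "config": self.config.to_dict(),
            "fractured": self.fractured,
            "bones": [
                {
                    "bone_index": b.bone_index,
                    "area": b.area,
                    "fractured": b.fractured,
                    "fracture_sites": b.fracture_sites,
                    "windows": [
                        {
                            "landmark_index": v.landmark_index,
                            "boundary_count": v.boundary_count,
                            "fractured": v.fractured,
                            "empty": v.empty,
                        }
                        for v in b.verdicts
                    ],
                }
                for b in self.bones
            ],
        }


def _circular_runs(flags: list[bool]) -> list[dict]:
    """Maximal runs of True over a circular index range."""
    n = len(flags)
    if n == 0 or not any(flags):
        return []
    if all(flags):
        return [{"start": 0, "end": n - 1, "length": n}]
    runs = []
    for i in range(n):
        if flags[i] and not flags[(i - 1) % n]:  # run start
            j = i
            length = 0
            while flags[j % n]:
                length += 1
                j += 1
            runs.append({"start": i, "end": (j - 1) % n, "length": length})
    runs.sort(key=lambda r: r["start"])
    return runs


def analyze_window(window: win.AdaptiveWindow, config: PipelineConfig) -> WindowVerdict:
    """SWT -> masking -> tracing for a single scaled window.

    The edge map fed to masking is the combined level-3 detail
    magnitude; by default it is taken from the analysis coefficients,
    whose ridge peaks on the edge line, rather than from the
    reconstructed detail arrays, which are exactly zero there (see
    ``wavelet.coefficient_magnitude``).
    """
    scaled = window.scaled
    magnitude = wavelet.detail_magnitude(
        scaled, levels=config.swt_levels, source=config.detail_source
    )
    ew = masking.edge_window(
        magnitude,
        scaled,
        sigma_mask=config.mask_sigma,
        dilation_radius=config.mask_dilation,
        min_component_fraction=config.mask_min_component_fraction,
        border_margin=config.mask_border,
        detail_sigma=config.detail_sigma,
    )
    bridged = masking.bridge_breaks(ew.w_e, config.mask_closing)
    cleaned = tracing.remove_small_objects(bridged, config.small_object_fraction)
    boundaries = tracing.trace_boundaries(cleaned)
    return tracing.classify_window(
        boundaries,
        bone_index=window.geometry.bone_index,
        landmark_index=window.geometry.landmark_index,
    )


def detect_fractures(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "",
    regions: list[BoneRegion] | None = None,
) -> SliceReport:
    """Run the full detection chain on one slice.

    ``regions`` may supply externally segmented bones (mask + landmark
    sidecar route); otherwise the built-in intensity segmentation runs
    on the conditioned slice.  Deterministic for fixed image + config.
    """
    config = config or PipelineConfig()
    config.validate()

    t0 = time.perf_counter()
    conditioned = remove_exterior_artifacts(image, config.body_blob_min_fraction)
    conditioned = denoise(conditioned, config.gaussian_sigma)
    conditioned = stretch_contrast(conditioned, config.stretch_low, config.stretch_high)
    t1 = time.perf_counter()

    if regions is None:
        regions = extract_bone_regions(
            conditioned,
            bone_threshold=config.bone_threshold,
            min_bone_area=config.min_bone_area,
            n_landmarks=config.n_landmarks,
            close_radius=config.bone_close_radius,
        )
    t2 = time.perf_counter()
    log.debug(
        "%s: preprocess %.3f s, segmentation %.3f s, %d bones",
        image_id or "slice",
        t1 - t0,
        t2 - t1,
        len(regions),
    )

    bone_reports = []
    for region in regions:
        try:
            bone_windows = win.windows_for_bone(conditioned, region)
            verdicts = [analyze_window(w, config) for w in bone_windows]
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in bone {region.bone_index}: {exc}"
            ) from exc
        sites = [
            r
            for r in _circular_runs([v.fractured for v in verdicts])
            if r["length"] >= config.min_consecutive
        ]
        bone_reports.append(
            BoneReport(
                bone_index=region.bone_index,
                area=region.area,
                verdicts=verdicts,
                fracture_sites=sites,
                fractured=bool(sites),
                region=region,
            )
        )
    log.debug(
        "%s: window analysis %.3f s total", image_id or "slice", time.perf_counter() - t2
    )
    return SliceReport(
        bones=bone_reports,
        fractured=any(b.fractured for b in bone_reports),
        config=config,
        image_id=image_id,
    )


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float  # (TP+TN)/(TP+TN+FP+FN) x 100
    sensitivity: float  # TP/(TP+FN) x 100
    specificity: float  # TN/(TN+FP) x 100

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def summary(self) -> str:
        return (
            f"n={self.tp + self.fp + self.tn + self.fn}  "
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}\n"
            f"accuracy    {self.accuracy:8.4f} %\n"
            f"sensitivity {self.sensitivity:8.4f} %\n"
            f"specificity {self.specificity:8.4f} %"
        )


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> EvalMetrics:
    total = tp + fp + tn + fn
    pct = lambda num, den: 100.0 * num / den if den else float("nan")  # noqa: E731
    return EvalMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=pct(tp + tn, total),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
    )


def evaluate(reports: list, truth: list[bool]) -> EvalMetrics:
    """Slice-level confusion counts and percentage metrics.

    ``reports`` may be SliceReports or plain booleans; ``truth`` is the
    aligned list of ground-truth fracture labels.
    """
    if len(reports) != len(truth):
        raise ValueError(f"{len(reports)} reports vs {len(truth)} labels")
    preds = [r.fractured if isinstance(r, SliceReport) else bool(r) for r in reports]
    tp = sum(p and t for p, t in zip(preds, truth))
    fp = sum(p and not t for p, t in zip(preds, truth))
    tn = sum(not p and not t for p, t in zip(preds, truth))
    fn = sum(not p and t for p, t in zip(preds, truth))
    return metrics_from_counts(tp, fp, tn, fn)
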