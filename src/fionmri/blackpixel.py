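"""Muscle-normalized signal-intensity histograms and the black pixel count.

The in-vivo hypointensity statistic works entirely on ratios: every lesion
voxel's signal is divided by the mean signal of a muscle reference region of
the same acquisition (muscle is unaffected by the iron agent, so it cancels
scanner-to-scanner intensity fluctuations) and expressed in percent — the
normalized SI (nSI). The pre-injection acquisition defines a baseline
threshold (the minimum pre-injection nSI: below it no voxel falls without
agent on board); the black pixel count is the percentage of post-injection
lesion voxels strictly below that threshold. Lymph nodes with a black pixel
count over 20% are called metastatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EchoSeries, ROISet  # noqa: F401  (re-export)
from .errors import (
    DegenerateReferenceError,
    EmptyROIError,
    GridMismatchError,
    PipelineStageError,
)

#: Decision rule: a node with > 20% black pixels is called metastatic.
DEFAULT_RULE_THRESHOLD_PCT = 20.0

#: Muscle reference ROIs outside ~3-5 mm² on a slice deserve scrutiny.
MUSCLE_AREA_SANITY_MM2 = (3.0, 5.0)


@dataclass(frozen=True)
class NSIHistogram:
    """1%-wide histogram of lesion nSI; frequencies in % of lesion voxels."""

    bin_edges: np.ndarray  # length n_bins + 1, uniform width 1, starting at 0
    frequencies: np.ndarray  # % of total, sums to 100
    n_pixels: int


@dataclass(frozen=True)
class BlackPixelResult:
    threshold_nsi: float  # %
    black_pixel_pct: float
    n_black: int
    n_total: int
    timepoint: str = "post"


@dataclass(frozen=True)
class LNCall:
    black_pixel_pct: float
    call: str  # "metastatic" | "non-metastatic"
    rule_threshold: float = DEFAULT_RULE_THRESHOLD_PCT


@dataclass(frozen=True)
class LesionReport:
    """All intermediates of one pre/post lesion analysis."""

    muscle_ref_pre: float
    muscle_ref_post: float
    histogram_pre: NSIHistogram
    histogram_post: NSIHistogram
    threshold_nsi: float
    result: BlackPixelResult
    call: LNCall | None


def check_muscle_area(muscle_mask, voxel_area_mm2: float) -> float:
    """Warn when the muscle reference ROI leaves the 3-5 mm² sanity band.

    A reference that is much smaller is noise-dominated; much larger risks
    including non-muscle tissue. Returns the area (mm²); never raises.
    """
    area = float(np.count_nonzero(muscle_mask)) * float(voxel_area_mm2)
    lo, hi = MUSCLE_AREA_SANITY_MM2
    if not lo <= area <= hi:
        import warnings

        warnings.warn(
            f"muscle ROI area {area:.2f} mm² outside the {lo}-{hi} mm² "
            "sanity band",
            stacklevel=2,
        )
    return area


def _as_image(image) -> np.ndarray:
    if isinstance(image, EchoSeries):
        if image.n_echoes != 1:
            raise GridMismatchError("expected a single-echo acquisition")
        return image.data[0]
    return np.asarray(image, dtype=float)


def _check_mask(image: np.ndarray, mask) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise GridMismatchError(f"mask shape {mask.shape} != image {image.shape}")
    return mask


def muscle_reference(image, muscle_mask) -> float:
    """Mean SI over the muscle ROI of this acquisition.

    Pre- and post-injection images each use their own muscle reference.
    """
    img = _as_image(image)
    mask = _check_mask(img, muscle_mask)
    if not mask.any():
        raise EmptyROIError("muscle mask is empty")
    ref = float(img[mask].mean())
    if ref <= 0:
        raise DegenerateReferenceError(f"muscle reference {ref} is not positive")
    return ref


def normalize_si(image, lesion_mask, muscle_ref: float) -> np.ndarray:
    """Per-voxel nSI (%) = 100 * lesion SI / muscle reference.

    Voxels are pooled across all slices of the volume (the statistic is over
    the whole lesion, not per slice).
    """
    if muscle_ref <= 0:
        raise DegenerateReferenceError("muscle reference must be > 0")
    img = _as_image(image)
    mask = _check_mask(img, lesion_mask)
    if not mask.any():
        raise EmptyROIError("lesion mask is empty")
    return 100.0 * img[mask] / muscle_ref


def build_histogram(nsi_values) -> NSIHistogram:
    """Histogram of nSI values with fixed 1% bins [k, k+1) starting at 0."""
    vals = np.asarray(nsi_values, dtype=float)
    if vals.size == 0:
        raise EmptyROIError("no nSI values to histogram")
    if np.any(vals < 0):
        raise ValueError("nSI values must be >= 0")
    n_bins = max(1, int(np.ceil(vals.max())))
    if vals.max() == np.floor(vals.max()) and vals.max() > 0:
        n_bins += 1  # value on a bin edge belongs to the bin starting there
    edges = np.arange(n_bins + 1, dtype=float)
    counts = np.zeros(n_bins)
    idx = np.floor(vals).astype(int)
    np.add.at(counts, idx, 1.0)
    return NSIHistogram(
        bin_edges=edges,
        frequencies=100.0 * counts / vals.size,
        n_pixels=int(vals.size),
    )


def baseline_threshold(pre_nsi_values, q: float = 0.0) -> float:
    """Minimum (or, optionally, a low quantile of the) pre-injection nSI.

    ``q=0`` is the literal sample minimum — the faithful default; a small
    positive ``q`` trades faithfulness for robustness against a single dark
    baseline voxel (lower interpolation, i.e. an order statistic).
    """
    vals = np.asarray(pre_nsi_values, dtype=float)
    if vals.size == 0:
        raise EmptyROIError("no baseline nSI values")
    if not 0.0 <= q < 1.0:
        raise ValueError("quantile q must be in [0, 1)")
    if q == 0.0:
        return float(vals.min())
    return float(np.quantile(vals, q, method="lower"))


def black_pixel_count(
    post_nsi_values, threshold: float, timepoint: str = "post"
) -> BlackPixelResult:
    """Percentage of lesion voxels strictly below the baseline threshold."""
    vals = np.asarray(post_nsi_values, dtype=float)
    if vals.size == 0:
        raise EmptyROIError("no post-injection nSI values")
    n_black = int(np.count_nonzero(vals < threshold))
    return BlackPixelResult(
        threshold_nsi=float(threshold),
        black_pixel_pct=100.0 * n_black / vals.size,
        n_black=n_black,
        n_total=int(vals.size),
        timepoint=timepoint,
    )


def classify_ln(
    result: BlackPixelResult | float,
    rule_threshold: float = DEFAULT_RULE_THRESHOLD_PCT,
) -> LNCall:
    """Metastatic iff black pixel count is strictly over the rule threshold."""
    pct = result.black_pixel_pct if isinstance(result, BlackPixelResult) else float(result)
    call = "metastatic" if pct > rule_threshold else "non-metastatic"
    return LNCall(black_pixel_pct=pct, call=call, rule_threshold=rule_threshold)


def run_lesion_pipeline(
    pre_image,
    post_image,
    roi_pre: ROISet,
    roi_post: ROISet,
    *,
    quantile: float = 0.0,
    classify: bool = False,
    rule_threshold: float = DEFAULT_RULE_THRESHOLD_PCT,
) -> LesionReport:
    """Full pre/post analysis of one lesion.

    Composes muscle reference → nSI → baseline threshold (pre) → black pixel
    count (post) → optional lymph-node call, tagging any stage failure with
    the stage name. Each timepoint uses its own masks and muscle reference.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # re-raise with stage context
            raise PipelineStageError(name, exc) from exc

    ref_pre = stage("muscle_reference(pre)", muscle_reference, pre_image, roi_pre.muscle)
    ref_post = stage("muscle_reference(post)", muscle_reference, post_image, roi_post.muscle)
    nsi_pre = stage("normalize_si(pre)", normalize_si, pre_image, roi_pre.lesion, ref_pre)
    nsi_post = stage("normalize_si(post)", normalize_si, post_image, roi_post.lesion, ref_post)
    hist_pre = stage("build_histogram(pre)", build_histogram, nsi_pre)
    hist_post = stage("build_histogram(post)", build_histogram, nsi_post)
    thr = stage("baseline_threshold", baseline_threshold, nsi_pre, quantile)
    result = stage("black_pixel_count", black_pixel_count, nsi_post, thr)
    call = classify_ln(result, rule_threshold) if classify else None
    return LesionReport(
        muscle_ref_pre=ref_pre,
        muscle_ref_post=ref_post,
        histogram_pre=hist_pre,
        histogram_post=hist_post,
        threshold_nsi=thr,
        result=result,
        call=call,
    )
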