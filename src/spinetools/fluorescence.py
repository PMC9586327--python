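"""Spine-vs-shaft fluorescence enrichment factor.

For a neuron image expressing a fluorescently tagged protein, the image is
thresholded into a mask of the brightest spots (dendritic spines), the mean
intensity of the top-k brightest spots (k = 40 by default) is averaged into
mu_spine, the mean of a handful of manually selected dendritic-shaft regions
(5 by default) gives mu_shaft, and the per-neuron enrichment factor is

    EF_i = mu_spine,i / mu_shaft,i.

Group comparison (e.g. wild type vs. knockout) reports per-group mean, SEM
and the ratio of group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .errors import ValidationError


@dataclass
class Spot:
    """One connected supra-threshold component."""

    label: int
    mean_intensity: float
    area: int
    centroid: tuple[float, float]


@dataclass
class SpotSet:
    """Detected spots, sorted by descending mean intensity."""

    labels: np.ndarray
    spots: list[Spot]
    threshold: float

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean_intensity for s in self.spots])


@dataclass
class EnrichmentFactorRecord:
    """Per-image EF with its two means."""

    image_id: str
    mu_spine: float
    mu_shaft: float
    ef: float
    k_requested: int = 40
    k_used: int = 40


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    ratio_of_means: float


def detect_spots(
    img: np.ndarray,
    threshold: float,
    min_area: int = 2,
    dendrite_mask: np.ndarray | None = None,
) -> SpotSet:
    """Connected supra-threshold components (8-neighbourhood), brightest first.

    An empty result is returned with a warning, not an exception, when no
    component survives the threshold and area filter.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValidationError("image must be 2D")
    if not np.isfinite(img).all():
        raise ValidationError("image intensities must be finite")
    mask = img >= threshold
    if dendrite_mask is not None:
        dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
        if dendrite_mask.shape != img.shape:
            raise ValidationError("dendrite mask shape must match the image")
        mask &= dendrite_mask
    labels = measure.label(mask, connectivity=2)
    spots: list[Spot] = []
    for region in measure.regionprops(labels, intensity_image=img):
        if region.area < min_area:
            labels[labels == region.label] = 0
            continue
        spots.append(
            Spot(
                label=int(region.label),
                mean_intensity=float(region.intensity_mean),
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    spots.sort(key=lambda s: (-s.mean_intensity, s.label))
    if not spots:
        warnings.warn("no spot survives the threshold; empty SpotSet", stacklevel=2)
    return SpotSet(labels=labels, spots=spots, threshold=float(threshold))


def top_k_spot_mean(spots: SpotSet, k: int = 40) -> tuple[float, int]:
    """Mean of the k brightest per-spot means; (mu_spine, k_used).

    With fewer than k spots all are used and a warning records the shortfall.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(spots) == 0:
        raise ValidationError("cannot average spot intensities of an empty SpotSet")
    k_used = min(k, len(spots))
    if k_used < k:
        warnings.warn(f"only {k_used} spots available for top-{k} mean", stacklevel=2)
    return float(spots.means[:k_used].mean()), k_used


def shaft_mean(
    img: np.ndarray, rois: Sequence[np.ndarray], weighting: str = "equal"
) -> float:
    """Pooled dendritic-shaft mean over the ROI masks.

    ``weighting="equal"`` (default) averages the per-region means; ``"area"``
    pools all ROI pixels.  ROIs must be non-empty and pairwise disjoint.
    """
    img = np.asarray(img, dtype=float)
    if not rois:
        raise ValidationError("at least one shaft ROI is required")
    if weighting not in ("equal", "area"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    seen = np.zeros(img.shape, dtype=bool)
    means = []
    total = 0.0
    area = 0
    for i, roi in enumerate(rois):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != img.shape:
            raise ValidationError(f"ROI {i} shape must match the image")
        if not roi.any():
            raise ValidationError(f"ROI {i} is empty")
        if (seen & roi).any():
            raise ValidationError(f"ROI {i} overlaps an earlier ROI")
        seen |= roi
        vals = img[roi]
        means.append(float(vals.mean()))
        total += float(vals.sum())
        area += int(roi.sum())
    return float(np.mean(means)) if weighting == "equal" else total / area


def enrichment_factor(mu_spine: float, mu_shaft: float) -> float:
    """EF = mu_spine / mu_shaft; requires a positive shaft mean."""
    if mu_shaft <= 0:
        raise ValidationError("mu_shaft must be positive")
    return mu_spine / mu_shaft


def quantify_image(
    img: np.ndarray,
    threshold: float,
    shaft_rois: Sequence[np.ndarray],
    k: int = 40,
    min_area: int = 2,
    image_id: str = "image",
    dendrite_mask: np.ndarray | None = None,
) -> EnrichmentFactorRecord:
    """End-to-end EF for one image: detect spots, top-k mean, shaft mean, ratio."""
    spots = detect_spots(img, threshold, min_area=min_area, dendrite_mask=dendrite_mask)
    mu_spine, k_used = top_k_spot_mean(spots, k=k)
    mu_shaft = shaft_mean(img, shaft_rois)
    return EnrichmentFactorRecord(
        image_id=image_id,
        mu_spine=mu_spine,
        mu_shaft=mu_shaft,
        ef=enrichment_factor(mu_spine, mu_shaft),
        k_requested=k,
        k_used=k_used,
    )


def auto_shaft_rois(shaft_mask: np.ndarray, n: int = 5, size: int = 12) -> list[np.ndarray]:
    """Deterministically place ``n`` disjoint square ROIs inside a shaft mask.

    A synthetic-test convenience standing in for the manual shaft selection:
    squares of ``size`` pixels are spread evenly along the mask's bounding
    box, keeping only fully interior placements.
    """
    shaft_mask = np.asarray(shaft_mask, dtype=bool)
    if not shaft_mask.any():
        raise ValidationError("shaft mask is empty")
    rows, cols = np.nonzero(shaft_mask)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    rc = (r0 + r1) // 2
    xs = np.linspace(c0 + size, c1 - size, n).astype(int)
    rois = []
    for cx in xs:
        roi = np.zeros(shaft_mask.shape, dtype=bool)
        roi[rc - size // 2 : rc + size // 2, cx - size // 2 : cx + size // 2] = True
        if not (roi & ~shaft_mask).any():
            rois.append(roi)
    if len(rois) < n:
        raise ValidationError(f"could only place {len(rois)} of {n} ROIs inside the shaft")
    return rois


def compare_groups(
    records_a: Sequence[EnrichmentFactorRecord], records_b: Sequence[EnrichmentFactorRecord]
) -> GroupComparison:
    """Per-group mean +/- SEM of EF and the ratio of group means.

    SEM is NaN for a single-record group (documented convention).
    """
    if not records_a or not records_b:
        raise ValidationError("both groups need at least one record")

    def _stats(recs: Sequence[EnrichmentFactorRecord]) -> tuple[float, float]:
        efs = np.array([r.ef for r in recs], dtype=float)
        mean = float(efs.mean())
        sem = float(efs.std(ddof=1) / np.sqrt(len(efs))) if len(efs) > 1 else float("nan")
        return mean, sem

    mean_a, sem_a = _stats(records_a)
    mean_b, sem_b = _stats(records_b)
    return GroupComparison(
        mean_a=mean_a, sem_a=sem_a, mean_b=mean_b, sem_b=sem_b, ratio_of_means=mean_a / mean_b
    )
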