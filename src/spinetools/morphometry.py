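"""Semiautomated spine-apparatus (SA) detection and morphometry in 3D EM stacks.

The spine apparatus is a specialization of the smooth endoplasmic reticulum
found in a subset of dendritic spines: a stack of two or more closely apposed,
parallel, flat membrane cisterns.  This module implements the image-analysis
chain used to find and measure it in volume-EM stacks:

1. band-pass membrane enhancement with a difference-of-Gaussians (DoG) filter,
2. global thresholding into a binary mask,
3. seeded plane-to-plane tracking of a structure of interest, exploiting the
   physical continuity of the organelle across imaging planes,
4. interactive mask refinement (add/remove voxels),
5. cistern segmentation and the stacked-cistern classification rule,
6. distance-based contact-site detection against other organelle masks
   (plasma membrane, tubulovesicles), and
7. a PSD-first spine census (spines are anchored on their postsynaptic
   density before ER/SA presence is scored, to minimize selection bias).

Coordinates are 0-based ``(plane, row, col)``.  All physical distances are
computed in nanometres through the per-axis voxel size, so anisotropic voxels
are handled correctly.

EM contrast convention: membranes are *dark* on a bright background
(heavy-metal stain).  Callers who want membranes as positive DoG ridges should
invert the volume first (see :func:`dog_filter`'s ``invert`` flag).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    CensusError,
    RefinementError,
    SeedError,
    ValidationError,
)

ROLE_TAGS = frozenset({"ER", "PM", "PSD", "tubulovesicle", "SA-candidate"})

#: 3x3x3 structuring element = 26-neighbourhood in 3D.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 3x3 structuring element = 8-neighbourhood in 2D (the in-plane slice of 26).
STRUCT_8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EMVolume:
    """A 3D intensity stack with physical voxel sizes.

    Parameters
    ----------
    voxels
        Intensity grid indexed ``(plane, row, col)``.
    voxel_size_nm
        Physical edge length per axis ``(z, y, x)`` in nanometres.
    """

    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("EMVolume requires a 3D array")
        if min(self.voxels.shape) < 1:
            raise ValidationError("EMVolume dimensions must be >= 1")
        if len(self.voxel_size_nm) != 3 or any(s <= 0 for s in self.voxel_size_nm):
            raise ValidationError("voxel_size_nm must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class VoxelMask:
    """A binary occupancy grid with an organelle role tag."""

    data: np.ndarray
    role: str = "SA-candidate"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("VoxelMask requires a 3D array")
        if self.role not in ROLE_TAGS:
            raise ValidationError(f"unknown role tag {self.role!r}; allowed: {sorted(ROLE_TAGS)}")


@dataclass
class SeedSelection:
    """A manually selected 2D region in a single plane."""

    plane: int
    region: np.ndarray

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.ndim != 2:
            raise ValidationError("seed region must be 2D")
        if not self.region.any():
            raise ValidationError("seed region must be non-empty")


@dataclass
class TrackedObject:
    """A structure propagated plane-by-plane from a manual seed.

    ``plane_masks`` maps plane index to the union of selected 2D components in
    that plane; ``provenance`` records the seed and tracking parameters.
    """

    plane_masks: dict[int, np.ndarray]
    shape: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for p, m in self.plane_masks.items():
            out[p] = m
        return out

    @property
    def n_voxels(self) -> int:
        return int(sum(int(m.sum()) for m in self.plane_masks.values()))

    @property
    def planes(self) -> tuple[int, int]:
        ps = sorted(self.plane_masks)
        return ps[0], ps[-1]


@dataclass
class Cistern:
    """One 3D connected ER component with shape descriptors.

    ``eigenvalues`` are the principal-axis variances (nm^2) of the voxel
    coordinate scatter, ascending; ``normal`` is the unit eigenvector of the
    smallest eigenvalue; ``flatness`` is smallest/middle eigenvalue — near 0
    for a sheet, near 1 for a ball.
    """

    label: int
    coords_nm: np.ndarray
    n_voxels: int
    eigenvalues: np.ndarray
    normal: np.ndarray
    flatness: float
    centroid_nm: np.ndarray

    @property
    def is_flat_candidate(self) -> bool:
        return math.isfinite(self.flatness)


@dataclass
class SAAnnotation:
    """Per-spine SA classification and contact-site result."""

    spine_id: int
    is_sa: bool
    cistern_count: int
    pm_contact: bool = False
    pm_contact_voxels: list[tuple[int, int, int]] = field(default_factory=list)
    tv_contact: bool = False
    tv_contact_voxels: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_sa and self.cistern_count < 2:
            raise ValidationError("an SA must have at least two cisterns")
        if self.pm_contact != bool(self.pm_contact_voxels):
            raise ValidationError("pm_contact flag inconsistent with voxel list")
        if self.tv_contact != bool(self.tv_contact_voxels):
            raise ValidationError("tv_contact flag inconsistent with voxel list")


@dataclass
class SpineRecord:
    """Census entry for one spine (PSD-anchored)."""

    spine_id: int
    has_psd: bool
    has_er: bool
    has_sa: bool

    def __post_init__(self) -> None:
        if self.has_sa and not self.has_er:
            raise ValidationError("has_sa implies has_er")


@dataclass
class CensusResult:
    """Fractions over PSD-positive spines."""

    n_psd_spines: int
    frac_er: float
    frac_sa: float
    frac_sa_given_er: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_psd_spines": self.n_psd_spines,
                "frac_er": self.frac_er,
                "frac_sa": self.frac_sa,
                "frac_sa_given_er": self.frac_sa_given_er,
            }
        )


# ---------------------------------------------------------------------------
# filtering and thresholding
# ---------------------------------------------------------------------------


def dog_filter(
    vol: EMVolume,
    sigma_small: float | Sequence[float],
    sigma_large: float | Sequence[float],
    *,
    invert: bool = False,
) -> EMVolume:
    """Difference-of-Gaussians band-pass filter, G(sigma_small) - G(sigma_large).

    Boundary handling is edge replication.  With ``invert=True`` the volume is
    negated before filtering so that dark EM membranes produce positive
    ridges; the DoG of the constant offset vanishes, so no re-scaling is
    needed.
    """
    s1 = np.atleast_1d(np.asarray(sigma_small, dtype=float))
    s2 = np.atleast_1d(np.asarray(sigma_large, dtype=float))
    if np.any(s1 <= 0) or np.any(s2 <= 0) or not np.all(s1 < s2):
        raise ValidationError("require 0 < sigma_small < sigma_large (per axis)")
    data = np.asarray(vol.voxels, dtype=float)
    if invert:
        data = -data
    lo = ndimage.gaussian_filter(data, sigma=np.broadcast_to(s1, (3,)), mode="nearest")
    hi = ndimage.gaussian_filter(data, sigma=np.broadcast_to(s2, (3,)), mode="nearest")
    return EMVolume(lo - hi, vol.voxel_size_nm)


def threshold_mask(filtered: EMVolume, threshold: float, role: str = "SA-candidate") -> VoxelMask:
    """Binary mask where intensity >= threshold (inclusive convention)."""
    return VoxelMask(np.asarray(filtered.voxels) >= threshold, role=role)


# ---------------------------------------------------------------------------
# seeded tracking
# ---------------------------------------------------------------------------


def _label_planes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-connected 2D labeling of every plane; returns (labels, n per plane)."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    counts = np.zeros(mask.shape[0], dtype=np.int32)
    for p in range(mask.shape[0]):
        labels[p], counts[p] = ndimage.label(mask[p], structure=STRUCT_8)
    return labels, counts


def track_structure(
    mask: VoxelMask | np.ndarray,
    seed: SeedSelection,
    min_overlap: int = 1,
    *,
    provenance: Mapping | None = None,
) -> TrackedObject:
    """Track a seeded structure across parallel planes by continuity.

    Starting from the 2D connected component(s) of the threshold mask that
    intersect the manual seed region, the selection is propagated to adjacent
    planes: a candidate 2D component in plane ``p +/- 1`` is accepted when at
    least ``min_overlap`` of its voxels are 26-adjacent to (i.e. fall within
    the 3x3 in-plane dilation of) the current selection in plane ``p``.
    Propagation is bidirectional, accepts multiple qualifying components per
    plane (cisterns may fork), and iterates until no further component
    qualifies.  With ``min_overlap=1`` the result is exactly the 3D
    26-connected component of the mask containing the seed.
    """
    data = mask.data if isinstance(mask, VoxelMask) else np.asarray(mask, dtype=bool)
    if data.ndim != 3:
        raise ValidationError("mask must be 3D")
    if not (0 <= seed.plane < data.shape[0]):
        raise ValidationError(f"seed plane {seed.plane} outside volume with {data.shape[0]} planes")
    if seed.region.shape != data.shape[1:]:
        raise ValidationError("seed region shape must match the plane shape")
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")

    labels, _ = _label_planes(data)
    seed_labels = np.unique(labels[seed.plane][seed.region & data[seed.plane]])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise SeedError("seed region does not intersect the mask in the seed plane")

    # BFS over (plane, label) nodes of the component adjacency graph.
    selected: dict[int, set[int]] = {seed.plane: set(int(v) for v in seed_labels)}
    queue: deque[tuple[int, int]] = deque((seed.plane, int(v)) for v in seed_labels)
    n_planes = data.shape[0]
    while queue:
        plane, lab = queue.popleft()
        footprint = ndimage.binary_dilation(labels[plane] == lab, structure=STRUCT_8)
        for nb in (plane - 1, plane + 1):
            if not (0 <= nb < n_planes):
                continue
            cand = np.bincount(labels[nb][footprint].ravel())
            for nb_lab in np.nonzero(cand >= min_overlap)[0]:
                if nb_lab == 0:
                    continue
                bucket = selected.setdefault(nb, set())
                if int(nb_lab) not in bucket:
                    bucket.add(int(nb_lab))
                    queue.append((nb, int(nb_lab)))

    plane_masks = {p: np.isin(labels[p], sorted(labs)) for p, labs in sorted(selected.items())}
    prov = dict(provenance or {})
    prov.update({"seed_plane": seed.plane, "min_overlap": min_overlap})
    return TrackedObject(plane_masks=plane_masks, shape=data.shape, provenance=prov)


def refine_object(
    obj: TrackedObject,
    additions: np.ndarray | VoxelMask | None = None,
    removals: np.ndarray | VoxelMask | None = None,
) -> TrackedObject:
    """Apply manual mask edits: (object ∪ additions) \\ removals.

    Removals win over additions on conflict.  Raises
    :class:`~spinetools.errors.RefinementError` if the result is empty.
    """

    def _as_array(m) -> np.ndarray:
        if m is None:
            return np.zeros(obj.shape, dtype=bool)
        arr = m.data if isinstance(m, VoxelMask) else np.asarray(m, dtype=bool)
        if arr.shape != obj.shape:
            raise ValidationError("edit mask shape must match the object volume")
        return arr

    add = _as_array(additions)
    rem = _as_array(removals)
    new = (obj.mask() | add) & ~rem
    if not new.any():
        raise RefinementError("refinement would remove every voxel of the object")
    plane_masks = {p: new[p] for p in range(obj.shape[0]) if new[p].any()}
    prov = dict(obj.provenance)
    edits = list(prov.get("edits", []))
    edits.append({"added": int(add.sum()), "removed": int((obj.mask() & rem).sum())})
    prov["edits"] = edits
    return TrackedObject(plane_masks=plane_masks, shape=obj.shape, provenance=prov)


# ---------------------------------------------------------------------------
# cistern segmentation and SA classification
# ---------------------------------------------------------------------------


def segment_cisterns(
    er_mask: np.ndarray | VoxelMask,
    voxel_size_nm: Sequence[float],
    min_voxels: int = 5,
) -> list[Cistern]:
    """Split an ER mask into 3D 26-connected components with shape descriptors.

    Components smaller than ``min_voxels`` get ``flatness = inf`` (never flat).
    Flatness is the ratio of the smallest to the middle eigenvalue of the
    physical-coordinate covariance; the unit normal is the smallest-eigenvalue
    axis.
    """
    data = er_mask.data if isinstance(er_mask, VoxelMask) else np.asarray(er_mask, dtype=bool)
    if not data.any():
        raise ValidationError("ER mask is empty")
    vz = np.asarray(voxel_size_nm, dtype=float)
    labels, n = ndimage.label(data, structure=STRUCT_26)
    out: list[Cistern] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab).astype(float) * vz
        nvox = coords.shape[0]
        if nvox < min_voxels:
            eig = np.zeros(3)
            normal = np.array([1.0, 0.0, 0.0])
            flatness = math.inf
        else:
            cov = np.cov(coords.T)
            eigval, eigvec = np.linalg.eigh(cov)
            eigval = np.clip(eigval, 0.0, None)
            eig = eigval
            normal = eigvec[:, 0]
            flatness = float(eigval[0] / eigval[1]) if eigval[1] > 0 else math.inf
        out.append(
            Cistern(
                label=lab,
                coords_nm=coords,
                n_voxels=nvox,
                eigenvalues=eig,
                normal=normal / np.linalg.norm(normal),
                flatness=flatness,
                centroid_nm=coords.mean(axis=0),
            )
        )
    return out


def _normal_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = min(1.0, abs(float(np.dot(a, b))))
    return math.degrees(math.acos(cosang))


def _min_gap_nm(a: Cistern, b: Cistern) -> float:
    """Minimum voxel-centre distance between two components, in nm."""
    small, big = (a, b) if a.n_voxels <= b.n_voxels else (b, a)
    tree = cKDTree(big.coords_nm)
    d, _ = tree.query(small.coords_nm, k=1)
    return float(np.min(d))


def classify_sa(
    cisterns: Sequence[Cistern],
    gap_max_nm: float = 80.0,
    parallel_tol_deg: float = 30.0,
    flatness_max: float = 0.33,
) -> tuple[bool, int, list[int]]:
    """Apply the stacked-cistern SA definition.

    A spine contains an SA iff at least two of its ER components are flat
    (``flatness <= flatness_max``), pairwise parallel (normals within
    ``parallel_tol_deg``), and closely apposed (chained through pairwise
    minimum distances ``<= gap_max_nm``).  Returns
    ``(is_sa, cistern_count, member_labels)`` where ``cistern_count`` is the
    size of the largest qualifying group (1 if only a lone flat cistern
    exists, 0 if none).
    """
    flat = [c for c in cisterns if c.flatness <= flatness_max]
    if not flat:
        return False, 0, []
    # Graph over flat components; edge = parallel AND apposed.
    k = len(flat)
    adj: list[set[int]] = [set() for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if _normal_angle_deg(flat[i].normal, flat[j].normal) > parallel_tol_deg:
                continue
            if _min_gap_nm(flat[i], flat[j]) > gap_max_nm:
                continue
            adj[i].add(j)
            adj[j].add(i)
    best: list[int] = []
    seen: set[int] = set()
    for start in range(k):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        if len(comp) > len(best):
            best = comp
    members = sorted(flat[i].label for i in best)
    count = len(best)
    return count >= 2, count, members


def detect_contacts(
    sa_mask: np.ndarray | VoxelMask,
    other: np.ndarray | VoxelMask,
    voxel_size_nm: Sequence[float],
    contact_dist_nm: float = 30.0,
) -> list[tuple[int, int, int]]:
    """Voxels of ``other`` within ``contact_dist_nm`` of the SA mask.

    Distances are anisotropy-aware Euclidean distances between voxel centres
    in nanometres.  An empty list means no contact.
    """
    if contact_dist_nm <= 0:
        raise ValidationError("contact_dist_nm must be positive")
    sa = sa_mask.data if isinstance(sa_mask, VoxelMask) else np.asarray(sa_mask, dtype=bool)
    oth = other.data if isinstance(other, VoxelMask) else np.asarray(other, dtype=bool)
    if sa.shape != oth.shape:
        raise ValidationError("masks must be shape-compatible")
    if not sa.any() or not oth.any():
        return []
    vz = np.asarray(voxel_size_nm, dtype=float)
    sa_pts = np.argwhere(sa).astype(float) * vz
    oth_idx = np.argwhere(oth)
    tree = cKDTree(sa_pts)
    d, _ = tree.query(oth_idx.astype(float) * vz, k=1, distance_upper_bound=contact_dist_nm * (1 + 1e-12))
    hit = np.isfinite(d) & (d <= contact_dist_nm)
    return [tuple(int(v) for v in row) for row in oth_idx[hit]]


# ---------------------------------------------------------------------------
# spine census
# ---------------------------------------------------------------------------


def spine_census(records: Iterable[SpineRecord]) -> CensusResult:
    """PSD-first spine census.

    Only PSD-positive spines enter the denominator (spines are identified by
    their postsynaptic density before ER/SA content is scored).  Reports the
    fraction of spines with ER, with an SA, and the fraction of ER-positive
    spines with an SA.
    """
    recs = [r for r in records if r.has_psd]
    if not recs:
        raise CensusError("no PSD-positive spines: census denominator is empty")
    n = len(recs)
    n_er = sum(r.has_er for r in recs)
    n_sa = sum(r.has_sa for r in recs)
    return CensusResult(
        n_psd_spines=n,
        frac_er=n_er / n,
        frac_sa=n_sa / n,
        frac_sa_given_er=(n_sa / n_er) if n_er else float("nan"),
    )


def census_table(records: Iterable[SpineRecord]) -> pd.DataFrame:
    """Per-spine census flags as a DataFrame (one row per spine)."""
    return pd.DataFrame(
        [
            {"spine_id": r.spine_id, "has_psd": r.has_psd, "has_er": r.has_er, "has_sa": r.has_sa}
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# phantom annotation (end-to-end convenience over the generator's masks)
# ---------------------------------------------------------------------------


def annotate_spines(
    masks: Mapping[str, np.ndarray],
    spine_boxes: Sequence[tuple[int, tuple[slice, slice, slice]]],
    voxel_size_nm: Sequence[float],
    *,
    gap_max_nm: float = 80.0,
    parallel_tol_deg: float = 30.0,
    flatness_max: float = 0.33,
    contact_dist_nm: float = 30.0,
) -> list[SAAnnotation]:
    """Classify every spine of a segmented volume.

    ``masks`` maps role tags (``"ER"``, ``"PM"``, ``"tubulovesicle"``) to full
    binary volumes; ``spine_boxes`` lists ``(spine_id, bounding box)`` pairs.
    Within each box the ER is segmented into cisterns and the SA rule applied;
    contacts are then measured from the qualifying cistern group against the
    PM and tubulovesicle masks.
    """
    er = np.asarray(masks["ER"], dtype=bool)
    pm = np.asarray(masks.get("PM", np.zeros_like(er)), dtype=bool)
    tv = np.asarray(masks.get("tubulovesicle", np.zeros_like(er)), dtype=bool)
    out: list[SAAnnotation] = []
    for spine_id, box in spine_boxes:
        er_c = er[box]
        if not er_c.any():
            out.append(SAAnnotation(spine_id=spine_id, is_sa=False, cistern_count=0))
            continue
        cisterns = segment_cisterns(er_c, voxel_size_nm)
        is_sa, count, members = classify_sa(
            cisterns,
            gap_max_nm=gap_max_nm,
            parallel_tol_deg=parallel_tol_deg,
            flatness_max=flatness_max,
        )
        pm_vox: list[tuple[int, int, int]] = []
        tv_vox: list[tuple[int, int, int]] = []
        if is_sa:
            labels, _ = ndimage.label(er_c, structure=STRUCT_26)
            sa_mask = np.isin(labels, members)
            pm_vox = detect_contacts(sa_mask, pm[box], voxel_size_nm, contact_dist_nm)
            tv_vox = detect_contacts(sa_mask, tv[box], voxel_size_nm, contact_dist_nm)
        out.append(
            SAAnnotation(
                spine_id=spine_id,
                is_sa=is_sa,
                cistern_count=count,
                pm_contact=bool(pm_vox),
                pm_contact_voxels=pm_vox,
                tv_contact=bool(tv_vox),
                tv_contact_voxels=tv_vox,
            )
        )
    return out
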