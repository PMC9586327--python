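"""Ground-truth synthetic data for all four analysis stages.

Every generator is deterministic given its spec's ``seed`` (per-object
sub-streams are split with :meth:`numpy.random.Generator.spawn`) and returns
the planted truth alongside the data, so each downstream stage can be tested
for parameter recovery without any external dataset.

The four generators emulate, at desk scale:

* ``generate_em_phantom`` — a FIB-SEM-like 3D stack with spine compartments
  containing stacked flat ER cisterns (the spine apparatus), a dark plasma
  membrane shell, a PSD patch, and optional nearby tubulovesicles.  Membranes
  are dark on a bright background, matching heavy-metal-stained EM.
* ``generate_proteomics_table`` — spectral-count tables for a two-bait
  proximity-labeling comparison (bait vs. spatial-reference control), with
  negative-binomial counts, per-sample biotinylation efficiency acting on the
  exogenously biotinylated proteins, an optional per-sample loading factor
  acting on everything, and two endogenously biotinylated carboxylases as
  internal standards.
* ``generate_scrna_matrix`` — sparse gene-by-cell counts in which each gene
  has a chosen Pearson correlation with a reference gene, induced by a shared
  Gaussian latent factor with an exact analytic calibration.
* ``generate_fluor_image`` — a 2D fluorescence image with a dendritic-shaft
  band and bright non-overlapping spine spots at a planted spine/shaft
  intensity ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import PlacementError, SizingError, ValidationError

# ---------------------------------------------------------------------------
# EM phantom
# ---------------------------------------------------------------------------

#: Cistern-count distribution over {2..8} with median 3, matching the observed
#: range (two to eight cisterns, median three).
MEDIAN3_SAMPLER: dict[int, float] = {2: 0.25, 3: 0.30, 4: 0.20, 5: 0.12, 6: 0.08, 7: 0.03, 8: 0.02}

_SLAB_EXTENT = 10  # in-plane cistern extent, voxels
_LAT_MARGIN = 7  # lateral clearance between cistern stack and PM shell, voxels
_Z_MARGIN = 5  # axial clearance, voxels
_BACKGROUND = 200.0  # cytosol intensity
_MEMBRANE = 60.0  # membrane intensity (dark)
_FRAC_ER_NON_SA = 0.5  # single-cistern ER probability for spines without SA


@dataclass
class VolumePhantomSpec:
    """Parameters of the EM spine phantom.

    Fractions are Bernoulli probabilities per spine; ``cistern_count_sampler``
    maps a cistern count in {2..8} to its probability (an ``int`` means a
    degenerate sampler).
    """

    shape: tuple[int, int, int]
    n_spines: int = 25
    frac_sa: float = 0.5
    cistern_count_sampler: Mapping[int, float] | int = field(
        default_factory=lambda: dict(MEDIAN3_SAMPLER)
    )
    cistern_thickness_vox: int = 2
    cistern_gap_vox: int = 2
    frac_pm_contact: float = 0.83
    frac_tv_contact: float = 0.41
    noise_sigma: float = 0.0
    voxel_size_nm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sa", "frac_pm_contact", "frac_tv_contact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_spines < 1:
            raise ValidationError("n_spines must be >= 1")
        if self.cistern_thickness_vox < 1 or self.cistern_gap_vox < 1:
            raise ValidationError("cistern thickness and gap must be positive integers")
        if isinstance(self.cistern_count_sampler, int):
            self.cistern_count_sampler = {self.cistern_count_sampler: 1.0}
        counts = sorted(self.cistern_count_sampler)
        probs = np.array([self.cistern_count_sampler[c] for c in counts], dtype=float)
        if min(counts) < 2:
            raise ValidationError("cistern_count_sampler must be supported on integers >= 2")
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValidationError("cistern_count_sampler probabilities must be >= 0 and sum to 1")
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValidationError("shape must be three axes, each >= 8")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @property
    def max_cisterns(self) -> int:
        return max(self.cistern_count_sampler)  # type: ignore[arg-type]

    def box_shape(self) -> tuple[int, int, int]:
        """Per-spine compartment size implied by the cistern geometry."""
        t, g = self.cistern_thickness_vox, self.cistern_gap_vox
        stack_z = self.max_cisterns * t + (self.max_cisterns - 1) * g
        bz = stack_z + 2 * (_Z_MARGIN + 1)
        lat = _SLAB_EXTENT + 2 * (_LAT_MARGIN + 1)
        return (bz, lat, lat)


def plan_phantom_shape(
    n_spines: int,
    cistern_count_sampler: Mapping[int, float] | int | None = None,
    cistern_thickness_vox: int = 2,
    cistern_gap_vox: int = 2,
) -> tuple[int, int, int]:
    """Smallest convenient volume shape that fits ``n_spines`` compartments."""
    probe = VolumePhantomSpec(
        shape=(64, 64, 64),
        n_spines=1,
        cistern_count_sampler=(
            dict(MEDIAN3_SAMPLER) if cistern_count_sampler is None else cistern_count_sampler
        ),
        cistern_thickness_vox=cistern_thickness_vox,
        cistern_gap_vox=cistern_gap_vox,
    )
    bz, by, bx = probe.box_shape()
    nx = math.ceil(math.sqrt(n_spines))
    ny = math.ceil(n_spines / nx)
    return (bz, ny * by, nx * bx)


@dataclass
class PlantedSpine:
    """Ground truth for one phantom spine."""

    spine_id: int
    bbox: tuple[slice, slice, slice]
    has_psd: bool
    has_er: bool
    has_sa: bool
    cistern_count: int
    pm_contact: bool
    tv_contact: bool


def spine_truth_table(spines: Sequence[PlantedSpine]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spine_id": s.spine_id,
                "has_psd": s.has_psd,
                "has_er": s.has_er,
                "has_sa": s.has_sa,
                "cistern_count": s.cistern_count,
                "pm_contact": s.pm_contact,
                "tv_contact": s.tv_contact,
            }
            for s in spines
        ]
    )


def _draw_cistern_count(rng: np.random.Generator, sampler: Mapping[int, float]) -> int:
    counts = sorted(sampler)
    probs = np.array([sampler[c] for c in counts], dtype=float)
    return int(rng.choice(counts, p=probs / probs.sum()))


def generate_em_phantom(spec: VolumePhantomSpec):
    """Render the spine phantom.

    Returns ``(EMVolume, masks, spines)`` where ``masks`` maps role tags
    (``PM``, ``ER``, ``PSD``, ``tubulovesicle``) to binary volumes and
    ``spines`` is the list of :class:`PlantedSpine` ground-truth records.
    """
    from .morphometry import EMVolume  # local import to avoid a cycle

    bz, by, bx = spec.box_shape()
    nz, ny, nx = (spec.shape[0] // bz, spec.shape[1] // by, spec.shape[2] // bx)
    capacity = nz * ny * nx
    if capacity < spec.n_spines:
        per_axis = {"planes": nz, "rows": ny, "cols": nx}
        limiting = min(per_axis, key=per_axis.get)
        raise SizingError(
            f"shape {spec.shape} fits only {capacity} spine compartments of size "
            f"{(bz, by, bx)} but {spec.n_spines} were requested; "
            f"limiting dimension: {limiting}"
        )

    root = np.random.default_rng(spec.seed)
    streams = root.spawn(spec.n_spines + 1)
    noise_rng = streams[-1]

    pm = np.zeros(spec.shape, dtype=bool)
    er = np.zeros(spec.shape, dtype=bool)
    psd = np.zeros(spec.shape, dtype=bool)
    tv = np.zeros(spec.shape, dtype=bool)
    spines: list[PlantedSpine] = []

    t, g = spec.cistern_thickness_vox, spec.cistern_gap_vox
    for idx in range(spec.n_spines):
        rng = streams[idx]
        gz, rem = divmod(idx, ny * nx)
        gy, gx = divmod(rem, nx)
        z0, y0, x0 = gz * bz, gy * by, gx * bx
        box = (slice(z0, z0 + bz), slice(y0, y0 + by), slice(x0, x0 + bx))

        # PM shell: compartment boundary.
        shell = np.zeros((bz, by, bx), dtype=bool)
        shell[0, :, :] = shell[-1, :, :] = True
        shell[:, 0, :] = shell[:, -1, :] = True
        shell[:, :, 0] = shell[:, :, -1] = True

        # PSD patch: disc on the top face.
        psd_local = np.zeros_like(shell)
        cy, cx = by // 2, bx // 2
        yy, xx = np.ogrid[:by, :bx]
        psd_local[0] = (yy - cy) ** 2 + (xx - cx) ** 2 <= 3**2
        shell &= ~psd_local

        has_sa = rng.random() < spec.frac_sa
        has_er = has_sa or (rng.random() < _FRAC_ER_NON_SA)
        pm_contact = bool(has_sa and rng.random() < spec.frac_pm_contact)
        tv_contact = bool(has_sa and rng.random() < spec.frac_tv_contact)
        k = _draw_cistern_count(rng, spec.cistern_count_sampler) if has_sa else (1 if has_er else 0)

        er_local = np.zeros_like(shell)
        tv_local = np.zeros_like(shell)
        if k:
            stack_z = k * t + (k - 1) * g
            zs = (bz - stack_z) // 2
            ys = (by - _SLAB_EXTENT) // 2
            xs = (bx - _SLAB_EXTENT) // 2
            mid = k // 2
            for c in range(k):
                cz0 = zs + c * (t + g)
                x_hi = xs + _SLAB_EXTENT
                if pm_contact and c == mid:
                    x_hi = bx - 2  # reach within ~2 voxels of the +x shell face
                er_local[cz0 : cz0 + t, ys : ys + _SLAB_EXTENT, xs:x_hi] = True
            if tv_contact:
                # small vesicle 2 voxels from the -y face of the stack
                bc = np.array([zs + stack_z // 2, ys - 4, xs + _SLAB_EXTENT // 2])
                zzz, yyy, xxx = np.ogrid[:bz, :by, :bx]
                tv_local = (zzz - bc[0]) ** 2 + (yyy - bc[1]) ** 2 + (xxx - bc[2]) ** 2 <= 2**2

        pm[box] |= shell
        psd[box] |= psd_local
        er[box] |= er_local
        tv[box] |= tv_local
        spines.append(
            PlantedSpine(
                spine_id=idx,
                bbox=box,
                has_psd=True,
                has_er=bool(has_er),
                has_sa=bool(has_sa),
                cistern_count=int(k if has_sa else k),
                pm_contact=pm_contact,
                tv_contact=tv_contact,
            )
        )

    intensity = np.full(spec.shape, _BACKGROUND, dtype=np.float32)
    membranes = pm | er | psd | tv
    intensity[membranes] = _MEMBRANE
    if spec.noise_sigma > 0:
        intensity = intensity + noise_rng.normal(0.0, spec.noise_sigma, spec.shape).astype(
            np.float32
        )
    vol = EMVolume(intensity, spec.voxel_size_nm)
    masks = {"PM": pm, "ER": er, "PSD": psd, "tubulovesicle": tv}
    return vol, masks, spines


# ---------------------------------------------------------------------------
# proximity-proteomics spectral counts
# ---------------------------------------------------------------------------


@dataclass
class ProteomicsSimSpec:
    """Parameters of the spectral-count simulation.

    ``dispersion`` is the negative-binomial overdispersion (variance =
    mu + dispersion * mu^2); 0 degenerates to Poisson.  ``efficiency_range``
    is the per-sample multiplicative biotinylation-efficiency interval applied
    to all *exogenously* biotinylated proteins; the two endogenously
    biotinylated internal-control proteins are independent of it.
    ``depth_log_sd`` adds a lognormal per-sample loading factor shared by all
    proteins, controls included — the component internal-standard
    normalization can remove.
    """

    n_proteins: int = 2000
    n_bait: int = 4
    n_ctrl: int = 3
    frac_enriched: float = 0.05
    log2_fc: float = 2.0
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    efficiency_range: tuple[float, float] = (1.0, 1.0)
    depth_log_sd: float = 0.0
    control_ids: tuple[str, str] = ("Pcca", "Pc")
    control_baseline: float = 500.0
    baseline_log_sd: float = 0.0
    seed: int = 0
    #: seed for choosing WHICH proteins are enriched; defaults to ``seed``.
    #: Two experiments sharing an ``enriched_seed`` probe the same biology
    #: with independent measurement noise.
    enriched_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bait < 2 or self.n_ctrl < 2:
            raise ValidationError("replicate counts must be >= 2 per group")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi):
            raise ValidationError("efficiency_range must be within (0, inf) with lo <= hi")
        if len(self.control_ids) != 2 or len(set(self.control_ids)) != 2:
            raise ValidationError("exactly two distinct control_ids are required")
        if not 0.0 <= self.frac_enriched <= 1.0:
            raise ValidationError("frac_enriched must be in [0, 1]")
        if self.dispersion < 0 or self.baseline_mean <= 0 or self.control_baseline <= 0:
            raise ValidationError("dispersion must be >= 0 and baselines positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_proteomics_table(spec: ProteomicsSimSpec):
    """Simulate a two-group iBioID spectral-count table.

    Returns ``(PeptideCountTable, enriched_ids)`` where ``enriched_ids`` is
    the list of truly bait-enriched protein ids.
    """
    from .enrichment import PeptideCountTable  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    truth_rng = (
        rng if spec.enriched_seed is None else np.random.default_rng(spec.enriched_seed)
    )
    n = spec.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    n_enriched = round(spec.frac_enriched * n)
    enriched_idx = (
        truth_rng.choice(n, size=n_enriched, replace=False)
        if n_enriched
        else np.array([], dtype=int)
    )
    enriched = np.zeros(n, dtype=bool)
    enriched[enriched_idx] = True

    # per-protein baseline abundance (lognormal dynamic range around the mean)
    if spec.baseline_log_sd > 0:
        base = spec.baseline_mean * np.exp(
            rng.normal(-0.5 * spec.baseline_log_sd**2, spec.baseline_log_sd, n)
        )
    else:
        base = np.full(n, spec.baseline_mean)

    samples = [f"bait_{i + 1}" for i in range(spec.n_bait)] + [
        f"ctrl_{i + 1}" for i in range(spec.n_ctrl)
    ]
    groups = {s: ("bait" if s.startswith("bait") else "control") for s in samples}
    n_samples = len(samples)
    eff = rng.uniform(spec.efficiency_range[0], spec.efficiency_range[1], n_samples)
    depth = (
        np.exp(rng.normal(0.0, spec.depth_log_sd, n_samples))
        if spec.depth_log_sd > 0
        else np.ones(n_samples)
    )

    fc = 2.0**spec.log2_fc
    counts = np.empty((n + 2, n_samples), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base * (fc if groups[s] == "bait" else 1.0) ** enriched
        counts[:n, j] = _nb_draw(rng, mu * eff[j] * depth[j], spec.dispersion)
        # endogenously biotinylated carboxylases: abundant, well measured,
        # independent of exogenous biotinylation efficiency
        counts[n:, j] = rng.poisson(spec.control_baseline * depth[j], 2)

    frame = pd.DataFrame(counts, index=protein_ids + list(spec.control_ids), columns=samples)
    table = PeptideCountTable(
        counts=frame, groups=groups, experiment_id=f"sim-{spec.seed}", control_ids=spec.control_ids
    )
    return table, [protein_ids[i] for i in sorted(enriched_idx)]


# ---------------------------------------------------------------------------
# single-cell count matrix with planted gene-gene correlation
# ---------------------------------------------------------------------------


@dataclass
class ScrnaSimSpec:
    """Parameters of the correlated single-cell count simulation.

    Counts are Poisson-lognormal: gene *g* gets a latent
    ``y_g = w_g z + sqrt(1 - w_g^2) eps`` sharing the reference gene's factor
    ``z``, and counts are ``Poisson(mu_g exp(s y_g - s^2/2))``.  The latent
    weight ``w_g`` is chosen so the *count-scale* Pearson correlation equals
    ``target_r`` exactly in expectation (see :func:`latent_weight_for_r`).
    ``target_r = 1`` is realized as an exact copy of the reference counts.
    """

    n_cells: int
    target_r: Mapping[str, float]
    ref_gene_id: str = "Synpo"
    mean_expression: float | Mapping[str, float] = 3.0
    latent_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValidationError("n_cells must be >= 3")
        for gene, r in self.target_r.items():
            if not -1.0 <= r <= 1.0:
                raise ValidationError(f"|target_r| must be <= 1 (gene {gene}: {r})")
        if self.ref_gene_id in self.target_r:
            raise ValidationError("target_r must not include the reference gene")
        if self.latent_sigma <= 0:
            raise ValidationError("latent_sigma must be positive")

    def mean_of(self, gene: str) -> float:
        if isinstance(self.mean_expression, Mapping):
            return float(self.mean_expression[gene])
        return float(self.mean_expression)


def _pln_var(mu: float, s: float) -> float:
    """Variance of a Poisson-lognormal count with mean mu and log-sd s."""
    return mu + mu**2 * (math.exp(s**2) - 1.0)


def attainable_r_range(mu_ref: float, mu_gene: float, s: float) -> tuple[float, float]:
    """Count-scale correlation reachable by the latent-factor construction."""
    denom = math.sqrt(_pln_var(mu_ref, s) * _pln_var(mu_gene, s))
    scale = mu_ref * mu_gene / denom
    return (scale * (math.exp(-(s**2)) - 1.0), scale * (math.exp(s**2) - 1.0))


def latent_weight_for_r(target_r: float, mu_ref: float, mu_gene: float, s: float) -> float:
    """Invert the exact count-scale correlation of the Poisson-lognormal pair.

    cov(c_ref, c_g) = mu_ref mu_g (exp(s^2 w) - 1) and the count variances are
    mu + mu^2 (exp(s^2) - 1), so r(w) is known in closed form and strictly
    increasing in w; this solves r(w) = target_r for w.
    """
    lo, hi = attainable_r_range(mu_ref, mu_gene, s)
    if not lo <= target_r <= hi:
        raise ValidationError(
            f"target_r={target_r} outside attainable range [{lo:.3f}, {hi:.3f}] "
            f"for mean expression ({mu_ref}, {mu_gene}) and latent sigma {s}"
        )
    denom = math.sqrt(_pln_var(mu_ref, s) * _pln_var(mu_gene, s))
    return math.log1p(target_r * denom / (mu_ref * mu_gene)) / s**2


def generate_scrna_matrix(spec: ScrnaSimSpec):
    """Simulate the gene-by-cell count matrix.

    Returns a :class:`~spinetools.coexpression.CellCountMatrix` whose first
    row is the reference gene followed by the target genes in spec order.
    """
    from .coexpression import CellCountMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    s = spec.latent_sigma
    n = spec.n_cells
    z = rng.standard_normal(n)
    mu_ref = spec.mean_of(spec.ref_gene_id)
    lam_ref = mu_ref * np.exp(s * z - 0.5 * s**2)
    ref_counts = rng.poisson(lam_ref)

    genes = [spec.ref_gene_id] + list(spec.target_r)
    rows = [ref_counts]
    for gene in list(spec.target_r):
        r = float(spec.target_r[gene])
        if r == 1.0:
            rows.append(ref_counts.copy())
            continue
        mu_g = spec.mean_of(gene)
        w = latent_weight_for_r(r, mu_ref, mu_g, s)
        y = w * z + math.sqrt(max(0.0, 1.0 - w**2)) * rng.standard_normal(n)
        rows.append(rng.poisson(mu_g * np.exp(s * y - 0.5 * s**2)))

    X = sparse.csr_matrix(np.vstack(rows))
    cells = [f"cell_{i}" for i in range(n)]
    return CellCountMatrix(X=X, gene_ids=genes, cell_ids=cells)


# ---------------------------------------------------------------------------
# fluorescence image with planted spine/shaft ratio
# ---------------------------------------------------------------------------


@dataclass
class FluorSimSpec:
    """Parameters of the spine-fluorescence phantom.

    The dendritic shaft is a horizontal band at ``shaft_intensity``; spines
    are disjoint discs at ``shaft_intensity * target_ef``; Gaussian noise is
    added everywhere.
    """

    shape: tuple[int, int] = (512, 512)
    n_spots: int = 60
    target_ef: float = 5.1
    shaft_intensity: float = 100.0
    spot_radius: int = 4
    shaft_halfwidth: int = 16
    noise_sigma: float = 2.0
    background: float = 5.0
    seed: int = 0
    max_tries_per_spot: int = 200

    def __post_init__(self) -> None:
        if self.target_ef <= 0:
            raise ValidationError("target_ef must be positive")
        if self.n_spots < 1:
            raise ValidationError("n_spots must be >= 1")
        if self.spot_radius < 1 or self.shaft_halfwidth < 1:
            raise ValidationError("spot_radius and shaft_halfwidth must be >= 1")
        if len(self.shape) != 2 or min(self.shape) < 8 * self.spot_radius:
            raise ValidationError("image shape too small for the requested spot radius")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def generate_fluor_image(spec: FluorSimSpec):
    """Render the fluorescence phantom.

    Returns ``(image, centers, shaft_mask)``: a float image, the planted spot
    centres as an ``(n, 2)`` integer array, and the boolean shaft-band mask.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), spec.background, dtype=float)

    row_mid = h // 2
    shaft = np.zeros((h, w), dtype=bool)
    shaft[row_mid - spec.shaft_halfwidth : row_mid + spec.shaft_halfwidth, :] = True
    img[shaft] = spec.shaft_intensity

    r = spec.spot_radius
    margin = r + 2
    # candidate rows above and below the shaft band, clear of it and the border
    lo_rows = (margin, row_mid - spec.shaft_halfwidth - margin)
    hi_rows = (row_mid + spec.shaft_halfwidth + margin, h - margin)
    centers: list[tuple[int, int]] = []
    min_sep2 = (2 * r + 3) ** 2
    for _ in range(spec.n_spots):
        for _try in range(spec.max_tries_per_spot):
            band = lo_rows if rng.random() < 0.5 else hi_rows
            if band[1] <= band[0]:
                band = hi_rows if band is lo_rows else lo_rows
            if band[1] <= band[0]:
                raise PlacementError("no room outside the shaft band for spots")
            cy = int(rng.integers(band[0], band[1]))
            cx = int(rng.integers(margin, w - margin))
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep2 for py, px in centers):
                centers.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place spot {len(centers) + 1}/{spec.n_spots} "
                f"after {spec.max_tries_per_spot} tries"
            )
    yy, xx = np.ogrid[:h, :w]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = spec.shaft_intensity * spec.target_ef
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, (h, w))
    return img, np.array(centers, dtype=int), shaft
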