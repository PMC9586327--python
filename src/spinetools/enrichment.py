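"""Differential enrichment statistics for two-bait in vivo proximity labeling.

A promiscuous biotin ligase fused to a bait protein biotinylates its
~10 nm neighbourhood in vivo; biotinylated proteins are purified and counted
by mass spectrometry.  Comparing the proximity proteome of the bait of
interest against a spatial-reference bait maps which proteins are enriched
near the bait.  The statistics implemented here:

* per-protein enrichment ratio of group mean spectral counts (bait / control),
* a two-sample Student's t test (pooled variance, two-sided) with the
  significance rule p < alpha AND ratio > 1 (alpha defaults to 0.1),
* internal-standard normalization: each sample's counts are divided by the
  summed counts of two endogenously biotinylated carboxylases
  (propionyl-CoA carboxylase alpha chain and pyruvate carboxylase), which
  report sample loading independently of exogenous biotinylation, and
* directional overlap of the significant sets of two experiments.

Degenerate zero-variance proteins follow a documented convention: equal group
means give p = 1; unequal means with zero pooled variance give a p = 0
sentinel.  A Benjamini-Hochberg q-value column is emitted for reference but
never used for the significance call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, ValidationError

RESULT_COLUMNS = [
    "mean_bait",
    "mean_ctrl",
    "ratio",
    "t_stat",
    "p_value",
    "q_value",
    "significant",
]


@dataclass
class PeptideCountTable:
    """Protein-by-sample spectral counts with group labels.

    ``counts`` is indexed by protein id with one column per sample; ``groups``
    maps each sample to ``"bait"`` or ``"control"``.  A protein absent from a
    sample is a count of 0.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]
    experiment_id: str = "exp"
    control_ids: tuple[str, str] = ("Pcca", "Pc")
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        bad = {g for g in self.groups.values()} - {"bait", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for grp in ("bait", "control"):
            if len(self.samples(grp)) < 2:
                raise ValidationError(f"need >= 2 samples in group {grp!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    def is_control(self) -> pd.Series:
        return pd.Series(self.counts.index.isin(self.control_ids), index=self.counts.index)


@dataclass
class EnrichmentResult:
    """Per-protein enrichment statistics."""

    protein_id: str
    mean_bait: float
    mean_ctrl: float
    ratio: float
    t_stat: float
    p_value: float
    significant: bool
    alpha: float = 0.1


@dataclass
class ExperimentResult:
    """Ordered result table plus the significant set for one experiment."""

    experiment_id: str
    mode: str
    alpha: float
    results: pd.DataFrame
    significant: set[str] = field(default_factory=set)


def normalize_by_endogenous(
    table: PeptideCountTable, control_ids: Sequence[str] | None = None
) -> PeptideCountTable:
    """Divide each sample by its summed internal-control counts.

    Both control proteins must be present with a positive summed count in
    every sample; otherwise a :class:`NormalizationError` names the offending
    sample.  Control rows are retained untouched (they stay flagged through
    ``control_ids``); the input table is not modified.
    """
    controls = tuple(control_ids) if control_ids is not None else table.control_ids
    if len(controls) != 2:
        raise ValidationError("exactly two internal-control protein ids are required")
    missing = [c for c in controls if c not in table.counts.index]
    if missing:
        raise NormalizationError(f"control protein(s) absent from table: {missing}")
    ctrl_counts = table.counts.loc[list(controls)]
    for s in table.counts.columns:
        if (ctrl_counts[s] <= 0).any() and ctrl_counts[s].sum() <= 0:
            raise NormalizationError(f"control protein counts sum to zero in sample {s!r}")
        if (ctrl_counts[s] < 0).any():
            raise NormalizationError(f"negative control counts in sample {s!r}")
        if ctrl_counts[s].sum() <= 0:
            raise NormalizationError(f"control protein counts sum to zero in sample {s!r}")
    factors = ctrl_counts.sum(axis=0)
    zero = factors[factors <= 0]
    if len(zero):
        raise NormalizationError(f"control protein counts sum to zero in sample {zero.index[0]!r}")
    normalized = table.counts.div(factors, axis=1)
    normalized.loc[list(controls)] = table.counts.loc[list(controls)]
    return replace(table, counts=normalized, control_ids=controls, normalized=True)


def enrichment_ratio(table: PeptideCountTable) -> pd.DataFrame:
    """Group means and bait/control ratio per protein.

    ``mean_ctrl == 0`` with positive ``mean_bait`` gives an infinite ratio;
    0/0 gives NaN (undefined).  No exception in either case.
    """
    bait = table.counts[table.samples("bait")].mean(axis=1)
    ctrl = table.counts[table.samples("control")].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bait / ctrl
    return pd.DataFrame({"mean_bait": bait, "mean_ctrl": ctrl, "ratio": ratio})


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided pooled-variance Student's t over rows.

    Zero pooled variance: equal means -> (t=0, p=1); unequal means ->
    (t=+-inf, p=0) sentinel.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    equal = degenerate & (diff == 0)
    unequal = degenerate & (diff != 0)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    t = np.where(unequal, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)
    return t, p


def test_enrichment(
    table: PeptideCountTable, alpha: float = 0.1, exclude_controls: bool = True
) -> pd.DataFrame:
    """Per-protein enrichment test.

    Returns a DataFrame indexed by protein id with group means, ratio,
    pooled-variance Student's t statistic, two-sided p-value, BH q-value, and
    the significance flag ``(p < alpha) AND (ratio > 1)``.  Internal-control
    proteins are excluded by default (they are standards, not candidates).
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    frame = enrichment_ratio(table)
    x = table.counts[table.samples("bait")].to_numpy(dtype=float)
    y = table.counts[table.samples("control")].to_numpy(dtype=float)
    t, p = _pooled_t(x, y)
    frame["t_stat"] = t
    frame["p_value"] = p
    frame["q_value"] = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    frame["significant"] = (frame["p_value"] < alpha) & (frame["ratio"] > 1)
    if exclude_controls:
        frame = frame[~frame.index.isin(table.control_ids)]
    return frame


def run_experiment(
    table: PeptideCountTable,
    mode: str = "raw",
    alpha: float = 0.1,
    control_ids: Sequence[str] | None = None,
) -> ExperimentResult:
    """Compose (optional normalization) -> ratio -> t test.

    ``mode`` is ``"raw"`` or ``"endogenous_normalized"``.  Results are ordered
    by descending ratio (infinite ratios first, NaN last).
    """
    if mode not in ("raw", "endogenous_normalized"):
        raise ValidationError(f"unknown mode {mode!r}")
    work = normalize_by_endogenous(table, control_ids) if mode == "endogenous_normalized" else table
    results = test_enrichment(work, alpha=alpha)
    order = results["ratio"].fillna(-np.inf)
    results = results.loc[order.sort_values(ascending=False, kind="mergesort").index]
    significant = set(results.index[results["significant"]])
    return ExperimentResult(
        experiment_id=table.experiment_id,
        mode=mode,
        alpha=alpha,
        results=results,
        significant=significant,
    )


def cross_experiment_overlap(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[float, float]:
    """Directional overlap fractions (|A∩B|/|A|, |A∩B|/|B|).

    An empty denominator yields NaN for that direction.
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return (
        inter / len(a) if a else float("nan"),
        inter / len(b) if b else float("nan"),
    )
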