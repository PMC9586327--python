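"""Readers, writers, run configuration and the stage dispatcher.

File conventions:

* spectral-count tables: TSV, first column ``protein_id``, one column per
  sample, ``#``-prefixed metadata/comment lines, ``.`` decimal;
* group maps and configs: YAML;
* count matrices: MatrixMarket ``.mtx`` with ``genes.txt`` / ``cells.txt``
  sidecars (one name per line);
* volumes, images and label masks: (multi-page) TIFF.

``run_stage`` dispatches a validated :class:`RunConfig` to the corresponding
analysis module and returns a :class:`RunReport` with the headline outputs;
re-running with an identical config, inputs and seed reproduces identical
headline outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as spio
from scipy import sparse

from . import coexpression, enrichment, fluorescence, morphometry, simulate
from .errors import SchemaError, ValidationError

# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def save_count_table(
    table: enrichment.PeptideCountTable, path: str | Path, metadata: Mapping[str, Any] | None = None
) -> Path:
    """Write a spectral-count table as TSV with '#' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "experiment_id": table.experiment_id,
        "control_ids": list(table.control_ids),
        "groups": dict(table.groups),
        "normalized": table.normalized,
    }
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        frame = table.counts.copy()
        frame.index.name = "protein_id"
        frame.to_csv(fh, sep="\t", float_format="%.12g")
    return path


def load_count_table(path: str | Path) -> enrichment.PeptideCountTable:
    """Read a TSV spectral-count table written by :func:`save_count_table`.

    Raises :class:`SchemaError` naming the offending column or cell on a
    missing ``protein_id`` column or a negative count.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.columns[0] != "protein_id":
        raise SchemaError("missing required first column 'protein_id'")
    frame = frame.set_index("protein_id")
    frame.index.name = None
    values = frame.to_numpy()
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise SchemaError(
            f"negative count at protein {frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    groups = meta.get("groups")
    if not isinstance(groups, dict):
        raise SchemaError("missing '# groups:' metadata line mapping samples to groups")
    return enrichment.PeptideCountTable(
        counts=frame,
        groups=groups,
        experiment_id=str(meta.get("experiment_id", path.stem)),
        control_ids=tuple(meta.get("control_ids", ("Pcca", "Pc"))),
        normalized=bool(meta.get("normalized", False)),
    )


def save_results_csv(frame: pd.DataFrame, path: str | Path, metadata: Mapping[str, Any] | None = None) -> Path:
    """Write an analysis result table as CSV with '#' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        frame.to_csv(fh, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# images and matrices
# ---------------------------------------------------------------------------


def save_volume_tiff(volume: morphometry.EMVolume | np.ndarray, path: str | Path) -> Path:
    """Write a 3D stack (or 2D image) as TIFF; float data is stored as float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.voxels if isinstance(volume, morphometry.EMVolume) else np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    return path


def load_volume_tiff(
    path: str | Path, voxel_size_nm: tuple[float, float, float] = (10.0, 10.0, 10.0)
) -> morphometry.EMVolume:
    return morphometry.EMVolume(tifffile.imread(path), voxel_size_nm)


def save_cell_matrix(matrix: coexpression.CellCountMatrix, out_dir: str | Path) -> Path:
    """Write MatrixMarket ``counts.mtx`` + ``genes.txt`` / ``cells.txt`` sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "counts.mtx", sparse.coo_matrix(matrix.X))
    (out_dir / "genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    (out_dir / "cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    return out_dir / "counts.mtx"


def load_cell_matrix(out_dir: str | Path) -> coexpression.CellCountMatrix:
    out_dir = Path(out_dir)
    X = sparse.csr_matrix(spio.mmread(out_dir / "counts.mtx"))
    genes = (out_dir / "genes.txt").read_text().splitlines()
    cells = (out_dir / "cells.txt").read_text().splitlines()
    return coexpression.CellCountMatrix(X=X, gene_ids=genes, cell_ids=cells)


# ---------------------------------------------------------------------------
# run configuration and dispatch
# ---------------------------------------------------------------------------

STAGES = ("simulate_proteomics", "ibioid", "coexpr", "spine_ef", "sa_census")


@dataclass
class RunConfig:
    """One pipeline run: a stage, its parameters, a seed, an output directory."""

    stage: str
    params: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; known: {STAGES}")
        alpha = self.params.get("alpha")
        if alpha is not None and not 0 < alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        t = self.params.get("t")
        if t is not None and t <= 0:
            raise ValidationError("t must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config file; keyword overrides take precedence over file keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)


@dataclass
class RunReport:
    """Echo of the run plus its headline outputs and warnings."""

    stage: str
    seed: int
    config: dict[str, Any]
    input_digests: dict[str, str]
    headline: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_stage(cfg: RunConfig) -> RunReport:
    """Dispatch a validated config to its stage and collect headline outputs."""
    digests = {name: _digest(p) for name, p in cfg.inputs.items() if Path(p).is_file()}
    params = dict(cfg.params)
    warnings_list: list[str] = []
    headline: dict[str, Any]

    if cfg.stage == "simulate_proteomics":
        spec = simulate.ProteomicsSimSpec(seed=cfg.seed, **params)
        table, truth = simulate.generate_proteomics_table(spec)
        headline = {"n_proteins": spec.n_proteins, "n_enriched_truth": len(truth)}
        if cfg.out_dir:
            save_count_table(table, Path(cfg.out_dir) / "counts.tsv")
            (Path(cfg.out_dir) / "truth.json").write_text(json.dumps(truth))
    elif cfg.stage == "ibioid":
        table = load_count_table(cfg.inputs["counts"])
        mode = params.pop("mode", "raw")
        res = enrichment.run_experiment(table, mode=mode, **params)
        headline = {"n_significant": len(res.significant), "mode": mode, "alpha": res.alpha}
        if cfg.out_dir:
            save_results_csv(
                res.results,
                Path(cfg.out_dir) / "enrichment.csv",
                metadata={"experiment_id": res.experiment_id, "mode": mode, "alpha": res.alpha},
            )
    elif cfg.stage == "coexpr":
        matrix = load_cell_matrix(cfg.inputs["matrix_dir"])
        ref = params.get("ref_gene", "Synpo")
        spec = coexpression.ThresholdSpec(n=matrix.n_cells, t=params.get("t", 0.99))
        results = coexpression.pearson_vs_reference(matrix, ref)
        ranked = coexpression.rank_genes(results, ref, threshold=spec)
        headline = {"r_min": spec.r_min, "n_cells": matrix.n_cells, "n_ranked": int(ranked["rank"].notna().sum())}
        if cfg.out_dir:
            save_results_csv(ranked, Path(cfg.out_dir) / "correlations.csv", metadata={"r_min": spec.r_min})
    elif cfg.stage == "spine_ef":
        img = tifffile.imread(cfg.inputs["image"])
        shaft_mask = tifffile.imread(cfg.inputs["shaft_mask"]).astype(bool)
        rois = fluorescence.auto_shaft_rois(shaft_mask, n=params.get("n_rois", 5))
        record = fluorescence.quantify_image(
            img,
            threshold=params["threshold"],
            shaft_rois=rois,
            k=params.get("k", 40),
            image_id=str(cfg.inputs["image"]),
        )
        if record.k_used < record.k_requested:
            warnings_list.append(f"only {record.k_used} spots for top-{record.k_requested} mean")
        headline = {"ef": record.ef, "mu_spine": record.mu_spine, "mu_shaft": record.mu_shaft}
    elif cfg.stage == "sa_census":
        truth = pd.read_csv(cfg.inputs["truth"], comment="#")
        records = [
            morphometry.SpineRecord(
                spine_id=int(row.spine_id),
                has_psd=bool(row.has_psd),
                has_er=bool(row.has_er),
                has_sa=bool(row.has_sa),
            )
            for row in truth.itertuples()
        ]
        census = morphometry.spine_census(records)
        headline = dict(census.to_series())
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ValidationError(f"unknown stage {cfg.stage!r}")

    report = RunReport(
        stage=cfg.stage,
        seed=cfg.seed,
        config={"params": cfg.params, "inputs": dict(cfg.inputs)},
        input_digests=digests,
        headline=headline,
        warnings=warnings_list,
    )
    if cfg.out_dir:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        report.to_json(Path(cfg.out_dir) / "report.json")
    return report
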