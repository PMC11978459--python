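"""End-to-end orchestration: meshes in, tables and model surfaces out.

`run_pipeline` chains the stages — read/condition meshes, choose a
prototype, group-wise superimposition, principal coordinates, covariate
models — and writes every artifact (CSV tables, mean and extreme-shape
surfaces with variation scalars, resolved config, log) into one output
directory. Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mesh_core import (SurfaceMesh, read_mesh, write_mesh, reflect_sagittal,
                        smooth)
from .gpsa import (generalized_align, select_prototype, prototype_sensitivity,
                   GPSAResult)
from .ordination import pcoa, extreme_shapes, variation_heatmap, Ordination
from .shape_stats import (fit_glm, backward_stepwise, validate_covariates,
                          DEFAULT_TERMS, ModelFit)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run.

    ``prototype`` is ``"auto"`` (lowest mean interspecimen distance),
    ``"auto_rank_K"`` (K-th lowest, e.g. to skip a visually rejected first
    choice) or an explicit specimen id. Serializes losslessly to YAML.
    """

    mesh_manifest: str = ""         # CSV: specimen_id, path, side
    covariates_csv: str = ""
    output_dir: str = "muscleshape_run"
    smoothing_sigma_mm: float = 0.0     # 0 disables smoothing
    smoothing_method: str = "taubin"
    unit_scale: bool = True
    prototype: str = "auto"
    icp_max_iter: int = 50
    icp_tol: float = 1.0e-4
    icp_correspondence: str = "surface"
    outer_max_iter: int = 20
    outer_tol: float = 1.0e-3
    n_axes: int = 2
    model_terms: list = field(default_factory=lambda: list(DEFAULT_TERMS))
    stepwise_criterion: str = "aic"
    stepwise_alpha: float = 0.05
    run_sensitivity: bool = False
    sensitivity_k_pcs: int = 4
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    config: RunConfig
    gpsa: GPSAResult
    ordination: Ordination
    models: dict[int, tuple[ModelFit, ModelFit]]   # axis -> (full, reduced)
    output_dir: Path


def load_manifest(manifest_csv: str | Path) -> list[SurfaceMesh]:
    """Read every mesh listed in a manifest; left sides are reflected."""
    manifest = pd.read_csv(manifest_csv)
    required = {"specimen_id", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = Path(manifest_csv).parent
    meshes = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        side = str(row.get("side", "unknown")) if "side" in manifest else "unknown"
        mesh = read_mesh(p, specimen_id=str(row["specimen_id"]), side=side)
        if mesh.side == "left":
            mesh = reflect_sagittal(mesh)
            log.info("%s: left side reflected about the sagittal plane",
                     mesh.specimen_id)
        meshes.append(mesh)
    return meshes


def _resolve_prototype(choice: str, specimens: list[SurfaceMesh],
                       distances: np.ndarray | None = None,
                       **align_kwargs) -> str:
    if choice == "auto":
        pid, _ = select_prototype(specimens, rank=1, distances=distances,
                                  **align_kwargs)
        return pid
    if choice.startswith("auto_rank_"):
        rank = int(choice.rsplit("_", 1)[1])
        pid, _ = select_prototype(specimens, rank=rank, distances=distances,
                                  **align_kwargs)
        return pid
    ids = [s.specimen_id for s in specimens]
    if choice not in ids:
        raise ValueError(f"explicit prototype {choice!r} not among specimens")
    return choice


def run_pipeline(config: RunConfig,
                 specimens: list[SurfaceMesh] | None = None,
                 covariates: pd.DataFrame | None = None) -> PipelineResult:
    """Execute all stages and write the artifact set.

    ``specimens`` and ``covariates`` may be passed in memory (e.g. straight
    from the synthetic generator); otherwise they are loaded from the paths
    in the config. Any stage failure aborts with a stage-named error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("muscleshape")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        log.info("muscleshape %s on python %s; seed=%d", __version__,
                 platform.python_version(), config.seed)
        config.to_yaml(out / "config_resolved.yaml")

        if specimens is None:
            try:
                specimens = load_manifest(config.mesh_manifest)
            except Exception as exc:
                raise RuntimeError(f"stage 'load_meshes' failed: {exc}") from exc
        if covariates is None and config.covariates_csv:
            covariates = pd.read_csv(config.covariates_csv)
        if config.smoothing_sigma_mm > 0:
            try:
                specimens = [smooth(s, config.smoothing_sigma_mm,
                                    config.smoothing_method)
                             for s in specimens]
            except Exception as exc:
                raise RuntimeError(f"stage 'smooth' failed: {exc}") from exc

        align_kwargs = dict(unit_scale=config.unit_scale,
                            icp_max_iter=config.icp_max_iter,
                            icp_tol=config.icp_tol,
                            icp_correspondence=config.icp_correspondence)
        try:
            prototype_id = _resolve_prototype(config.prototype, specimens,
                                              **align_kwargs)
            log.info("prototype: %s", prototype_id)
            gres = generalized_align(specimens, prototype_id,
                                     max_outer_iter=config.outer_max_iter,
                                     tol=config.outer_tol, **align_kwargs)
            log.info("GPSA converged=%s after %d outer iterations",
                     gres.converged, gres.n_outer_iter)
        except Exception as exc:
            raise RuntimeError(f"stage 'gpsa' failed: {exc}") from exc

        try:
            ordn = pcoa(gres.distances, ids=gres.specimen_ids)
        except Exception as exc:
            raise RuntimeError(f"stage 'ordination' failed: {exc}") from exc

        gres.distances_frame().to_csv(out / "distances.csv",
                                      index_label="specimen_id")
        scores = pd.DataFrame(
            ordn.scores, index=ordn.specimen_ids,
            columns=[f"PC{i + 1}" for i in range(ordn.axis_count)])
        scores.to_csv(out / "scores.csv", index_label="specimen_id")
        pd.DataFrame({
            "axis": [f"PC{i + 1}" for i in range(ordn.axis_count)],
            "eigenvalue": ordn.eigenvalues,
            "pct_variance": ordn.pct_variance,
        }).to_csv(out / "variance.csv", index=False)

        write_mesh(gres.mean_surface, out / "mean_surface.vtk")
        n_model_axes = min(config.n_axes, ordn.axis_count)
        for ax in range(n_model_axes):
            lo, hi = extreme_shapes(gres, ordn, ax)
            heat = variation_heatmap(lo, hi)
            write_mesh(lo, out / f"pc{ax + 1}_min.vtk", scalar_field=heat)
            write_mesh(hi, out / f"pc{ax + 1}_max.vtk", scalar_field=heat)

        models: dict[int, tuple[ModelFit, ModelFit]] = {}
        if covariates is not None:
            try:
                rows = []
                for ax in range(n_model_axes):
                    s = dict(zip(ordn.specimen_ids, ordn.scores[:, ax]))
                    full = fit_glm(s, covariates, config.model_terms)
                    reduced = backward_stepwise(
                        full, criterion=config.stepwise_criterion,
                        alpha=config.stepwise_alpha)
                    models[ax] = (full, reduced)
                    for name, row in reduced.coefficients.iterrows():
                        rows.append({
                            "axis": f"PC{ax + 1}", "coefficient": name,
                            "term": row["term"], "estimate": row["coef"],
                            "se": row["se"], "t": row["t"], "p": row["p"],
                            "partial_r2": reduced.partial_r2.get(
                                row["term"], np.nan),
                            "model_aic": reduced.aic,
                            "full_model_aic": full.aic,
                        })
                pd.DataFrame(rows).to_csv(out / "model_summary.csv",
                                          index=False)
            except Exception as exc:
                raise RuntimeError(f"stage 'models' failed: {exc}") from exc

        if config.run_sensitivity:
            try:
                sens = prototype_sensitivity(
                    specimens, k_pcs=config.sensitivity_k_pcs, **align_kwargs)
                table = sens.table.copy()
                table.loc["range_max_minus_min"] = sens.ranges
                table.to_csv(out / "sensitivity.csv")
            except Exception as exc:
                raise RuntimeError(f"stage 'sensitivity' failed: {exc}") from exc

        log.info("artifacts written to %s", out)
        return PipelineResult(config=config, gpsa=gres, ordination=ordn,
                              models=models, output_dir=out)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
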