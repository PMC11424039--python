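"""End-to-end orchestration of the synthetic analysis run.

A :class:`RunConfig` (YAML/JSON round-trippable) drives the whole chain:

    phantom -> deconvolution -> connectome -> metrics
    cohort  -> metric table  -> mixed models / per-network GLMs
            -> elastic-net feature importance

Every stochastic stage takes an explicit seed from the config; a config
with a missing seed fails validation before anything runs. Each stage
writes its artifacts under the output directory and the run ends with a
manifest (file list, SHA-256 checksums, seeds, package versions) so a
rerun with the same config can be verified byte-for-byte on the
deterministic path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import EffectSpec, GroupEffect, canonical_assignment, simulate_cohort
from .connectome import build_connectome
from .deconvolution import StreamlineDeconvolution
from .kernels import KernelParams
from .metrics import MetricConfig, compute_metric_table, local_efficiency_matrix
from .phantom import VoxelGrid, add_noise, make_crossing_phantom, simulate_signal
from .scheme import make_scheme
from .stats import (
    density_adjusted_replication,
    elasticnet_feature_importance,
    fit_metric_lmm,
    per_network_glm,
    select_model,
)
from . import io as mio

__all__ = ["RunConfig", "PipelineError", "run_all", "smoke_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete, serializable description of one synthetic run."""

    out_dir: str = "run_output"
    seeds: dict = field(
        default_factory=lambda: {"phantom": 1, "noise": 2, "cohort": 3, "stats": 4}
    )
    phantom: dict = field(
        default_factory=lambda: {
            "grid_shape": [10, 10, 10],
            "voxel_size": 2.0,
            "n_bundles": 2,
            "streamlines_per_bundle": 20,
            "noise_sigma": 0.0,
            "noise_model": "rician",
        }
    )
    scheme: dict = field(
        default_factory=lambda: {
            "shells": [[500, 30], [1200, 30], [2400, 60], [4000, 60], [6000, 60]],
            "n_b0": 14,
        }
    )
    kernels: dict = field(
        default_factory=lambda: asdict(KernelParams())
        | {"d_iso_list": list(KernelParams().d_iso_list)}
    )
    cohort: dict = field(
        default_factory=lambda: {
            "n": 88,
            "n_female": 46,
            "age_range": [8.0, 19.0],
            "nodes_per_network": 8,
            "effects": {"visual": {"age_slope": 0.01}},
        }
    )
    metrics: dict = field(default_factory=lambda: {"gamma": 1.0})
    stats: dict = field(
        default_factory=lambda: {
            "metric": "mean_strength",
            "alpha": 0.005,
            "feature_group": "visual",
            "n_alphas": 30,
            "k_folds": 5,
        }
    )

    def validate(self) -> None:
        for stage in ("phantom", "noise", "cohort", "stats"):
            if stage not in self.seeds:
                raise ValueError(f"config is missing a seed for stage {stage!r}")
            int(self.seeds[stage])
        if not self.scheme.get("shells"):
            raise ValueError("scheme must define at least one shell")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def smoke_config(out_dir: str) -> RunConfig:
    """A tiny configuration that exercises every stage in well under a minute."""
    cfg = RunConfig(out_dir=out_dir)
    cfg.phantom.update({"grid_shape": [6, 6, 6], "streamlines_per_bundle": 5})
    cfg.cohort.update({"n": 12, "n_female": 6, "nodes_per_network": 5})
    cfg.stats.update({"n_alphas": 5})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "seeds": dict(config.seeds),
        "versions": {"micoconn": __version__, "numpy": np.__version__},
        "stages": [],
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        written.extend(paths)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done", name)

        return _Ctx()

    # ---- phantom -------------------------------------------------------
    with stage("phantom"):
        p = config.phantom
        grid = VoxelGrid(tuple(p["grid_shape"]), p.get("voxel_size", 2.0))
        scheme = make_scheme(
            [tuple(s) for s in config.scheme["shells"]],
            n_b0=config.scheme.get("n_b0", 0),
            seed=int(config.seeds["phantom"]),
        )
        params = KernelParams(
            d_par=config.kernels["d_par"],
            d_par_zep=config.kernels["d_par_zep"],
            d_perp=config.kernels["d_perp"],
            d_iso_list=tuple(config.kernels["d_iso_list"]),
        )
        tractogram, truth, parc = make_crossing_phantom(
            grid,
            n_bundles=p["n_bundles"],
            streamlines_per_bundle=p["streamlines_per_bundle"],
            seed=int(config.seeds["phantom"]),
        )
        signal = simulate_signal(tractogram, truth, grid, scheme, params)
        if p.get("noise_sigma", 0.0) > 0:
            signal = add_noise(
                signal, p["noise_sigma"], p.get("noise_model", "rician"),
                seed=int(config.seeds["noise"]),
            )
        mio.save_tck(tractogram, out / "phantom.tck")
        mio.save_nifti(signal, out / "signal.nii.gz", grid.voxel_size)
        mio.save_nifti(parc.labels.astype(np.int32), out / "labels.nii.gz",
                       grid.voxel_size)
        mio.save_gradient_table(scheme, out / "bvals.txt", out / "bvecs.txt")
        record("phantom", out / "phantom.tck", out / "signal.nii.gz",
               out / "labels.nii.gz", out / "bvals.txt", out / "bvecs.txt")

    # ---- deconvolution -------------------------------------------------
    with stage("deconvolution"):
        fit = StreamlineDeconvolution(signal, tractogram, grid, scheme, params).fit()
        wdf = pd.DataFrame(
            {
                "streamline_id": np.arange(len(tractogram)),
                "x": fit.x,
                "kept": fit.kept_mask,
            }
        )
        wdf.to_csv(out / "weights.csv", index=False)
        record("deconvolution", out / "weights.csv")

    # ---- connectome ----------------------------------------------------
    with stage("connectome"):
        conn_iasf = build_connectome(tractogram, fit.weights, parc, "IASF")
        conn_nos = build_connectome(tractogram, fit.weights, parc, "NOS")
        mio.save_connectome(conn_iasf, out / "connectome_iasf.csv",
                            out / "connectome_nodes.tsv")
        mio.save_connectome(conn_nos, out / "connectome_nos.csv")
        record("connectome", out / "connectome_iasf.csv",
               out / "connectome_nodes.tsv", out / "connectome_nos.csv")

    # ---- cohort + metric table ----------------------------------------
    with stage("cohort"):
        c = config.cohort
        assignment = canonical_assignment(c.get("nodes_per_network", 8))
        effects = EffectSpec(
            groups={
                g: GroupEffect(**kw) for g, kw in c.get("effects", {}).items()
            }
        )
        cohort = simulate_cohort(
            n=c["n"], age_range=tuple(c.get("age_range", (8.0, 19.0))),
            n_female=c["n_female"], assignment=assignment, effects=effects,
            seed=int(config.seeds["cohort"]),
        )
        mio.save_cohort(cohort, out / "cohort")
        mio.save_assignment(assignment, out / "assignment.tsv")
        record("cohort", out / "cohort" / "subjects.tsv", out / "assignment.tsv")

    with stage("metrics"):
        mcfg = MetricConfig(gamma=config.metrics.get("gamma", 1.0))
        table = compute_metric_table(cohort, assignment, mcfg)
        table.to_csv(out / "metrics.csv", index=False)
        record("metrics", out / "metrics.csv")

    # ---- statistics ----------------------------------------------------
    with stage("stats"):
        s = config.stats
        metric = s.get("metric", "mean_strength")
        fits = fit_metric_lmm(table, metric)
        best = select_model(fits)
        pd.DataFrame(
            [
                {"model": f.name, "aic": f.aic, "n_params": f.n_params,
                 "converged": f.converged, "selected": f.name == best.name}
                for f in fits
            ]
        ).to_csv(out / "model_selection.csv", index=False)
        glms = []
        for g in assignment.groups():
            mf = per_network_glm(table, metric, g, alpha=s.get("alpha", 0.005))
            glms.append(
                {"network": g, "adj_r2": mf.adj_r2,
                 "age_p": mf.metadata["age_p"],
                 "significant": mf.metadata["significant"]}
            )
        pd.DataFrame(glms).to_csv(out / "per_network_glm.csv", index=False)
        density_adjusted_replication(table, metric).to_csv(
            out / "density_replication.csv", index=False
        )
        record("stats", out / "model_selection.csv", out / "per_network_glm.csv",
               out / "density_replication.csv")

    with stage("feature_importance"):
        group = s.get("feature_group", "visual")
        feats = local_efficiency_matrix(cohort, assignment, group)
        ages = np.array([rec.age for rec in cohort])
        res = elasticnet_feature_importance(
            feats, ages, seed=int(config.seeds["stats"]),
            n_alphas=s.get("n_alphas", 30), k_folds=s.get("k_folds", 5),
        )
        fi = pd.DataFrame(
            {
                "node": res.ranked_nodes,
                "weight": res.weights.loc[res.ranked_nodes].values,
                "rank": np.arange(1, len(res.ranked_nodes) + 1),
                "cumulative_share": res.cumulative_share,
            }
        )
        fi.to_csv(out / "feature_importance.csv", index=False)
        meta = {
            "validation_r2": res.validation_r2,
            "validation_rmse": res.validation_rmse,
            "l1_ratio": res.l1_ratio,
            "alpha": res.alpha,
            "cv_r2": res.cv_r2,
            **res.metadata,
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        record("feature_importance", out / "feature_importance.csv",
               out / "run_metadata.json")

    manifest["files"] = {
        str(pth.relative_to(out)): _sha256(pth) for pth in written
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
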