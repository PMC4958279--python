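"""End-to-end orchestration: simulate → preprocess → stats → explore → classify.

:func:`run_pipeline` executes the whole analysis from a :class:`RunConfig`
and writes every artifact plus a JSON manifest (parameters, seeds, output
hashes).  Re-running the same config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .explore import covariate_screen, hcluster, pca, heatmap_matrix
from .fingerprint import run_fingerprint
from .preprocess import preprocess
from .synthetic import StudyDesign, generate_dataset
from .tables import FeatureTable
from .univariate import differential_abundance, top_k_by_p

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs and parameters for a full run (defaults follow the study settings)."""

    feature_csv: str | None = None
    metadata_csv: str | None = None
    simulate: bool = False
    out_dir: str = "metabofp_out"
    missing_threshold: float = 0.5
    knn_k: int = 10
    p_threshold: float = 0.05
    q_threshold: float = 0.10
    t_variant: str = "welch"
    heatmap_top: int = 70
    svm_cost: float = 1.0
    n_iterations: int = 50
    train_fraction: float = 0.7
    top_n: int = 25
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(writer, obj, name):
        path = out / name
        writer(obj, path)
        written.append(path)
        return path

    # --- input or simulation -------------------------------------------
    if config.simulate:
        design = StudyDesign(seed=config.master_seed)
        table, metadata, truth = _stage("simulate")(generate_dataset)(design)
        _save(mio.write_feature_csv, table, "feature_table.csv")
        _save(mio.write_metadata_csv, metadata, "sample_metadata.csv")
        _save(mio.write_truth_tsv, truth, "truth.tsv")
    else:
        if not (config.feature_csv and config.metadata_csv):
            raise PipelineError(
                "stage 'input' failed: provide feature_csv and metadata_csv, "
                "or set simulate=true"
            )
        table = _stage("input")(mio.read_feature_csv)(config.feature_csv)
        metadata = _stage("input")(mio.read_metadata_csv)(config.metadata_csv)

    # --- preprocessing --------------------------------------------------
    scaled, imputed, fc, reports = _stage("preprocess")(preprocess)(
        table, metadata, config.missing_threshold, config.knn_k
    )
    _save(mio.write_feature_csv, scaled, "analysis_matrix.csv")
    discards = reports[0].discarded_features
    _save(mio.write_tsv, discards, "discarded_features.tsv")
    imputed_cells = pd.DataFrame(
        reports[1].imputed_cells, columns=["sample_id", "feature_id"]
    )
    _save(mio.write_tsv, imputed_cells, "imputed_cells.tsv")

    # --- univariate ------------------------------------------------------
    diff = _stage("univariate")(differential_abundance)(
        imputed, metadata, config.t_variant, config.p_threshold, config.q_threshold
    )
    _save(mio.write_tsv, diff, "differential.tsv")

    # --- explore ---------------------------------------------------------
    dendro = _stage("explore")(hcluster)(scaled)
    (out / "samples_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    written.append(out / "samples_dendrogram.nwk")
    pres = _stage("explore")(pca)(scaled)
    _save(mio.write_tsv, pres.scores.rename_axis("sample_id").reset_index(), "pca_scores.tsv")
    _save(mio.write_tsv, pres.loadings.rename_axis("feature_id").reset_index(), "pca_loadings.tsv")
    var = pd.DataFrame(
        {"component": pres.scores.columns, "variance_explained": pres.variance_explained}
    )
    _save(mio.write_tsv, var, "pca_variance.tsv")
    k = min(config.heatmap_top, len(diff))
    subset = top_k_by_p(diff, k)["feature_id"].tolist()
    heat, row_order, col_order = _stage("explore")(heatmap_matrix)(scaled, subset)
    _save(mio.write_tsv, heat.rename_axis("feature_id").reset_index(), "heatmap_matrix.tsv")
    screen = _stage("explore")(covariate_screen)(scaled, metadata)
    _save(mio.write_tsv, screen, "covariate_screen.tsv")

    # --- classify --------------------------------------------------------
    report = _stage("classify")(run_fingerprint)(
        scaled,
        metadata,
        master_seed=config.master_seed,
        n_iterations=config.n_iterations,
        train_fraction=config.train_fraction,
        cost=config.svm_cost,
        top_n=config.top_n,
        annotations=diff,
    )
    _save(mio.write_tsv, report.avg_rank, "fingerprint_full.tsv")
    _save(mio.write_tsv, report.top, f"fingerprint_top{config.top_n}.tsv")
    aucs = pd.DataFrame(
        {"iteration": range(len(report.iteration_aucs)), "auc": report.iteration_aucs}
    )
    _save(mio.write_tsv, aucs, "iteration_aucs.tsv")
    _save(mio.write_tsv, report.roc, "roc_average.tsv")
    null_aucs = pd.DataFrame(
        {"iteration": range(len(report.null.aucs)), "auc": report.null.aucs}
    )
    _save(mio.write_tsv, null_aucs, "null_aucs.tsv")

    # --- manifest --------------------------------------------------------
    mio.write_manifest(
        out / "manifest.json",
        config=asdict(config),
        mean_auc=report.mean_auc,
        null_mean_auc=report.null.mean,
        null_ci=[report.null.ci_low, report.null.ci_high],
        n_significant=int(diff["significant"].sum()),
        outputs={p.name: _sha256(p) for p in sorted(written)},
    )
    log.info("pipeline complete: %d artifacts in %s", len(written) + 1, out)
    return out
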