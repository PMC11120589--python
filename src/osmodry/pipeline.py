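"""End-to-end orchestration: load -> score -> multivariate -> ANN -> GSA -> report.

The pipeline is configured with a validated :class:`PipelineConfig` (usually
parsed from YAML), runs each analysis stage on the chosen design table and
writes a bundle of CSV/JSON artifacts to the output directory:

``scores.csv``          per-run normalized criterion scores, SS and rank
``correlations.csv``    Pearson coefficient matrix (``correlation_pvalues.csv``
                        holds the matching two-sided p-values)
``clusters.json``       merge list and flat cluster memberships
``pca.csv``             loadings, eigenvalues, percent variance, contributions
``ann_models.json``     serialized networks (optional stage)
``fit_report.csv``      goodness-of-fit suite per response (optional stage)
``ri_matrix.csv``       Yoon relative-importance matrix (optional stage)
``summary.json``        the optimal run and its settings/responses, seeds,
                        package version

Outputs are staged in memory and written only after every stage has
succeeded, so a failing stage leaves no partial bundle behind.  All
randomness (the ANN stage) flows from the single config seed, making two
runs with the same config byte-identical.
"""

from __future__ import annotations

import io
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .dataset import load_design_table
from .scoring import DEFAULT_DIRECTIONS, CriterionSpec, standard_scores
from .multivariate import cluster_runs, pca_correlation, pearson_matrix

__all__ = ["PipelineConfig", "AnnSettings", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class AnnSettings(BaseModel):
    """Neural-network stage settings (the slowest stage; off by default)."""

    enabled: bool = False
    hidden_min: int = Field(3, ge=1)
    hidden_max: int = Field(10, ge=1)
    restarts: int = Field(20, ge=1)
    max_iter: int = Field(200, ge=1)
    f_hidden: Literal["identity", "logistic", "tanh", "exponential"] = "tanh"
    f_output: Literal["identity", "logistic", "tanh", "exponential"] = "identity"

    @field_validator("hidden_max")
    @classmethod
    def _ordered(cls, v, info):
        if "hidden_min" in info.data and v < info.data["hidden_min"]:
            raise ValueError("hidden_max must be >= hidden_min")
        return v


class PipelineConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    input: str = "table1"
    directions: dict[str, Literal["benefit", "cost"]] = {}
    cluster_k: int = Field(4, ge=1)
    ann: AnnSettings = AnnSettings()
    outdir: Path
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**payload)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _csv(frame: pd.DataFrame, **kwargs) -> str:
    buf = io.StringIO()
    frame.to_csv(buf, **kwargs)
    return buf.getvalue()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage and write the report bundle.

    Returns a mapping from artifact name to written path.
    """
    artifacts: dict[str, str] = {}
    summary: dict = {"seed": cfg.seed, "version": __version__, "input": cfg.input}

    def stage(name):
        logger.info("stage %s (seed=%d)", name, cfg.seed)

    try:
        stage("load")
        table = load_design_table(cfg.input)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("scores")
        unknown = set(cfg.directions) - set(table.response_columns)
        if unknown:
            raise KeyError(f"direction override(s) for unknown column(s): {sorted(unknown)}")
        directions = {col: DEFAULT_DIRECTIONS.get(col, "benefit")
                      for col in table.response_columns}
        directions.update(cfg.directions)
        criteria = [CriterionSpec(col, directions[col]) for col in table.response_columns]
        score_table = standard_scores(table, criteria)
        frame = score_table.scores.copy()
        frame["SS"] = score_table.ss
        frame["rank"] = [score_table.ranking.index(r) + 1 for r in frame.index]
        artifacts["scores.csv"] = _csv(frame, index_label="run")
    except Exception as exc:
        raise PipelineError("scores", exc) from exc

    try:
        stage("correlations")
        corr = pearson_matrix(table)
        artifacts["correlations.csv"] = _csv(corr.r, index_label="")
        artifacts["correlation_pvalues.csv"] = _csv(corr.p, index_label="")
    except Exception as exc:
        raise PipelineError("correlations", exc) from exc

    try:
        stage("clusters")
        clusters = cluster_runs(table, k=cfg.cluster_k)
        artifacts["clusters.json"] = json.dumps({
            "metric": clusters.metric,
            "linkage": clusters.linkage,
            "k": clusters.k,
            "merges": clusters.merges.tolist(),
            "labels": {str(run): lab for run, lab in sorted(clusters.labels.items())},
        }, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError("clusters", exc) from exc

    try:
        stage("pca")
        pca = pca_correlation(table)
        frame = pca.loadings.copy()
        frame.loc["<eigenvalue>"] = pca.eigenvalues
        frame.loc["<percent_variance>"] = pca.percent_variance
        artifacts["pca.csv"] = _csv(frame, index_label="variable")
        artifacts["pca_contributions.csv"] = _csv(pca.contributions, index_label="variable")
    except Exception as exc:
        raise PipelineError("pca", exc) from exc

    if cfg.ann.enabled:
        from .ann import TrainConfig, summary_table, topology_search
        from .gsa import fit_report_table, relative_importance_matrix

        try:
            stage("ann")
            train_cfg = TrainConfig(
                hidden_range=tuple(range(cfg.ann.hidden_min, cfg.ann.hidden_max + 1)),
                restarts=cfg.ann.restarts, max_iter=cfg.ann.max_iter,
                seed=cfg.seed, f_hidden=cfg.ann.f_hidden, f_output=cfg.ann.f_output,
            )
            trained = topology_search(table, cfg=train_cfg)
            artifacts["ann_models.json"] = json.dumps(
                {res.response: res.model.to_dict() for res in trained},
                indent=2, sort_keys=True)
            artifacts["ann_summary.csv"] = _csv(summary_table(trained), index=False)
        except Exception as exc:
            raise PipelineError("ann", exc) from exc

        try:
            stage("gsa")
            artifacts["ri_matrix.csv"] = _csv(relative_importance_matrix(trained),
                                              index_label="input")
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # predictions beyond train bounds
                artifacts["fit_report.csv"] = _csv(fit_report_table(trained, table),
                                                   index_label="response")
        except Exception as exc:
            raise PipelineError("gsa", exc) from exc

    try:
        stage("summary")
        best = score_table.best_run
        settings, responses = table.run(best)
        summary.update({
            "optimal_run": best,
            "optimal_settings": {"T": settings.T, "Conc": settings.Conc, "t": settings.t},
            "optimal_responses": {k: float(v) for k, v in responses.items()},
            "optimal_SS": float(score_table.ss.loc[best]),
            "ranking": score_table.ranking,
        })
        artifacts["summary.json"] = json.dumps(summary, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError("summary", exc) from exc

    # all stages succeeded: write the bundle
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        for name, payload in artifacts.items():
            path = outdir / name
            path.write_text(payload)
            written[name] = path
        if cfg.plots:
            from . import plots

            written["correlation_heatmap.png"] = plots.save_correlation_heatmap(
                corr, outdir / "correlation_heatmap.png")
            written["dendrogram.png"] = plots.save_dendrogram(
                clusters, outdir / "dendrogram.png")
            written["pca_biplot.png"] = plots.save_biplot(
                pca, table, outdir / "pca_biplot.png")
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise PipelineError("write", exc) from exc
    return written
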