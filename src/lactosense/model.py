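"""High-level modelling surface: model object + results object.

`SensoryPhenotypeModel` binds a binary genotype matrix to a table of sensory
responses; `fit()` runs, per phenotype, the DBO search over the four-stage
feature-selection pipeline, fits the winning pipeline, cross-validates the
candidate regressors on its component scores, and back-projects importances.
The returned `SensoryPhenotypeResults` carries the per-phenotype estimates
and exposes the descriptive analytics (correlations, shared features,
importance rankings) and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, importance as importance_mod, models as models_mod, pipeline as pipe
from .dbo import OptimizationTrace
from .simulate import SimDesign, simulate_genotypes, simulate_phenotypes

__all__ = ["SensoryPhenotypeModel", "SensoryPhenotypeResults", "PhenotypeFit"]


@dataclass
class PhenotypeFit:
    """Everything estimated for one sensory channel."""

    name: str
    params: pipe.PipelineParams
    fitness: float
    trace: OptimizationTrace
    pipeline: pipe.FittedPipeline
    metrics: dict[str, models_mod.MetricSet]
    best_model: str
    importance: importance_mod.ImportanceVector


class SensoryPhenotypeModel:
    """Genotype → sensory-phenotype prediction model.

    Parameters
    ----------
    genotypes
        samples × binary features DataFrame (class-prefixed feature ids).
    phenotypes
        samples × sensory channels DataFrame; aligned to ``genotypes`` by
        sample id.
    """

    def __init__(self, genotypes: pd.DataFrame, phenotypes: pd.DataFrame):
        if set(genotypes.index) != set(phenotypes.index):
            raise ValueError("genotype and phenotype tables must cover the same samples")
        self.genotypes = genotypes
        self.phenotypes = phenotypes.loc[genotypes.index]
        self.feature_ids = np.asarray(genotypes.columns, dtype=object)

    @classmethod
    def from_design(cls, design: SimDesign) -> "SensoryPhenotypeModel":
        """Simulate a study from a synthetic design and wrap it as a model."""
        G = simulate_genotypes(design)
        P = simulate_phenotypes(G, design)
        obj = cls(G, P)
        obj.design = design
        return obj

    @classmethod
    def from_files(cls, genotype_paths, phenotype_path) -> "SensoryPhenotypeModel":
        """Load one or more genotype matrices (column-concatenated) + phenotypes."""
        from .io import read_genotype_matrix, read_phenotypes

        parts = [read_genotype_matrix(p) for p in genotype_paths]
        G = parts[0]
        for extra in parts[1:]:
            extra = extra.loc[G.index]
            G = pd.concat([G, extra], axis=1)
        P = read_phenotypes(phenotype_path, genotypes=G)
        return cls(G, P)

    def fit(
        self,
        phenotypes: list[str] | None = None,
        pop_size: int = 50,
        max_iter: int = 100,
        bounds: pipe.ParamBounds | None = None,
        model_names=models_mod.MODEL_NAMES,
        seed: int = 0,
        verbose: bool = False,
    ) -> "SensoryPhenotypeResults":
        """DBO-optimize, fit, and evaluate the pipeline for each phenotype."""
        X = self.genotypes.to_numpy(dtype=float)
        names = list(phenotypes) if phenotypes is not None else list(self.phenotypes.columns)
        unknown = [n for n in names if n not in self.phenotypes.columns]
        if unknown:
            raise ValueError(f"unknown phenotypes {unknown}")
        fits: dict[str, PhenotypeFit] = {}
        for name in names:
            y = self.phenotypes[name].to_numpy(dtype=float)
            params, fitness, trace = pipe.optimize_pipeline(
                X, y, pop_size=pop_size, max_iter=max_iter, bounds=bounds, seed=seed
            )
            fp = pipe.fit_pipeline(params, X, y, feature_ids=self.feature_ids, seed=seed)
            metrics = {
                m: models_mod.cross_validate_model(m, fp.component_scores, y, seed=seed)
                for m in model_names
            }
            report = models_mod.EvalReport(
                records={(name, m): ms for m, ms in metrics.items()}, fold_seed=seed
            )
            best = report.best_models()[name]
            iv = importance_mod.propagate_importance(fp)
            fits[name] = PhenotypeFit(
                name=name,
                params=params,
                fitness=fitness,
                trace=trace,
                pipeline=fp,
                metrics=metrics,
                best_model=best,
                importance=iv,
            )
            if verbose:
                print(
                    f"[{name}] fitness={fitness:.4f} best={best} "
                    f"r2={metrics[best].r2:.4f} params={params.as_dict()}"
                )
        return SensoryPhenotypeResults(model=self, fits=fits, seed=seed)


@dataclass
class SensoryPhenotypeResults:
    """Fitted estimates, diagnostics, and analytics for all phenotypes."""

    model: SensoryPhenotypeModel
    fits: dict[str, PhenotypeFit]
    seed: int

    @property
    def report(self) -> models_mod.EvalReport:
        records = {
            (name, m): ms for name, fit in self.fits.items() for m, ms in fit.metrics.items()
        }
        return models_mod.EvalReport(records=records, fold_seed=self.seed)

    def best_models(self) -> dict[str, str]:
        return {name: fit.best_model for name, fit in self.fits.items()}

    def report_dataframe(self, best_only: bool = True) -> pd.DataFrame:
        return self.report.to_dataframe(best_only=best_only)

    def importance(self, phenotype: str, k: int = 10) -> list[tuple[str, float]]:
        return importance_mod.rank_top_k(self.fits[phenotype].importance, k=k)

    def spearman_matrix(self) -> pd.DataFrame:
        cols = list(self.fits)
        return analysis.spearman_matrix(self.model.phenotypes[cols])

    def shared_feature_matrix(self) -> pd.DataFrame:
        masks = {name: fit.pipeline.selected_feature_ids for name, fit in self.fits.items()}
        return analysis.shared_feature_counts(masks, universe=self.model.feature_ids)

    def overlap_trend(self) -> analysis.TrendResult:
        return analysis.overlap_correlation_trend(
            self.spearman_matrix(), self.shared_feature_matrix()
        )

    def stage_counts(self) -> pd.DataFrame:
        rows = [{"phenotype": n, **f.pipeline.stage_counts()} for n, f in self.fits.items()]
        return pd.DataFrame(rows).set_index("phenotype")

    def summary(self) -> str:
        """Human-readable per-phenotype summary table."""
        lines = [
            "Sensory phenotype prediction from pan-genome variants",
            f"  samples: {self.model.genotypes.shape[0]}   "
            f"features: {self.model.genotypes.shape[1]}   "
            f"phenotypes fitted: {len(self.fits)}   seed: {self.seed}",
            "",
            f"{'Sensor':<14}{'Best model':<22}{'R2':>8}{'MAE':>9}{'MSE':>9}{'RMSE':>9}"
            f"{'features':>10}{'PCs':>5}",
            "-" * 86,
        ]
        for name, fit in self.fits.items():
            ms = fit.metrics[fit.best_model]
            lines.append(
                f"{name:<14}{fit.best_model:<22}{ms.r2:>8.4f}{ms.mae:>9.4f}"
                f"{ms.mse:>9.4f}{ms.rmse:>9.4f}"
                f"{int(fit.pipeline.rfecv_mask.sum()):>10}{fit.params.n_components:>5}"
            )
        lines.append("-" * 86)
        lines.append("Metrics are means over shuffled 10-fold cross-validation.")
        return "\n".join(lines)

    # plotting passthroughs -------------------------------------------------
    def plot_boxplots(self, ax=None):
        return analysis.plot_boxplots(self.model.phenotypes[list(self.fits)], ax=ax)

    def plot_correlation_heatmap(self, ax=None):
        return analysis.plot_heatmap(self.spearman_matrix(), ax=ax, title="Spearman correlation")

    def plot_shared_features(self, ax=None):
        return analysis.plot_heatmap(
            self.shared_feature_matrix(), ax=ax, title="shared selected features", fmt="{:.0f}"
        )

    def plot_importance(self, phenotype: str, k: int = 10, ax=None):
        return analysis.plot_importance(
            self.fits[phenotype].importance, k=k, ax=ax, title=phenotype
        )
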