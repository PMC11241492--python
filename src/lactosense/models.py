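"""Candidate regressor zoo, cross-validated metrics, and model selection.

Ten classic regression families are compared per phenotype on the pipeline's
component scores under shuffled 10-fold cross-validation; the model with the
best mean fold R² wins (lexicographically first name on ties).  Metrics are
the standard quartet: R², MAE, MSE, RMSE.  Hyperparameters are library
defaults frozen in the registry below — reproducibility over tuning — with
two deliberate fixtures: the neural net is a single 64-unit hidden layer with
a fixed iteration cap, and the boosted-tree entries use 100 estimators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

__all__ = [
    "MODEL_NAMES",
    "MetricSet",
    "EvalReport",
    "make_model",
    "compute_metrics",
    "cross_validate_model",
    "evaluate_models",
    "select_best_model",
]

MODEL_NAMES = (
    "decision_tree",
    "elastic_net",
    "gradient_boosting",
    "k_nearest_neighbors",
    "lasso",
    "neural_net",
    "random_forest",
    "ridge",
    "svr",
    "xgboost",
)


def make_model(name: str, seed: int = 0):
    """Instantiate a registry model with its frozen hyperparameters."""
    registry = {
        "ridge": lambda: Ridge(alpha=1.0),
        "lasso": lambda: Lasso(),
        "elastic_net": lambda: ElasticNet(),
        "svr": lambda: SVR(),
        "k_nearest_neighbors": lambda: KNeighborsRegressor(),
        "decision_tree": lambda: DecisionTreeRegressor(random_state=seed),
        "random_forest": lambda: RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1),
        "gradient_boosting": lambda: GradientBoostingRegressor(n_estimators=100, random_state=seed),
        "xgboost": lambda: XGBRegressor(
            n_estimators=100, random_state=seed, n_jobs=1, verbosity=0
        ),
        "neural_net": lambda: MLPRegressor(
            hidden_layer_sizes=(64,), max_iter=500, random_state=seed
        ),
    }
    try:
        return registry[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available models: {', '.join(MODEL_NAMES)}"
        ) from None


@dataclass(frozen=True)
class MetricSet:
    """R², MAE, MSE, RMSE for one evaluation (satisfies rmse² = mse)."""

    r2: float
    mae: float
    mse: float
    rmse: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "mse": self.mse, "rmse": self.rmse}


def compute_metrics(y_true, y_pred) -> MetricSet:
    """Standard regression metrics; requires a non-degenerate truth vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    var = float(np.var(y_true))
    if var == 0.0:
        raise ValueError("y_true has zero variance; R² is undefined")
    e = y_true - y_pred
    mse = float(np.mean(e * e))
    return MetricSet(
        r2=1.0 - mse / var,
        mae=float(np.mean(np.abs(e))),
        mse=mse,
        rmse=math.sqrt(mse),
    )


def _mean_metrics(folds: list[MetricSet]) -> MetricSet:
    return MetricSet(
        r2=float(np.mean([m.r2 for m in folds])),
        mae=float(np.mean([m.mae for m in folds])),
        mse=float(np.mean([m.mse for m in folds])),
        rmse=float(np.mean([m.rmse for m in folds])),
    )


def cross_validate_model(
    model_name: str,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    return_folds: bool = False,
):
    """Shuffled k-fold CV of a registry model; fold metrics are averaged."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError(f"k={k} exceeds {len(y)} samples")
    make_model(model_name, seed)  # fail fast on unknown names
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in kf.split(X):
        model = make_model(model_name, seed)
        model.fit(X[tr], y[tr])
        folds.append(compute_metrics(y[te], np.asarray(model.predict(X[te]), dtype=float)))
    mean = _mean_metrics(folds)
    return (mean, folds) if return_folds else mean


@dataclass
class EvalReport:
    """Mean CV metrics per (phenotype, model) plus the winning model."""

    records: dict[tuple[str, str], MetricSet]
    fold_seed: int

    @property
    def phenotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ph, _ in self.records:
            seen.setdefault(ph)
        return list(seen)

    def models_for(self, phenotype: str) -> list[str]:
        return [m for ph, m in self.records if ph == phenotype]

    def best_models(self) -> dict[str, str]:
        """Argmax of mean fold R²; lexicographically first model name on ties."""
        out = {}
        for ph in self.phenotypes:
            candidates = sorted(self.models_for(ph))
            if not candidates:
                raise ValueError(f"no models evaluated for phenotype {ph!r}")
            best = candidates[0]
            for m in candidates[1:]:
                if self.records[(ph, m)].r2 > self.records[(ph, best)].r2:
                    best = m
            out[ph] = best
        return out

    def to_dataframe(self, best_only: bool = False) -> pd.DataFrame:
        if best_only:
            best = self.best_models()
            rows = [
                {
                    "Sensor": ph,
                    "Optimal Model": best[ph],
                    "MSE": self.records[(ph, best[ph])].mse,
                    "R2": self.records[(ph, best[ph])].r2,
                    "MAE": self.records[(ph, best[ph])].mae,
                    "RMSE": self.records[(ph, best[ph])].rmse,
                }
                for ph in self.phenotypes
            ]
        else:
            rows = [
                {
                    "Sensor": ph,
                    "Model": m,
                    "MSE": ms.mse,
                    "R2": ms.r2,
                    "MAE": ms.mae,
                    "RMSE": ms.rmse,
                }
                for (ph, m), ms in self.records.items()
            ]
        return pd.DataFrame(rows)

    def to_json(self, path=None):
        payload = {
            "fold_seed": self.fold_seed,
            "records": [
                {"phenotype": ph, "model": m, **ms.as_dict()}
                for (ph, m), ms in self.records.items()
            ],
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return None

    @classmethod
    def from_json(cls, source) -> "EvalReport":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        records = {
            (r["phenotype"], r["model"]): MetricSet(
                r2=r["r2"], mae=r["mae"], mse=r["mse"], rmse=r["rmse"]
            )
            for r in payload["records"]
        }
        return cls(records=records, fold_seed=int(payload["fold_seed"]))


def evaluate_models(
    features_by_phenotype: Mapping[str, np.ndarray],
    targets_by_phenotype: Mapping[str, np.ndarray],
    model_names=MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Cross-validate every registry model on every phenotype's feature set."""
    records = {}
    for ph, X in features_by_phenotype.items():
        y = targets_by_phenotype[ph]
        for name in model_names:
            records[(ph, name)] = cross_validate_model(name, X, y, k=k, seed=seed)
    return EvalReport(records=records, fold_seed=seed)


def select_best_model(report: EvalReport) -> dict[str, str]:
    return report.best_models()
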