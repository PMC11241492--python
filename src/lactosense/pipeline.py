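"""Serialized four-stage feature-selection pipeline and its DBO fitness.

The pipeline refines a binary samples × features matrix in four stages:

1. **VT** — variance threshold: drop features whose population variance falls
   strictly below a cutoff (applied to the raw 0/1 values, where a Bernoulli
   feature's variance is p(1-p));
2. **UFS** — univariate F selection: per-feature F statistic from the simple
   regression of the target on that feature,
   ``F_j = r_j^2 (n-2) / (1 - r_j^2)`` with r_j the Pearson correlation;
   the top ``percentile`` percent by score are kept, ties broken by lower
   feature index;
3. **RFECV** — recursive feature elimination with a ridge (L2) estimator on
   standardized features: each round drops the ``step`` features with the
   smallest absolute ridge coefficients (never below
   ``min_features_to_select``), the mean 10-fold CV score is recorded at every
   feature count, and the count with the best score wins (ties -> fewer
   features);
4. **PCA** — the surviving standardized features are projected onto the top
   ``n_components`` principal directions.

A ridge model on the component scores closes the pipeline; its 10-fold CV
score is the fitness a Dung Beetle Optimizer maximizes over the six pipeline
parameters.  Any stage failure maps to ``-inf`` fitness so the metaheuristic
can roam near constraint boundaries.

Implementation note: the RFECV inner loop works in the kernel (Gram) dual.
With ``M = (Z Z' + aI)^{-1}`` the held-out residuals of a ridge fit trained on
the complement of fold T are ``e_T = M_TT^{-1} (M y)_T`` exactly, so one
matrix maintained across elimination rounds (Woodbury downdates when columns
leave) replaces thousands of per-fold refits.  The RFECV-internal ridge is
fit without intercept on globally standardized features and globally centered
targets; the equivalence of the block identity to direct per-fold fits is
covered by a unit test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from . import dbo

__all__ = [
    "PipelineError",
    "PipelineParams",
    "ParamBounds",
    "FittedPipeline",
    "variance_filter",
    "univariate_f_select",
    "rfecv_select",
    "pca_reduce",
    "fit_pipeline",
    "pipeline_fitness",
    "make_objective",
    "optimize_pipeline",
    "stage_progression",
    "params_from_position",
]

#: RFECV / fitness scoring options in their canonical order.
SCORING_OPTIONS = ("r2", "mse", "rmse", "mae")

RIDGE_ALPHA = 1.0  # fixed everywhere: RFECV estimator, fitness model, final model


class PipelineError(ValueError):
    """A pipeline stage could not run on the given input."""


@dataclass(frozen=True)
class PipelineParams:
    """The six-dimensional search point the DBO tunes."""

    variance_threshold: float
    percentile: int
    rfecv_step: int
    min_features_to_select: int
    scoring: str = "r2"
    n_components: int = 10

    def __post_init__(self) -> None:
        if self.scoring not in SCORING_OPTIONS:
            raise ValueError(f"scoring must be one of {SCORING_OPTIONS}, got {self.scoring!r}")

    def validate(self, bounds: "ParamBounds") -> None:
        """Check the point against a search-space definition."""
        checks = [
            ("variance_threshold", self.variance_threshold, bounds.variance_threshold),
            ("percentile", self.percentile, bounds.percentile),
            ("rfecv_step", self.rfecv_step, bounds.rfecv_step),
            ("min_features_to_select", self.min_features_to_select, bounds.min_features),
            ("n_components", self.n_components, bounds.n_components),
        ]
        for name, v, (lo, hi) in checks:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside range [{lo}, {hi}]")

    def as_dict(self) -> dict:
        return {
            "variance_threshold": self.variance_threshold,
            "percentile": self.percentile,
            "rfecv_step": self.rfecv_step,
            "min_features_to_select": self.min_features_to_select,
            "scoring": self.scoring,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d) -> "PipelineParams":
        return cls(
            variance_threshold=float(d["variance_threshold"]),
            percentile=int(d["percentile"]),
            rfecv_step=int(d["rfecv_step"]),
            min_features_to_select=int(d["min_features_to_select"]),
            scoring=str(d["scoring"]),
            n_components=int(d["n_components"]),
        )


@dataclass(frozen=True)
class ParamBounds:
    """Search ranges for the six pipeline parameters.

    Defaults are the published tuning ranges: threshold in [0, 1e-4],
    percentile in [1, 100], RFECV step in [1, 10], minimum retained features
    in [100, 300], scoring in {R2, MSE, RMSE, MAE}, and the PCA dimension
    bounded above by both the sample count and the guaranteed number of RFECV
    survivors.
    """

    variance_threshold: tuple[float, float] = (0.0, 1e-4)
    percentile: tuple[int, int] = (1, 100)
    rfecv_step: tuple[int, int] = (1, 10)
    min_features: tuple[int, int] = (100, 300)
    n_components: tuple[int, int] = (1, 100)

    def to_dbo_config(self, pop_size: int = 50, max_iter: int = 100, seed: int = 0, **kw) -> dbo.DBOConfig:
        bounds = (
            self.variance_threshold,
            (self.percentile[0], self.percentile[1]),
            (self.rfecv_step[0], self.rfecv_step[1]),
            (self.min_features[0], self.min_features[1]),
            (0.0, float(len(SCORING_OPTIONS))),
            (self.n_components[0], self.n_components[1]),
        )
        kinds = (
            dbo.CONTINUOUS,
            dbo.INTEGER,
            dbo.INTEGER,
            dbo.INTEGER,
            dbo.categorical(len(SCORING_OPTIONS)),
            dbo.INTEGER,
        )
        return dbo.DBOConfig(
            bounds=bounds, dim_kinds=kinds, pop_size=pop_size, max_iter=max_iter, seed=seed, **kw
        )


def default_param_bounds(n_samples: int) -> ParamBounds:
    """Published ranges, with the PCA dimension capped by the sample count and
    by the smallest guaranteed RFECV survivor count."""
    hi = max(1, min(n_samples - 1, 100))
    return ParamBounds(n_components=(1, hi))


def params_from_position(position: Sequence[float], config: dbo.DBOConfig) -> PipelineParams:
    thr, pct, step, minf, scoring_idx, ncomp = dbo.decode_position(position, config)
    return PipelineParams(
        variance_threshold=float(thr),
        percentile=int(pct),
        rfecv_step=int(step),
        min_features_to_select=int(minf),
        scoring=SCORING_OPTIONS[int(scoring_idx)],
        n_components=int(ncomp),
    )


# ---------------------------------------------------------------------------
# stages


def variance_filter(X, threshold: float) -> np.ndarray:
    """Boolean mask keeping features with population variance >= threshold."""
    if threshold < 0:
        raise PipelineError(f"variance threshold must be >= 0, got {threshold}")
    X = np.asarray(X, dtype=float)
    var = X.var(axis=0)
    mask = var >= threshold
    if not mask.any():
        raise PipelineError(f"variance threshold {threshold} removed every feature")
    return mask


def univariate_f_scores(X, y) -> np.ndarray:
    """Per-feature F statistic from the Pearson correlation with the target.

    Constant features score 0; a feature perfectly correlated with y scores
    ``+inf``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    yc = y - y.mean()
    sy = math.sqrt(float(yc @ yc))
    if sy == 0.0:
        raise PipelineError("target has zero variance")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    if not np.any(sx > 0):
        raise PipelineError("all features are constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        F = r * r * (n - 2) / (1.0 - r * r)
    F[sx == 0] = 0.0
    return F


def univariate_f_select(X, y, percentile: int) -> np.ndarray:
    """Keep the top ``percentile`` percent of features by F score.

    The kept count is ``ceil(p * percentile / 100)``; ties are broken in
    favour of the lower feature index.
    """
    if not 1 <= percentile <= 100:
        raise PipelineError(f"percentile must be in [1, 100], got {percentile}")
    F = univariate_f_scores(X, y)
    p = F.shape[0]
    n_keep = int(math.ceil(p * percentile / 100.0))
    order = np.argsort(-F, kind="stable")  # stable -> ties keep lower index first
    mask = np.zeros(p, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _fold_test_sets(n: int, k: int, seed: int) -> list[np.ndarray]:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [te for _, te in kf.split(np.empty((n, 1)))]


def _group_folds(folds: list[np.ndarray]) -> list[np.ndarray]:
    """Stack same-size test folds for batched linear solves."""
    by_size: dict[int, list[np.ndarray]] = {}
    for te in folds:
        by_size.setdefault(len(te), []).append(te)
    return [np.stack(group) for group in by_size.values()]


def _cv_residual_scores(
    M: np.ndarray,
    a: np.ndarray,
    y: np.ndarray,
    fold_groups: list[np.ndarray],
    scoring: str,
) -> float:
    """Mean CV score over folds from the block cross-validation identity.

    ``M`` is the inverse regularized Gram matrix, ``a = M @ (y - mean(y))``.
    Error metrics are negated so that all scorings are maximized.
    """
    total = 0.0
    n_folds = 0
    for T in fold_groups:  # (g, m) stacked same-size folds
        Msub = M[T[:, :, None], T[:, None, :]]
        asub = a[T]
        e = np.linalg.solve(Msub, asub[..., None])[..., 0]  # held-out residuals, per fold
        yte = y[T]
        mse = np.mean(e * e, axis=1)
        if scoring == "r2":
            var = yte.var(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                sc = 1.0 - mse / var
            sc = np.where(var > 0, sc, -np.inf)
        elif scoring == "mse":
            sc = -mse
        elif scoring == "rmse":
            sc = -np.sqrt(mse)
        elif scoring == "mae":
            sc = -np.mean(np.abs(e), axis=1)
        else:  # pragma: no cover - guarded upstream
            raise PipelineError(f"unknown scoring {scoring!r}")
        total += float(sc.sum())
        n_folds += len(T)
    return total / n_folds


_REINVERT_EVERY = 64  # refresh M from the exact Gram to cap Woodbury drift


def rfecv_select(
    X,
    y,
    step: int,
    min_features: int,
    scoring: str = "r2",
    cv_folds: int = 10,
    seed: int = 0,
    alpha: float = RIDGE_ALPHA,
) -> np.ndarray:
    """Recursive feature elimination with cross-validated count selection.

    Returns the boolean survivor mask over the columns of ``X`` at the feature
    count with the best mean CV score (ties resolved toward fewer features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if step < 1:
        raise PipelineError(f"step must be >= 1, got {step}")
    if min_features < 1:
        raise PipelineError(f"min_features must be >= 1, got {min_features}")
    if p < min_features:
        raise PipelineError(f"{p} features is fewer than min_features={min_features}")
    if cv_folds > n:
        raise PipelineError(f"cv_folds={cv_folds} exceeds {n} samples")
    if scoring not in SCORING_OPTIONS:
        raise PipelineError(f"scoring must be one of {SCORING_OPTIONS}, got {scoring!r}")
    if p == min_features:
        return np.ones(p, dtype=bool)

    Z, _, _ = _standardize(X)
    yc = y - y.mean()
    fold_groups = _group_folds(_fold_test_sets(n, cv_folds, seed))

    G = Z @ Z.T
    eye = np.eye(n)
    M = np.linalg.inv(G + alpha * eye)
    active = np.ones(p, dtype=bool)
    p_cur = p
    removed: list[int] = []
    counts: list[int] = []
    scores: list[float] = []
    rounds_since_invert = 0

    while True:
        a = M @ yc
        counts.append(p_cur)
        scores.append(_cv_residual_scores(M, a, y, fold_groups, scoring))
        if p_cur <= min_features:
            break
        # ridge coefficients on the full data drive elimination
        w = Z.T @ a
        w_abs = np.abs(w)
        w_abs[~active] = np.inf
        n_drop = min(step, p_cur - min_features)
        drop = np.argsort(w_abs, kind="stable")[:n_drop]
        active[drop] = False
        removed.extend(int(j) for j in drop)
        p_cur -= n_drop
        Zd = Z[:, drop]
        G -= Zd @ Zd.T
        rounds_since_invert += 1
        if rounds_since_invert >= _REINVERT_EVERY:
            M = np.linalg.inv(G + alpha * eye)
            rounds_since_invert = 0
        else:
            # Woodbury downdate: inv(A - UU') = M + MU (I - U'MU)^{-1} U'M
            U = Zd
            MU = M @ U
            C = np.eye(n_drop) - U.T @ MU
            M = M + MU @ np.linalg.solve(C, MU.T)

    best_score = max(scores)
    best_idx = max(i for i, s in enumerate(scores) if s == best_score)  # fewer features on ties
    n_removed_at_best = p - counts[best_idx]
    mask = np.ones(p, dtype=bool)
    mask[removed[:n_removed_at_best]] = False
    return mask


def pca_reduce(X, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and project onto the top principal directions.

    Returns ``(scores, loadings)`` with orthonormal loading columns ordered by
    non-increasing explained variance; ``scores = (X - mean) @ loadings``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise PipelineError(
            f"n_components={n_components} outside [1, {min(n - 1, p)}] for shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T
    return scores, loadings


# ---------------------------------------------------------------------------
# end-to-end fit


@dataclass
class FittedPipeline:
    """All artifacts of one pipeline fit on one phenotype.

    The three survivor masks live over the original feature ids and are
    nested: ``rfecv_mask ⊆ ufs_mask ⊆ vt_mask``.  ``loading_matrix`` maps the
    standardized RFECV survivors to component scores; the ridge coefficients
    act on those scores.
    """

    feature_ids: np.ndarray
    params: PipelineParams
    vt_mask: np.ndarray
    ufs_mask: np.ndarray
    rfecv_mask: np.ndarray
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    pca_mean: np.ndarray
    loading_matrix: np.ndarray
    component_scores: np.ndarray
    ridge_intercept: float
    ridge_coefficients: np.ndarray
    fold_seed: int

    @property
    def selected_feature_ids(self) -> np.ndarray:
        return self.feature_ids[self.rfecv_mask]

    def transform(self, X) -> np.ndarray:
        """Component scores for new samples (original full feature space)."""
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.rfecv_mask] - self.scale_mean) / self.scale_sd
        return (Z - self.pca_mean) @ self.loading_matrix

    def predict(self, X) -> np.ndarray:
        return self.transform(X) @ self.ridge_coefficients + self.ridge_intercept

    def stage_counts(self) -> dict[str, int]:
        return {
            "none": int(self.vt_mask.shape[0]),
            "vt": int(self.vt_mask.sum()),
            "ufs": int(self.ufs_mask.sum()),
            "rfecv": int(self.rfecv_mask.sum()),
            "pca": int(self.loading_matrix.shape[1]),
        }

    def save(self, path) -> None:
        np.savez(
            path,
            feature_ids=self.feature_ids.astype(str),
            params=np.asarray([str(self.params.as_dict())], dtype=object),
            vt_mask=self.vt_mask,
            ufs_mask=self.ufs_mask,
            rfecv_mask=self.rfecv_mask,
            scale_mean=self.scale_mean,
            scale_sd=self.scale_sd,
            pca_mean=self.pca_mean,
            loading_matrix=self.loading_matrix,
            component_scores=self.component_scores,
            ridge_intercept=np.asarray([self.ridge_intercept]),
            ridge_coefficients=self.ridge_coefficients,
            fold_seed=np.asarray([self.fold_seed]),
        )

    @classmethod
    def load(cls, path) -> "FittedPipeline":
        import ast

        with np.load(path, allow_pickle=True) as d:
            return cls(
                feature_ids=d["feature_ids"].astype(object),
                params=PipelineParams.from_dict(ast.literal_eval(str(d["params"][0]))),
                vt_mask=d["vt_mask"],
                ufs_mask=d["ufs_mask"],
                rfecv_mask=d["rfecv_mask"],
                scale_mean=d["scale_mean"],
                scale_sd=d["scale_sd"],
                pca_mean=d["pca_mean"],
                loading_matrix=d["loading_matrix"],
                component_scores=d["component_scores"],
                ridge_intercept=float(d["ridge_intercept"][0]),
                ridge_coefficients=d["ridge_coefficients"],
                fold_seed=int(d["fold_seed"][0]),
            )


def _compose(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    mask = np.zeros_like(outer)
    mask[np.flatnonzero(outer)[inner]] = True
    return mask


def fit_pipeline(
    params: PipelineParams,
    X,
    y,
    feature_ids: np.ndarray | None = None,
    seed: int = 0,
) -> FittedPipeline:
    """Run VT → UFS → RFECV → PCA on all samples and fit the final ridge."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = np.asarray([f"f{j}" for j in range(p)], dtype=object)

    def stage(name: str, fn: Callable):
        try:
            return fn()
        except PipelineError as err:
            raise PipelineError(f"{name}: {err}") from err

    vt_mask = stage("vt", lambda: variance_filter(X, params.variance_threshold))
    X_vt = X[:, vt_mask]
    ufs_local = stage("ufs", lambda: univariate_f_select(X_vt, y, params.percentile))
    ufs_mask = _compose(vt_mask, np.flatnonzero(ufs_local))
    X_ufs = X_vt[:, ufs_local]
    rfecv_local = stage(
        "rfecv",
        lambda: rfecv_select(
            X_ufs,
            y,
            step=params.rfecv_step,
            min_features=params.min_features_to_select,
            scoring=params.scoring,
            seed=seed,
        ),
    )
    rfecv_mask = _compose(ufs_mask, np.flatnonzero(rfecv_local))

    X_sel = X[:, rfecv_mask]
    Z, mu, sd = _standardize(X_sel)
    scores, loadings = stage("pca", lambda: pca_reduce(Z, params.n_components))
    pca_mean = Z.mean(axis=0)
    ridge = Ridge(alpha=RIDGE_ALPHA).fit(scores, y)
    return FittedPipeline(
        feature_ids=np.asarray(feature_ids, dtype=object),
        params=params,
        vt_mask=vt_mask,
        ufs_mask=ufs_mask,
        rfecv_mask=rfecv_mask,
        scale_mean=mu,
        scale_sd=sd,
        pca_mean=pca_mean,
        loading_matrix=loadings,
        component_scores=scores,
        ridge_intercept=float(ridge.intercept_),
        ridge_coefficients=np.asarray(ridge.coef_, dtype=float),
        fold_seed=seed,
    )


def _cv_component_score(scores: np.ndarray, y: np.ndarray, scoring: str, seed: int) -> float:
    """10-fold CV score of a ridge model on the component scores."""
    kf = KFold(n_splits=10, shuffle=True, random_state=seed)
    vals = []
    for tr, te in kf.split(scores):
        model = Ridge(alpha=RIDGE_ALPHA).fit(scores[tr], y[tr])
        pred = model.predict(scores[te])
        e = y[te] - pred
        mse = float(np.mean(e * e))
        if scoring == "r2":
            var = float(np.var(y[te]))
            vals.append(1.0 - mse / var if var > 0 else -np.inf)
        elif scoring == "mse":
            vals.append(-mse)
        elif scoring == "rmse":
            vals.append(-math.sqrt(mse))
        else:
            vals.append(-float(np.mean(np.abs(e))))
    return float(np.mean(vals))


def pipeline_fitness(params: PipelineParams, X, y, seed: int = 0) -> float:
    """Fitness the DBO maximizes: CV score of the end-to-end pipeline.

    Error scorings are negated so fitness is always maximized; any stage
    failure (including a degenerate target) yields ``-inf``.
    """
    try:
        fp = fit_pipeline(params, X, y, seed=seed)
        val = _cv_component_score(fp.component_scores, np.asarray(y, dtype=float), params.scoring, seed)
    except Exception:
        return -np.inf
    return val if np.isfinite(val) else -np.inf


def make_objective(
    X,
    y,
    config: dbo.DBOConfig,
    seed: int = 0,
    cache: dict | None = None,
) -> Callable[[np.ndarray], float]:
    """Decode-and-score objective with stage-level caching.

    Two observations collapse many DBO positions onto work already done:
    the variance threshold's only effect is the VT survivor mask, which is
    fully determined by the survivor count (variances are compared to a
    single cutoff); and the expensive RFECV elimination path depends only on
    (VT count, percentile, step, min_features, scoring) — not on the PCA
    dimension.  Fitness values are therefore cached on the decoded point and
    RFECV masks on their own sub-key.  Per-feature F statistics are computed
    once: each feature's F against the target does not depend on which other
    features survive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    var = X.var(axis=0)
    if cache is None:
        cache = {}
    mask_cache: dict[tuple, np.ndarray] = {}
    f_scores: list[np.ndarray] = []  # lazy singleton

    def _rfecv_mask(params: PipelineParams, n_vt: int) -> np.ndarray:
        key = (
            n_vt,
            params.percentile,
            params.rfecv_step,
            params.min_features_to_select,
            params.scoring,
        )
        if key in mask_cache:
            return mask_cache[key]
        vt_idx = np.flatnonzero(var >= params.variance_threshold)
        if vt_idx.size == 0:
            raise PipelineError("variance threshold removed every feature")
        if not f_scores:
            f_scores.append(univariate_f_scores(X, y))
        Fv = f_scores[0][vt_idx]
        n_keep = int(math.ceil(vt_idx.size * params.percentile / 100.0))
        order = np.argsort(-Fv, kind="stable")
        ufs_idx = np.sort(vt_idx[order[:n_keep]])  # original column order, as in fit_pipeline
        local = rfecv_select(
            X[:, ufs_idx],
            y,
            step=params.rfecv_step,
            min_features=params.min_features_to_select,
            scoring=params.scoring,
            seed=seed,
        )
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[ufs_idx[local]] = True
        mask_cache[key] = mask
        return mask

    def objective(position: np.ndarray) -> float:
        params = params_from_position(position, config)
        n_vt = int((var >= params.variance_threshold).sum())
        key = (
            n_vt,
            params.percentile,
            params.rfecv_step,
            params.min_features_to_select,
            params.scoring,
            params.n_components,
        )
        if key in cache:
            return cache[key]
        try:
            sel = _rfecv_mask(params, n_vt)
            Z, _, _ = _standardize(X[:, sel])
            scores, _ = pca_reduce(Z, params.n_components)
            val = _cv_component_score(scores, y, params.scoring, seed)
            if not np.isfinite(val):
                val = -np.inf
        except Exception:
            val = -np.inf
        cache[key] = val
        return val

    return objective


def optimize_pipeline(
    X,
    y,
    pop_size: int = 50,
    max_iter: int = 100,
    bounds: ParamBounds | None = None,
    seed: int = 0,
    **dbo_kw,
) -> tuple[PipelineParams, float, "dbo.OptimizationTrace"]:
    """DBO search over the pipeline parameter space for one phenotype."""
    X = np.asarray(X, dtype=float)
    if bounds is None:
        bounds = default_param_bounds(X.shape[0])
    config = bounds.to_dbo_config(pop_size=pop_size, max_iter=max_iter, seed=seed, **dbo_kw)
    objective = make_objective(X, y, config, seed=seed)
    best_pos, best_fit, trace = dbo.optimize(objective, config)
    return params_from_position(best_pos, config), best_fit, trace


def _ridge_cv_r2(Z: np.ndarray, y: np.ndarray, seed: int, alpha: float = RIDGE_ALPHA) -> float:
    """10-fold CV R² of ridge on a (possibly wide) standardized matrix."""
    n = Z.shape[0]
    fold_groups = _group_folds(_fold_test_sets(n, 10, seed))
    M = np.linalg.inv(Z @ Z.T + alpha * np.eye(n))
    a = M @ (y - y.mean())
    return _cv_residual_scores(M, a, y, fold_groups, "r2")


def stage_progression(params: PipelineParams, X, y, seed: int = 0) -> pd.DataFrame:
    """Cross-validated R² after each pipeline stage (the stage-wise gain curve).

    Stages: no selection, VT, UFS, RFECV (ridge on standardized survivors) and
    PCA (ridge on component scores).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fp = fit_pipeline(params, X, y, seed=seed)
    rows = []
    for name, mask in (
        ("none", np.ones(X.shape[1], dtype=bool)),
        ("vt", fp.vt_mask),
        ("ufs", fp.ufs_mask),
        ("rfecv", fp.rfecv_mask),
    ):
        Z, _, _ = _standardize(X[:, mask])
        rows.append({"stage": name, "n_features": int(mask.sum()), "cv_r2": _ridge_cv_r2(Z, y, seed)})
    rows.append(
        {
            "stage": "pca",
            "n_features": int(fp.loading_matrix.shape[1]),
            "cv_r2": _cv_component_score(fp.component_scores, y, "r2", seed),
        }
    )
    return pd.DataFrame(rows)
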