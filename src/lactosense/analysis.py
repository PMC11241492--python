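"""Descriptive sensory analytics.

Distribution summaries (box-plot statistics) per channel, Spearman rank
correlation matrices between channels, counts of original genomic features
jointly retained by the selection pipeline for pairs of phenotypes, and the
association between phenotype correlation and shared-feature count.  Shared
features are counted at the post-RFECV stage — the last stage at which
survivors are original features rather than principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_matrix",
    "boxplot_stats",
    "shared_feature_counts",
    "overlap_correlation_trend",
    "TrendResult",
    "plot_boxplots",
    "plot_heatmap",
    "plot_importance",
]


def spearman_matrix(P: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation (mid-ranks for ties) between all channels."""
    if P.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {P.shape[0]}")
    for col in P.columns:
        if float(np.var(P[col].to_numpy(dtype=float))) == 0.0:
            raise ValueError(f"column {col!r} is constant; Spearman correlation undefined")
    vals = P.to_numpy(dtype=float)
    if P.shape[1] == 1:
        rho = np.ones((1, 1))
    else:
        rho = stats.spearmanr(vals).statistic
        if np.isscalar(rho):  # two-column input returns a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=P.columns, columns=P.columns)


def boxplot_stats(P: pd.DataFrame) -> pd.DataFrame:
    """Tukey box-plot statistics per channel.

    Quartiles use linear interpolation; whiskers reach the most extreme data
    points within 1.5·IQR of the quartiles; everything beyond is flagged as an
    outlier (sample ids reported).
    """
    if P.shape[0] < 5:
        raise ValueError(f"need at least 5 samples, got {P.shape[0]}")
    rows = []
    for col in P.columns:
        x = P[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = (x >= lo_f) & (x <= hi_f)
        rows.append(
            {
                "phenotype": col,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_lo": float(x[inside].min()),
                "whisker_hi": float(x[inside].max()),
                "outliers": list(P.index[~inside]),
            }
        )
    return pd.DataFrame(rows).set_index("phenotype")


def shared_feature_counts(
    masks: Mapping[str, Iterable], universe: Iterable | None = None
) -> pd.DataFrame:
    """Pairwise intersection cardinality of per-phenotype survivor sets.

    The diagonal is each phenotype's own survivor count.  With ``universe``
    given, every survivor id must belong to it (guards against masks computed
    over different feature spaces).
    """
    sets = {name: set(ids) for name, ids in masks.items()}
    if universe is not None:
        allowed = set(universe)
        for name, s in sets.items():
            stray = s - allowed
            if stray:
                raise ValueError(
                    f"phenotype {name!r} has {len(stray)} feature ids outside the common id space"
                )
    names = list(sets)
    out = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            out[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(out, index=names, columns=names)


@dataclass
class TrendResult:
    """Association between phenotype |correlation| and shared-feature count."""

    rho: float  # Spearman rho over unordered phenotype pairs; NaN if degenerate
    pairs: pd.DataFrame  # columns: phenotype_a, phenotype_b, abs_corr, shared
    note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def overlap_correlation_trend(corr: pd.DataFrame, sfm: pd.DataFrame) -> TrendResult:
    """Spearman rho of |pairwise correlation| vs shared-feature count.

    Computed over all unordered phenotype pairs.  A degenerate input (all
    shared counts equal, or all |correlations| equal) has no defined rank
    correlation and is reported as NaN with an explanation.
    """
    if list(corr.columns) != list(sfm.columns) or list(corr.index) != list(sfm.index):
        raise ValueError("correlation and shared-feature matrices must share the phenotype set")
    names = list(corr.columns)
    if len(names) < 3:
        raise ValueError(f"need at least 3 phenotypes (3 pairs), got {len(names)}")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "phenotype_a": names[i],
                    "phenotype_b": names[j],
                    "abs_corr": abs(float(corr.iloc[i, j])),
                    "shared": int(sfm.iloc[i, j]),
                }
            )
    pairs = pd.DataFrame(rows)
    if pairs["shared"].nunique() == 1 or pairs["abs_corr"].nunique() == 1:
        return TrendResult(
            rho=float("nan"),
            pairs=pairs,
            note="rank correlation undefined: one of the pair variables is constant",
        )
    rho = float(stats.spearmanr(pairs["abs_corr"], pairs["shared"]).statistic)
    return TrendResult(rho=rho, pairs=pairs)


# ---------------------------------------------------------------------------
# plotting (matplotlib, headless-safe)


def plot_boxplots(P: pd.DataFrame, ax=None, title: str | None = None):
    """Box plots of all channels on one axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.8 * P.shape[1]), 4))
    ax.boxplot([P[c].to_numpy(dtype=float) for c in P.columns], tick_labels=list(P.columns))
    ax.set_ylabel("response")
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_heatmap(M: pd.DataFrame, ax=None, title: str | None = None, fmt: str = "{:.2f}"):
    """Annotated heatmap of a correlation or shared-feature matrix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.7 * M.shape[1], 1 + 0.7 * M.shape[0]))
    vals = M.to_numpy(dtype=float)
    im = ax.imshow(vals, cmap="coolwarm")
    ax.set_xticks(range(M.shape[1]), labels=list(M.columns), rotation=90)
    ax.set_yticks(range(M.shape[0]), labels=list(M.index))
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            ax.text(j, i, fmt.format(vals[i, j]), ha="center", va="center", fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    return ax


def plot_importance(iv, k: int = 10, ax=None, title: str | None = None):
    """Horizontal bar chart of the top-k signed feature contributions."""
    from .importance import rank_top_k

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    top = rank_top_k(iv, k)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1))
    ids = [t[0] for t in top][::-1]
    vals = [t[1] for t in top][::-1]
    colors = ["#c0504d" if v < 0 else "#4f81bd" for v in vals]
    ax.barh(ids, vals, color=colors)
    ax.set_xlabel("signed contribution (standardized-feature scale)")
    if title:
        ax.set_title(title)
    return ax
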