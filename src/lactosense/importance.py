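"""Back-projection of ridge coefficients through PCA loadings.

The final model predicts from principal-component scores, so a single
original feature influences the prediction through every component it loads
on.  Because both maps are linear, the total signed contribution of feature j
is the chain-rule product

    c_j = sum_k L_jk * beta_k   (c = L @ beta),

where L is the loading matrix over the RFECV-surviving standardized features
and beta the ridge coefficients on the scores.  ``c`` is exactly the gradient
of the prediction with respect to the standardized features, so it reproduces
the component-space prediction: ``scores @ beta == Z_centered @ c``.

Contributions are reported on the standardized-feature scale used by the
pipeline fits (|c| is then comparable across features); ranking uses the
absolute value with the sign retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import FittedPipeline

__all__ = ["ImportanceVector", "propagate_importance", "rank_top_k", "importance_table"]


@dataclass
class ImportanceVector:
    feature_ids: np.ndarray
    contribution: np.ndarray

    def __len__(self) -> int:
        return len(self.feature_ids)

    def abs_rank(self) -> np.ndarray:
        """Permutation ordering features by |contribution| desc, ties by id."""
        order = sorted(
            range(len(self)),
            key=lambda i: (-abs(float(self.contribution[i])), str(self.feature_ids[i])),
        )
        return np.asarray(order, dtype=int)


def propagate_importance(fp: FittedPipeline) -> ImportanceVector:
    """Signed total contribution of each RFECV survivor: ``c = L @ beta``."""
    L = np.asarray(fp.loading_matrix, dtype=float)
    beta = np.asarray(fp.ridge_coefficients, dtype=float)
    if L.ndim != 2 or beta.ndim != 1 or L.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: loadings {L.shape} vs coefficients {beta.shape}"
        )
    ids = fp.selected_feature_ids
    if len(ids) != L.shape[0]:
        raise ValueError(
            f"{len(ids)} surviving features but {L.shape[0]} loading rows"
        )
    return ImportanceVector(feature_ids=np.asarray(ids, dtype=object), contribution=L @ beta)


def rank_top_k(iv: ImportanceVector, k: int = 10) -> list[tuple[str, float]]:
    """Top-k features by |contribution| (signed values retained)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    order = iv.abs_rank()[: min(k, len(iv))]
    return [(str(iv.feature_ids[i]), float(iv.contribution[i])) for i in order]


def feature_class(feature_id: str) -> str:
    """Feature class (SNP/GENE/IGR/...) from the id prefix."""
    return str(feature_id).split("_", 1)[0]


def importance_table(iv: ImportanceVector) -> pd.DataFrame:
    """Per-feature table: id, class, signed contribution, absolute rank."""
    order = iv.abs_rank()
    return pd.DataFrame(
        {
            "feature_id": [str(iv.feature_ids[i]) for i in order],
            "class": [feature_class(iv.feature_ids[i]) for i in order],
            "contribution": [float(iv.contribution[i]) for i in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
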