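"""Covariate adjustment, heritability filtering and per-family splitting.

Expression is carried as a pandas DataFrame with probe ids on the rows and
sample ids on the columns; phenotypes as a DataFrame indexed by sample id
with trait and covariate columns.  Traits and probes are adjusted for
covariates (age, sex) by ordinary least squares and the residuals carried
forward, before any network construction or mixed-model decorrelation.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from . import lmm
from .pedkin import KinshipMatrix, Pedigree

__all__ = [
    "PreprocessError",
    "regress_out_covariates",
    "filter_heritable",
    "split_by_family",
    "impute_missing",
]

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


def _design(covariates: np.ndarray) -> np.ndarray:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] == 1:
        covariates = covariates.T
    X = np.column_stack([np.ones(covariates.shape[0]), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PreprocessError("covariate matrix is rank-deficient (with intercept)")
    return X


def regress_out_covariates(values, covariates):
    """Replace values by OLS residuals on (intercept, covariates).

    ``values`` may be a vector of length n (one observation per sample) or
    a features-by-samples matrix/DataFrame; ``covariates`` is samples-by-
    covariates (an intercept is added internally).  The output is
    orthogonal to the covariate columns.
    """
    X = _design(covariates)
    Q, _ = np.linalg.qr(X)

    def _resid(mat: np.ndarray) -> np.ndarray:
        return mat - (mat @ Q) @ Q.T

    if isinstance(values, pd.DataFrame):
        if values.shape[1] != X.shape[0]:
            raise PreprocessError("sample count mismatch between values and covariates")
        return pd.DataFrame(_resid(values.to_numpy(dtype=float)),
                            index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(_resid(values.to_numpy(dtype=float)[None, :])[0],
                         index=values.index, name=values.name)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        return _resid(arr[None, :])[0]
    if arr.shape[1] != X.shape[0]:
        raise PreprocessError("sample count mismatch between values and covariates")
    return _resid(arr)


def impute_missing(expr: pd.DataFrame, max_missing: float = 0.10) -> pd.DataFrame:
    """Drop probes with too many missing values; mean-impute the rest.

    Robust correlation needs complete vectors, so probes with more than
    ``max_missing`` missing fraction are dropped (logged) and remaining
    gaps are filled with the probe mean.
    """
    frac = expr.isna().mean(axis=1)
    drop = frac > max_missing
    if drop.any():
        logger.warning("dropping %d probes with >%.0f%% missing values",
                       int(drop.sum()), 100 * max_missing)
    kept = expr.loc[~drop]
    if kept.isna().any().any():
        kept = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    return kept


def filter_heritable(
    expr: pd.DataFrame,
    ped: Pedigree,
    K: KinshipMatrix,
    top_fraction: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep the most heritable probes.

    Each probe is fitted with an intercept-only mixed model (genetic 2K,
    shared-family and identity kernels); probes are ranked by
    h2 = sigma_g^2 / (sigma_g^2 + sigma_v^2 + sigma_e^2) and the
    ``ceil(top_fraction * P)`` highest kept.  Ties at the cutoff are broken
    by probe id so the subset is deterministic.  Returns the kept subset
    (original row order) and the full per-probe h2 series (NaN where a fit
    failed).
    """
    if not 0 < top_fraction <= 1:
        raise PreprocessError("top_fraction must be in (0, 1]")
    P = expr.shape[0]
    n_keep = math.ceil(top_fraction * P)
    sample_ids = list(expr.columns)
    kernels = [
        ("genetic", lmm.genetic_kernel(K, sample_ids)),
        ("family", lmm.family_block_kernel(ped, sample_ids)),
    ]
    Y = expr.to_numpy(dtype=float)
    sd = Y.std(axis=1)
    ok = sd > 1e-12
    h2 = pd.Series(np.nan, index=expr.index, name="h2")
    if ok.any():
        fits, _ = lmm.reml_grid_fit(Y[ok], np.ones((len(sample_ids), 1)), kernels)
        h2.loc[ok] = fits["h2"].to_numpy()
    n_failed = int(h2.isna().sum())
    if n_failed:
        warnings.warn(f"{n_failed} probe(s) had no usable heritability fit; "
                      "excluded from the kept set")
    ranked = (
        h2.dropna()
        .rename_axis("probe_id")
        .reset_index()
        .sort_values(["h2", "probe_id"], ascending=[False, True])
    )
    keep_ids = set(ranked["probe_id"].head(n_keep))
    subset = expr.loc[expr.index.isin(keep_ids)]
    return subset, h2


def split_by_family(expr: pd.DataFrame, ped: Pedigree) -> dict[str, pd.DataFrame]:
    """Partition the sample columns by pedigree family.

    The probe order is preserved; the union of the column sets equals the
    input columns.  Families follow pedigree order.
    """
    unknown = [s for s in expr.columns if s not in ped]
    if unknown:
        raise PreprocessError(
            f"samples absent from the pedigree: {unknown[:5]}"
        )
    out: dict[str, pd.DataFrame] = {}
    for fam in ped.family_ids:
        cols = [s for s in expr.columns if ped.family_of(s) == fam]
        if cols:
            out[fam] = expr[cols]
    return out
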