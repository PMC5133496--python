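"""Per-probe mixed-model association scan (the non-network comparator).

For each probe the model ``Y = mu + u + v + beta * X + e`` is fitted
(genetic kernel 2K, shared-family block, identity residual) and the Wald
test of beta recorded, with Bonferroni control over the number of probes
scanned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import lmm
from .pedkin import KinshipMatrix, Pedigree

__all__ = ["single_probe_scan"]

logger = logging.getLogger(__name__)


def single_probe_scan(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
    ped: Pedigree,
    alpha: float = 0.05,
    reuse_null_components: bool = False,
) -> pd.DataFrame:
    """Scan every probe for association with a quantitative trait.

    By default the variance components are re-estimated for every probe,
    exactly as the per-probe model is written; each probe's numbers equal
    an independent ``fit_lmm`` + ``wald_test``.  With
    ``reuse_null_components=True`` the components are estimated once under
    the no-probe null model and reused for every probe's GLS fit — a fast
    approximation for large probe counts.

    Returns a DataFrame with columns probe_id, beta, se, p, p_bonferroni,
    significant; probes whose fit failed appear with NaN statistics and
    are logged (they still count toward the Bonferroni denominator).
    """
    if trait not in pheno.columns:
        raise lmm.LMMError(f"trait {trait!r} not in phenotype table")
    sample_ids = [s for s in expr.columns if s in pheno.index]
    if len(sample_ids) < expr.shape[1]:
        raise lmm.LMMError("phenotype table is missing samples present in expression")
    y = pheno.loc[sample_ids, trait].to_numpy(dtype=float)
    kernels = [
        ("genetic", lmm.genetic_kernel(K, sample_ids)),
        ("family", lmm.family_block_kernel(ped, sample_ids)),
    ]
    X_expr = expr[sample_ids].to_numpy(dtype=float)
    P = expr.shape[0]
    rows = []

    if reuse_null_components:
        null_fit = lmm.fit_lmm(
            lmm.LMMSpec(y, np.ones((len(sample_ids), 1)), kernels)
        )
        se2 = null_fit.sigma_e2
        V = se2 * np.eye(len(sample_ids))
        for name, Km in kernels:
            V += null_fit.variance_components[name] * Km
        L = linalg.cholesky(V, lower=True)
        yt = linalg.solve_triangular(L, y, lower=True)
        ones_t = linalg.solve_triangular(L, np.ones(len(sample_ids)), lower=True)
        for i, probe in enumerate(expr.index):
            xt = linalg.solve_triangular(L, X_expr[i], lower=True)
            Xt = np.column_stack([ones_t, xt])
            XtX = Xt.T @ Xt
            try:
                beta_hat = linalg.solve(XtX, Xt.T @ yt, assume_a="pos")
                cov = linalg.inv(XtX)
            except linalg.LinAlgError:
                rows.append((probe, np.nan, np.nan, np.nan))
                continue
            beta, se = float(beta_hat[1]), float(np.sqrt(cov[1, 1]))
            p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
            rows.append((probe, beta, se, p))
    else:
        ones = np.ones(len(sample_ids))
        for i, probe in enumerate(expr.index):
            design = np.column_stack([ones, X_expr[i]])
            try:
                fit = lmm.fit_lmm(lmm.LMMSpec(y, design, kernels))
                beta, se, p = lmm.wald_test(fit, 1)
            except (lmm.LMMError, lmm.ConvergenceError) as exc:
                logger.warning("probe %s: fit failed (%s)", probe, exc)
                rows.append((probe, np.nan, np.nan, np.nan))
                continue
            rows.append((probe, beta, se, p))

    out = pd.DataFrame(rows, columns=["probe_id", "beta", "se", "p"])
    out["p_bonferroni"] = np.minimum(out["p"] * P, 1.0)
    out["significant"] = out["p"] <= alpha / P
    out["n"] = len(sample_ids)
    return out
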