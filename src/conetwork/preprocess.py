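"""Covariate residualization and variance-based gene filtering."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def residualize(expr: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene profile by its OLS residuals against age and sex.

    The design is (intercept, age, sex).  Samples absent from ``cov``
    raise; samples with missing covariate values are dropped with a
    warning.  Residuals have zero mean and are orthogonal to both
    covariates.
    """
    if cov.index.has_duplicates:
        dupes = cov.index[cov.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in covariate table: {dupes[:10]}")
    missing = [s for s in expr.columns if s not in cov.index]
    if missing:
        raise ValueError(f"samples missing from covariate table: {missing[:10]}")
    cov = cov.loc[expr.columns, ["age", "sex"]]
    complete = cov.notna().all(axis=1)
    if not complete.all():
        dropped = cov.index[~complete].tolist()
        log.warning("dropping %d samples with missing covariates: %s", len(dropped), dropped[:10])
        cov = cov.loc[complete]
        expr = expr.loc[:, complete.to_numpy()]

    design = np.column_stack([np.ones(len(cov)), cov["age"].to_numpy(float), cov["sex"].to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for col, name in [(1, "age"), (2, "sex")]:
            if np.unique(design[:, col]).size == 1:
                raise ValueError(f"rank-deficient design: column '{name}' is constant")
        raise ValueError("rank-deficient design: age and sex are collinear")

    y = np.asarray(expr, dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


def filter_genes(expr: pd.DataFrame, min_variance_quantile: float = 0.0) -> pd.DataFrame:
    """Drop genes whose sample variance falls below the given quantile.

    ``min_variance_quantile=0`` keeps everything.  Gene order is
    preserved for the survivors.
    """
    if not 0 <= min_variance_quantile < 1:
        raise ValueError(f"min_variance_quantile must be in [0, 1), got {min_variance_quantile}")
    variances = np.asarray(expr, dtype=float).var(axis=1, ddof=1)
    threshold = np.quantile(variances, min_variance_quantile)
    keep = variances >= threshold
    if not keep.any():
        raise ValueError("variance filter removed every gene")
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("variance filter removed %d of %d genes", n_removed, len(keep))
    return expr.loc[keep]
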