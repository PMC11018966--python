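"""Correlation, soft-threshold adjacency, scale-free diagnostics and TOM.

All matrices are dense :class:`pandas.DataFrame` objects indexed by gene id
on both axes.  Matrix sizes up to ~20k genes are handled in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_MODES = ("signed", "unsigned")

#: soft-threshold powers used by default for each mode
DEFAULT_BETA = {"signed": 10.0, "unsigned": 3.0}


@dataclass
class NetworkConfig:
    """Parameters for one network run.

    Defaults encode the reference analysis constants: soft power 10
    (signed) / 3 (unsigned), minimum module size 30, deepSplit 2,
    eigengene merge threshold 0.8, hub quantile 0.90, assignment cutoff
    0.10 and predicted-function cutoff 0.20.
    """

    mode: str = "signed"
    beta: float | None = None
    min_module_size: int = 30
    deep_split: int = 2
    merge_cor_threshold: float = 0.8
    hub_quantile: float = 0.90
    assign_cutoff: float = 0.10
    predict_cutoff: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.beta is None:
            self.beta = DEFAULT_BETA[self.mode]
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 < self.merge_cor_threshold < 1:
            raise ValueError("merge_cor_threshold must be in (0,1)")
        if not 0 < self.hub_quantile < 1:
            raise ValueError("hub_quantile must be in (0,1)")
        if not 0 < self.assign_cutoff < 1:
            raise ValueError("assign_cutoff must be in (0,1)")
        if not 0 < self.predict_cutoff < 1:
            raise ValueError("predict_cutoff must be in (0,1)")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be an integer in 0..4")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between all gene profiles (rows).

    Raises if fewer than 3 samples or if any gene has zero variance
    (filter such genes first).  Output is exactly symmetric with unit
    diagonal.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    values = np.asarray(expr, dtype=float)
    sd = values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = list(expr.index[zero[:10]])
        raise ValueError(f"zero-variance gene(s): {names}")
    cor = np.corrcoef(values)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def adjacency(cor: pd.DataFrame, mode: str, beta: float) -> pd.DataFrame:
    """Soft-threshold adjacency from a correlation matrix.

    unsigned: ``a = |r| ** beta``;  signed: ``a = ((1 + r) / 2) ** beta``.
    The diagonal is stored as 1 but excluded from connectivity sums
    downstream.
    """
    if mode not in VALID_MODES:
        raise ValueError(f"mode must be one of {VALID_MODES}, got {mode!r}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    r = np.asarray(cor, dtype=float)
    if mode == "unsigned":
        adj = np.abs(r) ** beta
    else:
        adj = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-gene connectivity ``k_i = sum_{u != i} a_iu``."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adj.index, name="connectivity")


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit (scale-free diagnostic).

    Connectivities are binned into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity) over
    non-empty bins.
    """
    k = connectivity(adj).to_numpy()
    return fit_log_log_r2(k, n_bins)


def fit_log_log_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) vs log10(mean k) over equal-width k bins."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    k = np.asarray(k, dtype=float)
    if np.unique(k).size < 2:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(mask.sum() / k.size))
    log_k = np.asarray(log_k)
    log_f = np.asarray(log_f)
    if log_k.size < 2 or np.unique(log_k).size < 2:
        raise ValueError("not enough distinct bins for a fit")
    slope, intercept = np.polyfit(log_k, log_f, 1)
    resid = log_f - (slope * log_k + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    For i != j::

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with ``l_ij = sum_{u != i,j} a_iu * a_uj`` and ``k_i`` the
    connectivity.  Diagonal is 1; an isolated pair (k_i = k_j = 0,
    a_ij = 0) gets TOM 0.
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # l_ij over u != i,j: the matmul includes no u==i or u==j terms since
    # diag(a) = 0 removes them.
    l = a @ a
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom, 0.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)
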