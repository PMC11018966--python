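"""Module detection: 1-TOM clustering, dynamic tree cut, eigengenes,
membership, eigengene-based merging and hub calling.

Module labels follow the classical color vocabulary, assigned by
decreasing module size; ``grey`` is reserved for unassigned genes.
All tie-breaks are by lowest gene/module index so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

GREY = "grey"

# classical module color vocabulary, in assignment order
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2",
]


@dataclass
class MembershipTable:
    """Gene-module correlations (MM) plus assigned-module quantile ranks.

    ``mm`` holds MM for every gene x module pair; ``assigned`` the gene's
    own module label; ``own_mm`` / ``quantile`` the MM and within-module
    quantile rank of |MM| for the assigned module (NaN for grey genes).
    """

    mm: pd.DataFrame  # genes x modules
    assigned: pd.Series  # gene -> module label
    own_mm: pd.Series
    quantile: pd.Series

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.assigned,
                "MM": self.own_mm,
                "one_minus_quantile": 1.0 - self.quantile,
            }
        )


def cluster_genes(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram on the dissimilarity 1 - TOM.

    Returns a scipy linkage matrix.
    """
    if tom.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    d = 1.0 - np.asarray(tom, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite dissimilarities")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return linkage(squareform(d, checks=False), method="average")


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Map integer module ids to colors by decreasing size.

    Ties broken by the module's smallest member position.
    """
    out = pd.Series(GREY, index=labels.index, dtype=object)
    nongrey = labels[labels != 0]
    order = []
    for mod, grp in nongrey.groupby(nongrey):
        first = int(np.flatnonzero(labels.to_numpy() == mod)[0])
        order.append((-len(grp), first, mod))
    for rank, (_, _, mod) in enumerate(sorted(order)):
        color = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module_{rank + 1}"
        out[labels == mod] = color
    return out


def cut_tree_dynamic(
    dendrogram: np.ndarray,
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
) -> pd.Series:
    """Two-stage hybrid cut of the dendrogram into modules.

    Stage 1 cuts at the fraction ``(99 - 2.5 * deep_split) / 100`` of the
    merge-height range (deeper split => lower cut => more, smaller
    clusters) and keeps branches with at least ``min_module_size``
    members.  Stage 2 reassigns each leftover gene to the module with the
    smallest average dissimilarity, provided that average is below the
    cut height and beats the gene's average dissimilarity to genes
    outside that module; otherwise it stays grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in range(5):
        raise ValueError("deep_split must be in 0..4")
    genes = tom.index
    n = len(genes)
    if min_module_size > n:
        import logging

        logging.getLogger(__name__).warning(
            "min_module_size %d exceeds gene count %d: all genes grey", min_module_size, n
        )
        return pd.Series(GREY, index=genes, dtype=object)

    heights = dendrogram[:, 2]
    frac = (99.0 - 2.5 * deep_split) / 100.0
    cut_height = heights.min() + frac * (heights.max() - heights.min())
    raw = fcluster(dendrogram, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    next_id = 1
    for cl in np.unique(raw):
        members = np.flatnonzero(raw == cl)
        if members.size >= min_module_size:
            labels[members] = next_id
            next_id += 1

    # stage 2: PAM-like reassignment of unassigned genes
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    module_ids = np.arange(1, next_id)
    if module_ids.size:
        member_idx = {m: np.flatnonzero(labels == m) for m in module_ids}
        unassigned = np.flatnonzero(labels == 0)
        assigned_new = {}
        for g in unassigned:
            best_mod, best_avg = 0, np.inf
            for m in module_ids:
                avg = d[g, member_idx[m]].mean()
                if avg < best_avg - 1e-15:
                    best_mod, best_avg = m, avg
            if best_mod and best_avg < cut_height:
                outside = np.setdiff1d(
                    np.flatnonzero(labels != best_mod), [g], assume_unique=False
                )
                if outside.size and best_avg < d[g, outside].mean():
                    assigned_new[g] = best_mod
        for g, m in assigned_new.items():
            labels[g] = m

    return _relabel_by_size(pd.Series(labels, index=genes))


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Each eigengene is rescaled to unit variance and signed so it
    correlates non-negatively with the module's mean standardized
    profile.  Returns a sample x module DataFrame; grey is skipped.
    """
    z = _standardize_rows(np.asarray(expr, dtype=float))
    modules = sorted(set(labels) - {GREY})
    mes = {}
    label_arr = labels.reindex(expr.index).to_numpy()
    for mod in modules:
        sub = z[label_arr == mod]
        if sub.shape[0] == 0:
            raise ValueError(f"module {mod!r} has no genes")
        if sub.shape[0] == 1:
            v = sub[0]
        else:
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            v = vt[0]
        mean_profile = sub.mean(axis=0)
        if float(v @ mean_profile) < 0:
            v = -v
        sd = v.std(ddof=1)
        mes[mod] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    out = pd.DataFrame(mes, index=expr.columns)
    return out[modules]


def module_membership(expr: pd.DataFrame, mes: pd.DataFrame, labels: pd.Series) -> MembershipTable:
    """MM (Pearson r of gene profile vs each eigengene) for all pairs.

    Within-module quantile ranks of |MM| (rank / size, average ties,
    gene included) are attached for assigned genes.
    """
    shared = [s for s in expr.columns if s in mes.index]
    if not shared:
        raise ValueError("no shared samples between expression and eigengenes")
    zg = _standardize_rows(np.asarray(expr[shared], dtype=float))
    zm = _standardize_rows(np.asarray(mes.loc[shared], dtype=float).T)
    mm_values = zg @ zm.T / (len(shared) - 1)
    mm = pd.DataFrame(
        np.clip(mm_values, -1.0, 1.0), index=expr.index, columns=mes.columns
    )

    assigned = labels.reindex(expr.index)
    own_mm = pd.Series(np.nan, index=expr.index, dtype=float)
    quantile = pd.Series(np.nan, index=expr.index, dtype=float)
    for mod in mes.columns:
        members = assigned.index[assigned == mod]
        if len(members) == 0:
            continue
        vals = mm.loc[members, mod]
        own_mm[members] = vals
        quantile[members] = rankdata(vals.abs(), method="average") / len(members)
    return MembershipTable(mm=mm, assigned=assigned, own_mm=own_mm, quantile=quantile)


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_cor_threshold: float = 0.8,
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge the module pair with maximal eigengene correlation.

    One pair per iteration, eigengenes recomputed after every merge;
    stops when no pair's ME correlation exceeds the threshold.  Grey is
    never merged.  Returns relabeled assignments and final eigengenes.
    """
    labels = labels.copy()
    if (labels != GREY).sum() == 0:
        raise ValueError("no non-grey modules to merge")
    while True:
        mes = module_eigengene(expr, labels)
        mods = list(mes.columns)
        if len(mods) < 2:
            break
        cor = np.corrcoef(np.asarray(mes, dtype=float).T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(int(np.argmax(cor)), cor.shape)
        if cor[i, j] <= merge_cor_threshold:
            break
        keep, absorb = sorted((mods[i], mods[j]))
        labels[labels == absorb] = keep
    # relabel by size for a clean color sequence
    mods = sorted(set(labels) - {GREY})
    as_int = pd.Series(0, index=labels.index, dtype=int)
    for k, mod in enumerate(mods, start=1):
        as_int[labels == mod] = k
    labels = _relabel_by_size(as_int)
    return labels, module_eigengene(expr, labels)


def call_hubs(
    membership: MembershipTable,
    hub_quantile: float = 0.90,
    assign_cutoff: float = 0.10,
) -> pd.DataFrame:
    """Flag hubs (top |MM| quantile within module) and unreliable genes.

    hub: 1 - q(|MM|) < 1 - hub_quantile within the assigned module;
    unreliable: |MM| to the assigned module below ``assign_cutoff``.
    Grey genes get neither flag.
    """
    q = membership.quantile
    own = membership.own_mm
    hub = (1.0 - q) < (1.0 - hub_quantile)
    unreliable = own.abs() < assign_cutoff
    grey = membership.assigned == GREY
    return pd.DataFrame(
        {
            "module": membership.assigned,
            "MM": own,
            "one_minus_quantile": 1.0 - q,
            "hub": hub.fillna(False) & ~grey,
            "unreliable": unreliable.fillna(False) & ~grey,
        }
    )
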