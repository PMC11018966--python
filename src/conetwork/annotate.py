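"""Module annotation: marker-list enrichment, eigengene-trait correlation,
cross-network overlap and guilt-by-association calls for lncRNAs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from conetwork.moddetect import GREY, MembershipTable

log = logging.getLogger(__name__)


def list_enrichment(
    labels: pd.Series,
    lists: dict[str, set[str]],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each marker list in each module.

    ``p_raw`` is the upper tail P(X >= overlap) with population =
    universe size, successes = list size (after intersecting with the
    universe), draws = module size.  Bonferroni is over all non-grey
    module x list tests.
    """
    if universe is None:
        universe = set(labels.index)
    if not universe:
        raise ValueError("empty gene universe")
    module_genes = set(labels.index) & universe
    if not set(labels.index) <= universe:
        raise ValueError("universe must contain all module genes")
    n_universe = len(universe)
    modules = sorted(m for m in labels.unique() if m != GREY)
    rows = []
    for mod in modules:
        members = set(labels.index[labels == mod])
        for name in sorted(lists):
            listed = lists[name] & universe
            overlap = len(members & listed)
            # P(X >= overlap), hypergeometric
            p_raw = float(
                stats.hypergeom.sf(overlap - 1, n_universe, len(listed), len(members))
            )
            rows.append(
                {
                    "module": mod,
                    "list_name": name,
                    "overlap": overlap,
                    "module_size": len(members),
                    "list_size": len(listed),
                    "universe_size": n_universe,
                    "p_raw": min(p_raw, 1.0),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
    return out


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student asymptotic p-value for a Pearson correlation."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def trait_correlation(
    mes: pd.DataFrame,
    traits: pd.DataFrame,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    Pairwise-complete samples per (module, trait); p from the Student-t
    transform with n-2 degrees of freedom; Bonferroni flag across all
    pairs.  Constant traits on the overlap are dropped with a warning.
    """
    shared = [s for s in mes.index if s in traits.index]
    rows = []
    for mod in mes.columns:
        me = mes.loc[shared, mod]
        for trait in traits.columns:
            tv = traits.loc[shared, trait]
            ok = me.notna() & tv.notna()
            n_used = int(ok.sum())
            if n_used < min_samples:
                log.warning("(%s, %s): only %d overlapping samples, skipped", mod, trait, n_used)
                continue
            x, y = me[ok].to_numpy(float), tv[ok].to_numpy(float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                log.warning("(%s, %s): constant values on overlap, dropped", mod, trait)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "module": mod,
                    "trait": trait,
                    "n_used": n_used,
                    "r": r,
                    "p": correlation_pvalue(r, n_used),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p"] * len(out) < 0.05
    return out


def crosstab_overlap(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Module-by-module overlap between two labelings of one gene universe.

    Two-sided Fisher's exact test on the 2x2 membership table per module
    pair.  Returns long-format rows (module_a, module_b, overlap, p,
    neg_log10_p).
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings cover different gene universes")
    labels_b = labels_b.reindex(labels_a.index)
    n = len(labels_a)
    rows = []
    mods_a = sorted(m for m in labels_a.unique() if m != GREY)
    mods_b = sorted(m for m in labels_b.unique() if m != GREY)
    for ma in mods_a:
        in_a = labels_a == ma
        for mb in mods_b:
            in_b = labels_b == mb
            k = int((in_a & in_b).sum())
            table = [
                [k, int(in_a.sum()) - k],
                [int(in_b.sum()) - k, n - int(in_a.sum()) - int(in_b.sum()) + k],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "overlap": k,
                    "size_a": int(in_a.sum()),
                    "size_b": int(in_b.sum()),
                    "p": p,
                    "neg_log10_p": -np.log10(max(p, 1e-300)),
                }
            )
    return pd.DataFrame(rows)


def guilt_by_association(
    membership: MembershipTable,
    annotation: pd.DataFrame,
    module_functions: dict[str, str],
    predict_cutoff: float = 0.20,
    hub_quantile: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted-function rows for genes strongly tied to labeled modules.

    A gene gets a prediction when |MM| to its assigned module exceeds
    ``predict_cutoff`` and that module has a function label.  Returns the
    per-gene table and a biotype summary (total / predicted / hubs).
    """
    assigned = membership.assigned
    rows = []
    for gene in membership.mm.index:
        mod = assigned[gene]
        if mod == GREY or mod not in module_functions:
            continue
        mm = float(membership.own_mm[gene])
        if abs(mm) <= predict_cutoff:
            continue
        q = float(membership.quantile[gene])
        rows.append(
            {
                "gene_id": gene,
                "biotype": annotation.loc[gene, "biotype"] if gene in annotation.index else "NA",
                "module": mod,
                "module_function": module_functions[mod],
                "MM": mm,
                "one_minus_quantile": 1.0 - q,
                "hub": bool((1.0 - q) < (1.0 - hub_quantile)),
            }
        )
    predicted = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "biotype", "module", "module_function", "MM",
            "one_minus_quantile", "hub",
        ],
    )
    biotypes = annotation["biotype"].reindex(membership.mm.index).fillna("NA")
    summary_rows = []
    for bt in sorted(biotypes.unique()):
        genes_bt = set(biotypes.index[biotypes == bt])
        pred_bt = predicted[predicted["biotype"] == bt]
        summary_rows.append(
            {
                "biotype": bt,
                "total": len(genes_bt),
                "predicted": len(pred_bt),
                "hubs": int(pred_bt["hub"].sum()),
            }
        )
    return predicted, pd.DataFrame(summary_rows)


def closest_partner_summary(
    adj: pd.DataFrame,
    labels: pd.Series,
    membership: MembershipTable,
    annotation: pd.DataFrame,
    adjacency_floor: float | None = None,
    important_cutoff: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Closest same-module partner per gene plus biotype contingency.

    The closest partner is the co-module gene with the highest adjacency
    (self excluded); singleton-module genes are flagged.  The filtered
    summary is restricted to genes with ``1 - q(|MM|) < important_cutoff``
    whose top adjacency exceeds ``adjacency_floor`` (default: the
    empirical 75th percentile of top adjacencies).
    """
    genes = list(adj.index)
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, -np.inf)
    label_arr = labels.reindex(adj.index).to_numpy()
    rows = []
    for i, g in enumerate(genes):
        mod = label_arr[i]
        mates = np.flatnonzero((label_arr == mod) & (np.arange(len(genes)) != i))
        if mates.size == 0:
            rows.append({"gene_id": g, "module": mod, "partner": None, "adjacency": np.nan,
                         "singleton": True})
            continue
        best = mates[int(np.argmax(a[i, mates]))]
        rows.append(
            {
                "gene_id": g,
                "module": mod,
                "partner": genes[best],
                "adjacency": float(a[i, best]),
                "singleton": False,
            }
        )
    partners = pd.DataFrame(rows).set_index("gene_id")

    if adjacency_floor is None:
        tops = partners["adjacency"].dropna()
        adjacency_floor = float(np.quantile(tops, 0.75)) if len(tops) else 0.0

    biotypes = annotation["biotype"]

    def contingency(sub: pd.DataFrame) -> pd.DataFrame:
        valid = sub.dropna(subset=["partner"])
        bt_gene = biotypes.reindex(valid.index).fillna("NA")
        bt_partner = biotypes.reindex(valid["partner"].to_numpy()).fillna("NA").to_numpy()
        return pd.crosstab(
            pd.Series(bt_partner, name="partner_biotype"),
            pd.Series(bt_gene.to_numpy(), name="gene_biotype"),
        )

    one_minus_q = 1.0 - membership.quantile.reindex(partners.index)
    important = partners[
        (one_minus_q < important_cutoff) & (partners["adjacency"] > adjacency_floor)
    ]
    return partners, contingency(partners), contingency(important)


def run_stratified(
    expr: pd.DataFrame,
    cov: pd.DataFrame,
    traits: pd.DataFrame,
    sample_filter: pd.Series,
    config,
    pooled_labels: pd.Series | None = None,
    pooled_membership: MembershipTable | None = None,
    min_stratum: int = 30,
):
    """Re-run the full pipeline on a sample stratum.

    ``sample_filter`` is a boolean Series over samples.  If pooled
    results are supplied, a crosstab against the pooled modules is
    computed on the "important" genes (1 - q(|MM|) < 0.20 in the
    stratum run).  Returns (stratum PipelineResult, crosstab or None).
    """
    from conetwork.workflow import run_pipeline

    keep = sample_filter.reindex(expr.columns).fillna(False).astype(bool)
    n_kept = int(keep.sum())
    if n_kept < min_stratum:
        raise ValueError(f"stratum has {n_kept} samples; minimum is {min_stratum}")
    result = run_pipeline(
        expr.loc[:, keep.to_numpy()],
        cov.loc[keep[keep].index] if cov is not None else None,
        traits.loc[[s for s in traits.index if keep.get(s, False)]] if traits is not None else None,
        config,
    )
    crosstab = None
    if pooled_labels is not None:
        important = result.membership.quantile.index[
            (1.0 - result.membership.quantile) < 0.20
        ]
        if len(important):
            crosstab = crosstab_overlap(
                result.labels.loc[important], pooled_labels.loc[important]
            )
    return result, crosstab
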