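"""End-to-end pipeline: residualize -> network -> modules -> membership."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from conetwork import moddetect, netbuild, preprocess
from conetwork.moddetect import MembershipTable
from conetwork.netbuild import NetworkConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: NetworkConfig
    expression: pd.DataFrame  # residualized
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    labels: pd.Series
    eigengenes: pd.DataFrame
    membership: MembershipTable
    hubs: pd.DataFrame


def run_pipeline(
    expr: pd.DataFrame,
    cov: pd.DataFrame | None,
    traits: pd.DataFrame | None,
    config: NetworkConfig,
    min_variance_quantile: float = 0.0,
) -> PipelineResult:
    """Run preprocess -> netbuild -> moddetect on one expression matrix."""
    if cov is not None:
        expr = preprocess.residualize(expr, cov)
    if min_variance_quantile > 0:
        expr = preprocess.filter_genes(expr, min_variance_quantile)
    log.info("network input: %d genes x %d samples (%s, beta=%s)",
             expr.shape[0], expr.shape[1], config.mode, config.beta)
    cor = netbuild.correlation_matrix(expr)
    adj = netbuild.adjacency(cor, config.mode, config.beta)
    tom_m = netbuild.tom(adj)
    dendro = moddetect.cluster_genes(tom_m)
    labels = moddetect.cut_tree_dynamic(
        dendro, tom_m, config.min_module_size, config.deep_split
    )
    if (labels != moddetect.GREY).any():
        labels, mes = moddetect.merge_modules(expr, labels, config.merge_cor_threshold)
    else:
        mes = pd.DataFrame(index=expr.columns)
    membership = moddetect.module_membership(expr, mes, labels)
    hubs = moddetect.call_hubs(membership, config.hub_quantile, config.assign_cutoff)
    log.info("detected %d modules (%d grey genes)",
             mes.shape[1], int((labels == moddetect.GREY).sum()))
    return PipelineResult(
        config=config,
        expression=expr,
        adjacency=adj,
        tom=tom_m,
        labels=labels,
        eigengenes=mes,
        membership=membership,
        hubs=hubs,
    )
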