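"""Query tools over a completed network run.

A :class:`NetworkBundle` persists the run as a directory of TSVs plus a
JSON manifest with sha256 digests, so results are inspectable and can be
verified on load.  The four tools are pure reads of the bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from conetwork.moddetect import GREY, MembershipTable
from conetwork.netbuild import NetworkConfig

MANIFEST_NAME = "manifest.json"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class NetworkBundle:
    adjacency: pd.DataFrame
    labels: pd.Series
    membership: MembershipTable
    eigengenes: pd.DataFrame
    annotation: pd.DataFrame
    config: NetworkConfig

    def __post_init__(self) -> None:
        universe = set(self.adjacency.index)
        for name, idx in [
            ("labels", set(self.labels.index)),
            ("membership", set(self.membership.mm.index)),
        ]:
            if idx != universe:
                raise ValueError(f"{name} gene universe differs from adjacency")

    # -- persistence ---------------------------------------------------
    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "adjacency.tsv": lambda p: self.adjacency.to_csv(p, sep="\t"),
            "labels.tsv": lambda p: self.labels.rename("module").to_csv(p, sep="\t"),
            "mm.tsv": lambda p: self.membership.mm.to_csv(p, sep="\t"),
            "membership.tsv": lambda p: self.membership.table().to_csv(p, sep="\t"),
            "eigengenes.tsv": lambda p: self.eigengenes.to_csv(p, sep="\t"),
            "annotation.tsv": lambda p: self.annotation.to_csv(p, sep="\t"),
        }
        for name, writer in files.items():
            writer(outdir / name)
        manifest = {
            "config": asdict(self.config),
            "files": {name: _digest(outdir / name) for name in files},
        }
        (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
        return outdir

    @classmethod
    def load(cls, bundledir: str | Path) -> "NetworkBundle":
        bundledir = Path(bundledir)
        manifest = json.loads((bundledir / MANIFEST_NAME).read_text())
        for name, want in manifest["files"].items():
            got = _digest(bundledir / name)
            if got != want:
                raise ValueError(f"digest mismatch for {name}: {got} != {want}")
        read = lambda name, **kw: pd.read_csv(bundledir / name, sep="\t", index_col=0, **kw)
        adjacency = read("adjacency.tsv")
        labels = read("labels.tsv")["module"]
        mm = read("mm.tsv")
        table = read("membership.tsv")
        membership = MembershipTable(
            mm=mm,
            assigned=table["module"],
            own_mm=table["MM"],
            quantile=1.0 - table["one_minus_quantile"],
        )
        return cls(
            adjacency=adjacency,
            labels=labels,
            membership=membership,
            eigengenes=read("eigengenes.tsv"),
            annotation=read("annotation.tsv"),
            config=NetworkConfig(**manifest["config"]),
        )


def tool1_closest_genes(bundle: NetworkBundle, gene_id: str) -> pd.DataFrame:
    """All co-module genes of ``gene_id`` ranked by adjacency (self excluded)."""
    if gene_id not in bundle.labels.index:
        raise KeyError(f"unknown gene: {gene_id}")
    mod = bundle.labels[gene_id]
    if mod == GREY:
        raise ValueError(f"gene {gene_id} is unassigned (grey); no module to query")
    mates = [g for g in bundle.labels.index if bundle.labels[g] == mod and g != gene_id]
    table = bundle.membership.table()
    ann = bundle.annotation
    out = pd.DataFrame(
        {
            "gene_id": mates,
            "adjacency": bundle.adjacency.loc[gene_id, mates].to_numpy(float),
            "MM": table.loc[mates, "MM"].to_numpy(float),
            "one_minus_quantile": table.loc[mates, "one_minus_quantile"].to_numpy(float),
            "chromosome": ann["chromosome"].reindex(mates).to_numpy(),
            "position": ann["start"].reindex(mates).to_numpy(),
        }
    )
    out = out.sort_values(["adjacency", "gene_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def tool2_geneset_enrichment(bundle: NetworkBundle, gene_set: set[str]) -> pd.DataFrame:
    """One-sided (enrichment) Fisher's exact test of a gene set per module."""
    from scipy import stats
    import logging

    universe = list(bundle.labels.index)
    inside = set(gene_set) & set(universe)
    dropped = set(gene_set) - inside
    if dropped:
        logging.getLogger(__name__).warning(
            "%d query genes outside the network universe dropped", len(dropped)
        )
    if not inside:
        raise ValueError("gene set does not intersect the network universe")
    n = len(universe)
    n_set = len(inside)
    rows = []
    for mod in sorted(m for m in bundle.labels.unique() if m != GREY):
        members = set(bundle.labels.index[bundle.labels == mod])
        k = len(members & inside)
        table = [
            [k, len(members) - k],
            [n_set - k, n - len(members) - n_set + k],
        ]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append(
            {"module": mod, "overlap": k, "module_size": len(members),
             "set_size": n_set, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out


def tool3_region(bundle: NetworkBundle, chromosome: str, start: int, end: int) -> pd.DataFrame:
    """Network genes overlapping a 1-based inclusive genomic interval.

    Grey genes are included (labeled grey).  Overlap of >= 1 bp counts;
    unknown chromosomes yield an empty table with a warning.
    """
    import logging

    if start > end:
        raise ValueError(f"start {start} > end {end}")
    ann = bundle.annotation
    if chromosome not in set(ann["chromosome"]):
        logging.getLogger(__name__).warning("chromosome %s not in annotation", chromosome)
        return pd.DataFrame(columns=["gene_id", "module", "MM", "chromosome", "start", "end"])
    hits = ann[
        (ann["chromosome"] == chromosome) & (ann["start"] <= end) & (ann["end"] >= start)
    ]
    hits = hits.loc[[g for g in hits.index if g in bundle.labels.index]]
    table = bundle.membership.table()
    out = pd.DataFrame(
        {
            "gene_id": hits.index,
            "module": bundle.labels.reindex(hits.index).to_numpy(),
            "MM": table["MM"].reindex(hits.index).to_numpy(float),
            "chromosome": hits["chromosome"].to_numpy(),
            "start": hits["start"].to_numpy(),
            "end": hits["end"].to_numpy(),
        }
    )
    return out.sort_values("start", kind="mergesort").reset_index(drop=True)


def tool4_gene_profile(
    bundle: NetworkBundle, gene_id: str, mm_floor: float = 0.10, max_rows: int = 10
) -> pd.DataFrame:
    """Modules where |MM| of ``gene_id`` exceeds ``mm_floor``, top 10 by |MM|."""
    if gene_id not in bundle.membership.mm.index:
        raise KeyError(f"unknown gene: {gene_id}")
    mm = bundle.membership.mm.loc[gene_id]
    passing = mm[mm.abs() > mm_floor]
    passing = passing.reindex(passing.abs().sort_values(ascending=False, kind="mergesort").index)
    passing = passing.iloc[:max_rows]
    own = bundle.labels[gene_id]
    return pd.DataFrame(
        {
            "module": passing.index,
            "MM": passing.to_numpy(float),
            "is_assigned_module": [m == own for m in passing.index],
        }
    ).reset_index(drop=True)
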