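"""Seeded synthetic data with planted co-expression module structure.

The generator plants latent per-module factors, assigns each module gene a
loading and a sign, and emits expression, traits, covariates, gene
annotation and marker lists together with the full ground truth, so that
every downstream stage can be tested against known structure.

Gene model (module gene i, sample j)::

    x_ij = s_i * w_i * f_{m(i),j} + sqrt(1 - w_i^2) * eps_ij
           + age_effect * age_j + sex_effect * sex_j

with factors f and noise eps standard normal; background genes are pure
noise plus covariate effects.  Trait k driven by module m::

    t_kj = trait_loading * f_{m,j} + sqrt(1 - trait_loading^2) * eta_kj
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other_ncRNA")
_N_CHROMS = 22
_GENE_SPACING = 10_000
_GENE_LENGTH = 1_000


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    ``factor_correlation`` (if given) is the module-pair correlation
    matrix of the latent factors; identity by default.  ``trait_modules``
    maps each trait to the planted module driving it (``None`` entries
    give pure-noise traits); by default traits cycle through modules.
    """

    n_samples: int = 200
    n_modules: int = 4
    genes_per_module: int = 40
    n_background_genes: int = 100
    weight_range: tuple[float, float] = (0.6, 0.9)
    neg_fraction: float = 0.0
    lncrna_fraction: float = 0.11
    n_traits: int = 4
    trait_loading: float = 0.6
    trait_modules: Sequence[int | None] | None = None
    factor_correlation: np.ndarray | None = None
    age_effect: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_modules", "genes_per_module"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.n_traits < 0:
            raise ValueError("n_traits must be >= 0")
        lo, hi = self.weight_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"weight_range must lie within (0, 1], got {self.weight_range}")
        for name in ("neg_fraction", "lncrna_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.trait_loading <= 1:
            raise ValueError(f"trait_loading must be in [0, 1], got {self.trait_loading}")
        if self.factor_correlation is not None:
            fc = np.asarray(self.factor_correlation, dtype=float)
            if fc.shape != (self.n_modules, self.n_modules):
                raise ValueError(
                    f"factor_correlation must be {self.n_modules}x{self.n_modules}, got {fc.shape}"
                )
            if not np.allclose(fc, fc.T, atol=1e-10):
                raise ValueError("factor_correlation must be symmetric")
            if not np.allclose(np.diag(fc), 1.0, atol=1e-10):
                raise ValueError("factor_correlation must have unit diagonal")
            if np.linalg.eigvalsh(fc).min() < -1e-10:
                raise ValueError("factor_correlation must be positive semi-definite")
        if self.trait_modules is not None:
            if len(self.trait_modules) != self.n_traits:
                raise ValueError("trait_modules length must equal n_traits")
            for m in self.trait_modules:
                if m is not None and not 1 <= m <= self.n_modules:
                    raise ValueError(f"trait module id {m} out of range 1..{self.n_modules}")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    factor_matrix: pd.DataFrame  # sample x module latent values
    gene_module: pd.Series  # gene -> module id, 0 = background
    gene_weight: pd.Series
    gene_sign: pd.Series
    trait_module: dict[str, int | None]
    covariates: pd.DataFrame  # sample x (age, sex)


@dataclass
class SimDataset:
    expression: pd.DataFrame  # genes x samples
    traits: pd.DataFrame  # samples x traits
    covariates: pd.DataFrame  # samples x (age, sex)
    annotation: pd.DataFrame  # gene_id-indexed: symbol, biotype, chromosome, start, end
    marker_lists: dict[str, set[str]]
    truth: SimTruth


def _correlated_factors(rng: np.random.Generator, n: int, cor: np.ndarray) -> np.ndarray:
    """Sample n rows from N(0, cor) via eigendecomposition (PSD-safe)."""
    vals, vecs = np.linalg.eigh(cor)
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    z = rng.standard_normal((n, cor.shape[0]))
    return z @ root.T


def _biotypes(n_genes: int, lncrna_fraction: float) -> list[str]:
    """Deterministic biotype labels with an exact lncRNA count."""
    n_lnc = int(round(lncrna_fraction * n_genes))
    labels = ["protein_coding"] * n_genes
    if n_lnc > 0:
        # spread lncRNAs evenly over the gene list
        for i in np.linspace(0, n_genes - 1, n_lnc).round().astype(int):
            labels[i] = "lncRNA"
    # sprinkle a few other non-coding biotypes over remaining slots
    free = [i for i, b in enumerate(labels) if b == "protein_coding"]
    for j, i in enumerate(free):
        if j % 29 == 13:
            labels[i] = "pseudogene"
        elif j % 37 == 17:
            labels[i] = "other_ncRNA"
    return labels


def _coordinates(n_genes: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tile genes along chr1..chr22 in order, 10 kb apart, 1 kb long."""
    per_chrom = math.ceil(n_genes / _N_CHROMS)
    chroms, starts = [], np.empty(n_genes, dtype=int)
    for i in range(n_genes):
        chroms.append(f"chr{i // per_chrom + 1}")
        pos = i % per_chrom
        starts[i] = 1 + pos * _GENE_SPACING
    ends = starts + _GENE_LENGTH - 1
    return chroms, starts, ends


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full synthetic dataset, reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_mod = config.n_modules
    gpm = config.genes_per_module
    n_genes = n_mod * gpm + config.n_background_genes
    n = config.n_samples

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    module_names = [f"M{m}" for m in range(1, n_mod + 1)]

    fc = (
        np.asarray(config.factor_correlation, dtype=float)
        if config.factor_correlation is not None
        else np.eye(n_mod)
    )
    factors = _correlated_factors(rng, n, fc)  # n x n_mod

    age = rng.uniform(18.0, 102.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cov_shift = config.age_effect * age + config.sex_effect * sex

    gene_module = np.zeros(n_genes, dtype=int)
    gene_weight = np.zeros(n_genes)
    gene_sign = np.ones(n_genes, dtype=int)
    lo, hi = config.weight_range
    expr = np.empty((n_genes, n))

    for m in range(n_mod):
        rows = slice(m * gpm, (m + 1) * gpm)
        w = rng.uniform(lo, hi, size=gpm)
        s = np.ones(gpm, dtype=int)
        n_neg = int(round(config.neg_fraction * gpm))
        if n_neg:
            s[gpm - n_neg :] = -1  # deterministic: last genes of the module flip
        gene_module[rows] = m + 1
        gene_weight[rows] = w
        gene_sign[rows] = s
        noise = rng.standard_normal((gpm, n))
        expr[rows] = (s * w)[:, None] * factors[:, m][None, :] + np.sqrt(1 - w**2)[
            :, None
        ] * noise

    n_bg = config.n_background_genes
    if n_bg:
        expr[n_mod * gpm :] = rng.standard_normal((n_bg, n))
    expr += cov_shift[None, :]

    traits = np.empty((n, config.n_traits))
    if config.trait_modules is not None:
        trait_mods: list[int | None] = list(config.trait_modules)
    else:
        trait_mods = [(k % n_mod) + 1 for k in range(config.n_traits)]
    trait_names = [f"trait{k + 1}" for k in range(config.n_traits)]
    tl = config.trait_loading
    for k, m in enumerate(trait_mods):
        eta = rng.standard_normal(n)
        if m is None:
            traits[:, k] = eta
        else:
            traits[:, k] = tl * factors[:, m - 1] + math.sqrt(1 - tl**2) * eta

    chroms, starts, ends = _coordinates(n_genes)
    annotation = pd.DataFrame(
        {
            "symbol": [f"SYM{i:05d}" for i in range(n_genes)],
            "biotype": _biotypes(n_genes, config.lncrna_fraction),
            "chromosome": chroms,
            "start": starts,
            "end": ends,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # one marker list per planted module: the first half of its genes
    marker_lists = {
        f"markers_M{m + 1}": set(gene_ids[m * gpm : m * gpm + max(1, gpm // 2)])
        for m in range(n_mod)
    }

    truth = SimTruth(
        factor_matrix=pd.DataFrame(factors, index=sample_ids, columns=module_names),
        gene_module=pd.Series(gene_module, index=gene_ids, name="module"),
        gene_weight=pd.Series(gene_weight, index=gene_ids, name="weight"),
        gene_sign=pd.Series(gene_sign, index=gene_ids, name="sign"),
        trait_module=dict(zip(trait_names, trait_mods)),
        covariates=pd.DataFrame({"age": age, "sex": sex}, index=sample_ids),
    )
    return SimDataset(
        expression=pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        traits=pd.DataFrame(traits, index=pd.Index(sample_ids, name="sample_id"), columns=trait_names),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex}, index=pd.Index(sample_ids, name="sample_id")
        ),
        annotation=annotation,
        marker_lists=marker_lists,
        truth=truth,
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all dataset components as TSVs (+ truth JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "traits": outdir / "traits.tsv",
        "covariates": outdir / "covariates.tsv",
        "annotation": outdir / "annotation.tsv",
        "marker_lists": outdir / "marker_lists.tsv",
        "truth": outdir / "truth.json",
    }
    ds.expression.to_csv(paths["expression"], sep="\t")
    ds.traits.to_csv(paths["traits"], sep="\t")
    ds.covariates.to_csv(paths["covariates"], sep="\t")
    ds.annotation.to_csv(paths["annotation"], sep="\t")
    rows = [
        {"list_name": name, "gene_id": g}
        for name in sorted(ds.marker_lists)
        for g in sorted(ds.marker_lists[name])
    ]
    pd.DataFrame(rows).to_csv(paths["marker_lists"], sep="\t", index=False)
    truth_obj = {
        "gene_module": ds.truth.gene_module.to_dict(),
        "gene_weight": ds.truth.gene_weight.to_dict(),
        "gene_sign": {k: int(v) for k, v in ds.truth.gene_sign.items()},
        "trait_module": ds.truth.trait_module,
        "factor_matrix": {
            "index": list(ds.truth.factor_matrix.index),
            "columns": list(ds.truth.factor_matrix.columns),
            "values": ds.truth.factor_matrix.to_numpy().tolist(),
        },
    }
    paths["truth"].write_text(json.dumps(truth_obj))
    return paths


def read_marker_lists(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for name, grp in df.groupby("list_name"):
        out[str(name)] = set(grp["gene_id"].astype(str))
    return out
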