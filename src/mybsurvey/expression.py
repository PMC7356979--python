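"""Hormone-response expression profiling of MYB genes from FPKM matrices.

Genes with FPKM < 1 in every sample are removed as unexpressed.  Retained
values are log2(FPKM + 1)-transformed and median-centered per gene, then
hierarchically clustered (average linkage on 1 − Pearson correlation, the
convention of classic gene-expression clustering tools).  Regulation is
called per hormone from condition means against the time-0 control: a
gene is up (down) under a hormone when its fold change reaches the
threshold (default 1.5) at one or more post-treatment time points.  Genes
are grouped as up-all / down-all / mixed across the five hormones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import HORMONES, ExpressionMatrix

GROUPS = ("up-all", "down-all", "mixed", "not-expressed")


@dataclass
class ExpressionCall:
    gene_id: str
    expressed: bool
    directions: dict[str, str]               # hormone -> up/down/both/none
    group: str
    # per-(hormone, time) direction grid for stricter downstream summaries
    per_time: dict[tuple[str, int], str] = field(default_factory=dict)


@dataclass
class ClusteredMatrix:
    values: pd.DataFrame                      # transformed, leaf order
    linkage: np.ndarray
    gene_order: list[str]


def filter_expressed(matrix: ExpressionMatrix
                     ) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes with FPKM >= 1 in at least one sample (inclusive bound)."""
    mask = (matrix.values >= 1.0).any(axis=1)
    dropped = list(matrix.values.index[~mask])
    return matrix.subset(list(matrix.values.index[mask])), dropped


def transform(values: pd.DataFrame, zero_handling: str = "plus-one",
              epsilon: float = 0.01) -> pd.DataFrame:
    """log2 transform then per-gene median centering.

    ``plus-one`` uses log2(FPKM + 1), keeping zeros at zero;
    ``epsilon`` uses log2(max(FPKM, epsilon)).
    """
    if zero_handling == "plus-one":
        x = np.log2(values + 1.0)
    elif zero_handling == "epsilon":
        x = np.log2(values.clip(lower=epsilon))
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    return x.sub(x.median(axis=1), axis=0)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 − Pearson across samples; zero-variance rows at distance 1 to all."""
    sd = x.std(axis=1)
    corr = np.corrcoef(x)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    d = 1.0 - corr
    zero_var = sd == 0
    d[zero_var, :] = 1.0
    d[:, zero_var] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def _deterministic_order(linkage: np.ndarray, ids: list[str]) -> list[str]:
    """Leaf order with, at each merge, the subtree holding the smallest
    gene id (lexicographically) on the left."""
    n = len(ids)

    def leaves(node: int) -> list[str]:
        if node < n:
            return [ids[node]]
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        a, b = leaves(left), leaves(right)
        return a + b if min(a) <= min(b) else b + a

    return leaves(2 * n - 2) if n > 1 else list(ids)


def cluster_genes(transformed: pd.DataFrame) -> ClusteredMatrix:
    """Average-linkage hierarchical clustering on correlation distance with
    a deterministic (input-order invariant) leaf ordering."""
    ids = list(transformed.index)
    if len(ids) < 2:
        return ClusteredMatrix(transformed.copy(), np.empty((0, 4)), ids)
    # canonical input order for reproducible linkage regardless of row order
    canon = sorted(ids)
    x = transformed.loc[canon].to_numpy(dtype=float)
    d = _correlation_distance(x)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = _deterministic_order(z, canon)
    return ClusteredMatrix(transformed.loc[order], z, order)


def call_regulation(matrix: ExpressionMatrix, fold: float = 1.5,
                    pseudocount: float = 0.1) -> list[ExpressionCall]:
    """Direction calls per hormone and overall response group per gene.

    Replicates are averaged per (hormone, time) condition.  With control
    mean m0 (time 0) and treatment mean m, the ratio (m + c)/(m0 + c) with
    pseudocount c is compared to the fold threshold at every post-treatment
    time point; up/down need one qualifying time point each, both when
    both occur.  Missing controls raise.
    """
    means = matrix.condition_means()
    calls = []
    shared_ck = None
    if matrix.shared_control:
        if ("CK", 0) not in means.columns:
            raise ValueError("shared control requires a CK time-0 condition")
        shared_ck = means[("CK", 0)]
    for gene in matrix.gene_ids:
        expressed = bool((matrix.values.loc[gene] >= 1.0).any())
        directions: dict[str, str] = {}
        per_time: dict[tuple[str, int], str] = {}
        for h in HORMONES:
            if shared_ck is not None:
                m0 = shared_ck.loc[gene]
            else:
                if (h, 0) not in means.columns:
                    raise ValueError(f"missing time-0 control for {h}")
                m0 = means[(h, 0)].loc[gene]
            up = down = False
            for (hh, t) in means.columns:
                if hh != h or t == 0:
                    continue
                r = (means[(hh, t)].loc[gene] + pseudocount) / (m0 + pseudocount)
                if r >= fold:
                    up = True
                    per_time[(h, t)] = "up"
                elif r <= 1.0 / fold:
                    down = True
                    per_time[(h, t)] = "down"
                else:
                    per_time[(h, t)] = "none"
            directions[h] = ("both" if up and down else
                             "up" if up else "down" if down else "none")
        if not expressed:
            group = "not-expressed"
        elif all(directions[h] in ("up", "both") for h in HORMONES):
            group = "up-all"
        elif all(directions[h] in ("down", "both") for h in HORMONES):
            group = "down-all"
        else:
            group = "mixed"
        calls.append(ExpressionCall(gene, expressed, directions, group,
                                    per_time))
    return calls


def _pct(num: int, den: int) -> int:
    if den == 0:
        return 0
    return int(100.0 * num / den + 0.5)


def group_summary(calls: list[ExpressionCall],
                  families: dict[str, str] | None = None) -> dict:
    """Group sizes plus expressed-gene counts and integer shares per family."""
    group_counts = {g: sum(1 for c in calls if c.group == g) for g in GROUPS}
    out = {
        "n_genes": len(calls),
        "n_expressed": sum(1 for c in calls if c.expressed),
        "group_counts": group_counts,
        "empty": len(calls) == 0,
    }
    out["expressed_pct"] = _pct(out["n_expressed"], out["n_genes"])
    if families:
        per_family: dict[str, dict] = {}
        for fam in sorted(set(families.values())):
            members = [c for c in calls if families.get(c.gene_id) == fam]
            n_exp = sum(1 for c in members if c.expressed)
            per_family[fam] = {
                "n": len(members),
                "n_expressed": n_exp,
                "expressed_pct": _pct(n_exp, len(members)),
            }
        out["per_family"] = per_family
    return out
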