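"""Stage 1 of the enrichment pipeline: the per-identity upregulation screen.

For every gene and every cell-identity group the screen asks whether
expression inside the group is stochastically *greater* than in all other
cells, via a one-sided Wilcoxon rank-sum test on normalized expression.
The resulting p-value matrix (genes x identities) is corrected with a
"horizontal" Benjamini-Hochberg step-up — by default the correction family
is the row, i.e. each gene's p-values across identity groups — giving
q-values.  A gene is called upregulated in a group when q <= 0.05 and
log2 fold change > 1 (both thresholds configurable).

Fold changes are ratios of group means of normalized expression with a
small epsilon guard; percent-expressed columns count cells with any
detected signal inside and outside the group.

The rank-sum test uses midranks for ties.  With combined sample size at
most ``exact_limit`` (default 12) the p-value is computed by exhaustive
enumeration of group-label assignments (a permutation p-value, so all-tied
data gives p = 1); above that, a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm, rankdata

from .io import CountMatrix

__all__ = [
    "NormalizedExpression",
    "normalize",
    "filter_genes",
    "rank_sum_upregulation",
    "horizontal_bh",
    "compute_fc",
    "call_upregulated",
    "de_table",
]

BH_FAMILIES = ("per_gene", "per_group", "global")


@dataclass
class NormalizedExpression:
    """Genes x cells matrix of normalized expression (non-negative reals)."""

    values: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize(
    counts: CountMatrix,
    scale_target: float | None = None,
    log_base: str | float = "e",
) -> NormalizedExpression:
    """Per-cell library-size scaling followed by log(1 + x).

    Each cell's counts are rescaled so its total equals ``scale_target``
    (default: the median cell total), then log1p-transformed in the
    requested base (natural log or 2).  A cell with zero total count has
    no defined scaling and is rejected by name.
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count: {names}")
    if scale_target is None:
        scale_target = float(np.median(totals))
    if scale_target <= 0:
        raise ValueError("scale_target must be positive")
    scaled = counts.values.astype(float) @ sparse.diags(scale_target / totals)
    scaled = sparse.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    if log_base in (2, "2"):
        scaled.data /= np.log(2.0)
        base = "2"
    elif log_base in ("e", np.e):
        base = "e"
    else:
        raise ValueError(f"unsupported log base: {log_base!r}")
    return NormalizedExpression(
        values=scaled,
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        normalization={"scale_target": scale_target, "log_base": base},
    )


def filter_genes(
    expr: NormalizedExpression, min_cells: int = 20
) -> NormalizedExpression:
    """Keep genes detected (value > 0) in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    detected = expr.values.getnnz(axis=1)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError(
            f"the {min_cells}-cell filter removed every gene"
        )
    return NormalizedExpression(
        values=expr.values[keep],
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        cell_ids=list(expr.cell_ids),
        normalization=dict(expr.normalization),
    )


def _group_mask(
    expr: NormalizedExpression, ann: pd.DataFrame, identity: str
) -> np.ndarray:
    ident = ann.set_index("cell_id")["identity"]
    missing = [c for c in expr.cell_ids if c not in ident.index]
    if missing:
        raise KeyError(f"cells without identity annotation: {missing[:5]}")
    labels = ident.reindex(expr.cell_ids).to_numpy()
    if identity not in labels:
        raise KeyError(f"unknown identity group: {identity!r}")
    return labels == identity


def _exact_greater_p(values: np.ndarray, in_mask: np.ndarray) -> float:
    """Permutation p-value for elevated in-group midrank sum.

    Enumerates every assignment of the in-group labels over the pooled
    observations; p is the fraction of assignments whose midrank sum is at
    least the observed one (the observed assignment counts itself, so the
    p-value is never 0 and all-tied data gives exactly 1).
    """
    ranks = rankdata(values, method="average")
    n_in = int(in_mask.sum())
    observed = ranks[in_mask].sum()
    hits = 0
    total = 0
    for combo in combinations(range(values.size), n_in):
        total += 1
        if ranks[list(combo)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


def _normal_greater_p(
    rank_sum_in: np.ndarray,
    tie_term: np.ndarray,
    n_in: int,
    n_total: int,
) -> np.ndarray:
    """Vectorized one-sided (greater) normal-approximation p-values.

    ``rank_sum_in`` and ``tie_term`` (sum of t^3 - t over tie groups) are
    per-gene arrays computed from midranks over all cells.
    """
    n_out = n_total - n_in
    u = rank_sum_in - n_in * (n_in + 1) / 2.0
    mu = n_in * n_out / 2.0
    var = (
        n_in
        * n_out
        / 12.0
        * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    )
    p = np.ones_like(u, dtype=float)
    ok = var > 0
    z = (u[ok] - mu - 0.5) / np.sqrt(var[ok])
    p[ok] = norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _ranks_and_ties(
    values: sparse.csr_matrix, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Midranks per gene row plus the tie term sum(t^3 - t) per gene."""
    n_genes, n_cells = values.shape
    ranks = np.empty((n_genes, n_cells))
    tie_term = np.empty(n_genes)
    for start in range(0, n_genes, chunk):
        block = values[start : start + chunk].toarray()
        ranks[start : start + block.shape[0]] = rankdata(
            block, axis=1, method="average"
        )
        for i, row in enumerate(block):
            _, counts = np.unique(row, return_counts=True)
            tie_term[start + i] = float(np.sum(counts**3 - counts))
    return ranks, tie_term


def rank_sum_upregulation(
    expr: NormalizedExpression,
    ann: pd.DataFrame,
    identity: str,
    exact_limit: int = 12,
) -> np.ndarray:
    """One-sided (greater) rank-sum p per gene: identity group vs the rest."""
    in_mask = _group_mask(expr, ann, identity)
    n_in, n_total = int(in_mask.sum()), in_mask.size
    if n_in == n_total:
        raise ValueError(f"no cells outside identity group {identity!r}")
    if n_total <= exact_limit:
        dense = expr.values.toarray()
        return np.array(
            [_exact_greater_p(row, in_mask) for row in dense]
        )
    ranks, tie_term = _ranks_and_ties(expr.values)
    rank_sum_in = ranks[:, in_mask].sum(axis=1)
    return _normal_greater_p(rank_sum_in, tie_term, n_in, n_total)


def _bh_1d(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up along a 1-D family."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def horizontal_bh(p: np.ndarray, family: str = "per_gene") -> np.ndarray:
    """BH step-up over a genes x identities p-value matrix.

    ``family`` selects the correction family: ``per_gene`` (horizontal —
    each gene's row across identity groups, the default), ``per_group``
    (each column) or ``global`` (one family over the whole matrix).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if family not in BH_FAMILIES:
        raise ValueError(f"bh_family must be one of {BH_FAMILIES}")
    if p.ndim == 1:
        return _bh_1d(p)
    if family == "global":
        return _bh_1d(p.ravel()).reshape(p.shape)
    axis = 1 if family == "per_gene" else 0
    return np.apply_along_axis(_bh_1d, axis, p)


def compute_fc(
    expr: NormalizedExpression,
    ann: pd.DataFrame,
    identity: str,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Linear/log2 fold change and percent-expressed, group vs rest.

    fc = (mean_in + eps) / (mean_out + eps) on normalized values;
    pct_in / pct_out are the percentages of cells with detected signal
    (value > 0) inside and outside the group.
    """
    in_mask = _group_mask(expr, ann, identity)
    n_in = int(in_mask.sum())
    n_out = in_mask.size - n_in
    if n_out == 0:
        raise ValueError(f"no cells outside identity group {identity!r}")
    vin = expr.values[:, in_mask]
    vout = expr.values[:, ~in_mask]
    mean_in = np.asarray(vin.sum(axis=1)).ravel() / n_in
    mean_out = np.asarray(vout.sum(axis=1)).ravel() / n_out
    fc = (mean_in + epsilon) / (mean_out + epsilon)
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "fc": fc,
            "log2fc": np.log2(fc),
            "pct_in": 100.0 * vin.getnnz(axis=1) / n_in,
            "pct_out": 100.0 * vout.getnnz(axis=1) / n_out,
        }
    )


def call_upregulated(q, log2fc, q_max: float = 0.05, lfc_min: float = 1.0):
    """Upregulation call: q <= q_max (inclusive) AND log2fc > lfc_min (strict)."""
    return np.logical_and(np.asarray(q) <= q_max, np.asarray(log2fc) > lfc_min)


def de_table(
    expr: NormalizedExpression,
    ann: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
    epsilon: float = 1e-9,
    bh_family: str = "per_gene",
    exact_limit: int = 12,
) -> pd.DataFrame:
    """Run the full upregulation screen over every identity group.

    Returns the long-form DE table: one row per (gene, identity) with
    p_raw, q, fc, log2fc, pct_in, pct_out and the boolean upregulation
    call.  Identity groups are screened in first-appearance order.
    """
    identities = list(dict.fromkeys(ann["identity"]))
    if len(identities) < 2:
        raise ValueError("need at least 2 identity groups to screen")
    ident = ann.set_index("cell_id")["identity"]
    missing = [c for c in expr.cell_ids if c not in ident.index]
    if missing:
        raise KeyError(f"cells without identity annotation: {missing[:5]}")
    labels = ident.reindex(expr.cell_ids).to_numpy()
    n_genes, n_total = expr.shape

    if n_total <= exact_limit:
        p_mat = np.column_stack(
            [
                rank_sum_upregulation(expr, ann, ident_, exact_limit)
                for ident_ in identities
            ]
        )
    else:
        # Midranks are over all cells, so rank once and reuse per group.
        ranks, tie_term = _ranks_and_ties(expr.values)
        p_cols = []
        for ident_ in identities:
            in_mask = labels == ident_
            rank_sum_in = ranks[:, in_mask].sum(axis=1)
            p_cols.append(
                _normal_greater_p(
                    rank_sum_in, tie_term, int(in_mask.sum()), n_total
                )
            )
        p_mat = np.column_stack(p_cols)

    q_mat = horizontal_bh(p_mat, family=bh_family)
    frames = []
    for j, ident_ in enumerate(identities):
        fctab = compute_fc(expr, ann, ident_, epsilon=epsilon)
        fctab.insert(1, "identity", ident_)
        fctab["p_raw"] = p_mat[:, j]
        fctab["q"] = q_mat[:, j]
        fctab["upregulated"] = call_upregulated(
            q_mat[:, j], fctab["log2fc"], q_max=q_max, lfc_min=lfc_min
        )
        frames.append(fctab)
    out = pd.concat(frames, ignore_index=True)
    return out[
        [
            "gene",
            "identity",
            "p_raw",
            "q",
            "fc",
            "log2fc",
            "pct_in",
            "pct_out",
            "upregulated",
        ]
    ]
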