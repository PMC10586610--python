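"""Stage 2: eligibility-gated over-representation of a gene set.

For each identity group a 2x2 table is formed from the upregulation calls:

                      upregulated   not upregulated
    set genes              a               b
    non-set genes          c               d

with the gene universe being the genes that passed the detection filter in
the dataset (not the genome), and the gene set intersected with that
universe first.  Enrichment is a one-sided Fisher exact test, i.e. the
hypergeometric upper tail P[X >= a].  To avoid chasing groups where only
one or two set genes pass, a group enters the test only when at least a
configurable fraction (default 5%) of the dataset-intersected set is
upregulated in it; Bonferroni correction then runs over the eligible
groups only.  The mean linear fold change of set genes versus the rest is
reported per group as a descriptive contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSet, match_genes

logger = logging.getLogger(__name__)

__all__ = [
    "contingency",
    "fisher_one_sided",
    "eligibility",
    "bonferroni",
    "mean_fc_contrast",
    "overrepresentation",
    "rank_hits",
]


def contingency(
    upregulated_genes: set[str],
    dataset_genes: set[str],
    gene_set: GeneSet,
) -> tuple[int, int, int, int]:
    """Build the 2x2 table (a, b, c, d) for one identity group.

    Matching of set genes against the dataset universe is case-insensitive;
    set genes absent from the universe are dropped before counting, so
    a + b is the size of the set's intersection with the dataset.
    """
    extra = {g.casefold() for g in upregulated_genes} - {
        g.casefold() for g in dataset_genes
    }
    if extra:
        raise ValueError(
            f"upregulated genes absent from the dataset universe: "
            f"{sorted(extra)[:5]}"
        )
    matched, _ = match_genes(gene_set.genes, sorted(dataset_genes))
    set_in_dataset = {g.casefold() for g in matched}
    if not set_in_dataset:
        logger.warning("gene set is disjoint from the dataset universe")
    up = {g.casefold() for g in upregulated_genes}
    a = len(set_in_dataset & up)
    b = len(set_in_dataset) - a
    c = len(up) - a
    d = len(dataset_genes) - len(set_in_dataset) - c
    return a, b, c, d


def fisher_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p) where p is the hypergeometric upper tail
    P[X >= a] with X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c) and the odds
    ratio is ad/bc (+inf when bc = 0 and ad > 0, NaN when both products
    vanish).  p is clamped into (0, 1].
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative contingency cell in {cells}")
    n_total = a + b + c + d
    p = float(hypergeom.sf(a - 1, n_total, a + b, a + c))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def eligibility(
    a: int, set_size_in_dataset: int, min_fraction: float = 0.05
) -> bool:
    """A group is eligible when a >= min_fraction * |set in dataset|.

    The comparison is on the exact real product — no rounding of the
    floor — so with a 74-gene set and the 5% default, 4 upregulated set
    genes qualify (4 >= 3.7) but 3 do not.
    """
    if set_size_in_dataset < 1:
        raise ValueError("set_size_in_dataset must be >= 1")
    return a >= min_fraction * set_size_in_dataset


def bonferroni(p: float, m_eligible: int) -> float:
    """Bonferroni correction over the eligible-group family."""
    if m_eligible < 1:
        raise ValueError("m_eligible must be >= 1")
    return min(1.0, p * m_eligible)


def mean_fc_contrast(
    de: pd.DataFrame,
    identity: str,
    gene_set: GeneSet,
    upregulated_only: bool = False,
) -> tuple[float, float]:
    """Mean linear fold change of set genes vs the rest within a group.

    By default every filter-passing gene contributes; with
    ``upregulated_only`` the averages run over the group's upregulated
    genes only.
    """
    sub = de[de["identity"] == identity]
    if sub.empty:
        raise ValueError(f"identity {identity!r} absent from DE table")
    if upregulated_only:
        sub = sub[sub["upregulated"]]
    set_names = {g.casefold() for g in gene_set.genes}
    in_set = sub["gene"].str.casefold().isin(set_names)
    if not in_set.any():
        raise ValueError("gene set has no genes in the DE table")
    return float(sub.loc[in_set, "fc"].mean()), float(
        sub.loc[~in_set, "fc"].mean()
    )


def overrepresentation(
    de: pd.DataFrame,
    gene_set: GeneSet,
    eligibility_fraction: float = 0.05,
    upregulated_only_fc: bool = False,
) -> pd.DataFrame:
    """Run the gated ORA over every identity group in a DE table.

    Returns one row per identity: the 2x2 table, odds ratio, Fisher p,
    eligibility flag, Bonferroni-corrected p (NaN for ineligible groups,
    which never join the correction family) and the set/rest mean-FC
    contrast.
    """
    dataset_genes = set(de["gene"].unique())
    identities = list(dict.fromkeys(de["identity"]))
    rows = []
    for ident in identities:
        sub = de[de["identity"] == ident]
        up = set(sub.loc[sub["upregulated"], "gene"])
        a, b, c, d = contingency(up, dataset_genes, gene_set)
        odds, p = fisher_one_sided(a, b, c, d)
        set_size = a + b
        eligible = set_size >= 1 and eligibility(
            a, set_size, eligibility_fraction
        )
        mean_set, mean_rest = mean_fc_contrast(
            de, ident, gene_set, upregulated_only=upregulated_only_fc
        )
        rows.append(
            {
                "identity": ident,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p_fisher": p,
                "eligible": eligible,
                "p_bonferroni": np.nan,
                "mean_fc_set": mean_set,
                "mean_fc_rest": mean_rest,
            }
        )
    result = pd.DataFrame(rows)
    m_eligible = int(result["eligible"].sum())
    if m_eligible:
        mask = result["eligible"]
        result.loc[mask, "p_bonferroni"] = [
            bonferroni(p, m_eligible) for p in result.loc[mask, "p_fisher"]
        ]
    return result


def rank_hits(result: pd.DataFrame) -> pd.DataFrame:
    """Order eligible groups by Fisher p, breaking ties by larger a then name."""
    hits = result[result["eligible"]].copy()
    hits["_neg_a"] = -hits["a"]
    hits = hits.sort_values(
        ["p_fisher", "_neg_a", "identity"], kind="mergesort"
    ).drop(columns="_neg_a")
    return hits.reset_index(drop=True)
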