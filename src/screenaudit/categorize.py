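"""Replicate-based hit calling, gene categories, expression filtering, and screen rates.

A reagent is a *hit* when |Z| >= threshold (default 2) in every replicate,
with a consistent sign across replicates — a reagent scoring +2.5 in one
replicate and -2.5 in the other has not reproduced an effect.

Genes are then binned by how their reagents behaved:

* category 1 — every reagent against the gene was a hit;
* category 2 — at least two hit, at least one did not;
* category 3 — exactly one reagent hit (the classic single-reagent
  ambiguity: an off-target false positive, or the gene's only effective
  reagent);
* none (0)  — no reagent hit.

Category-3 calls can be triaged with the cell line's transcriptome: a scoring
reagent against a gene the cell line does not express (FPKM below threshold)
is almost certainly a false positive.  Treating all category-3 genes as false
positives bounds the screen's reagent-level FP rate; the non-scoring reagents
of category-1/2 genes bound the FN rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateEstimates",
    "call_reagent_hits",
    "category_from_counts",
    "assign_gene_categories",
    "apply_expression_filter",
    "count_expressed_intersection",
    "estimate_screen_rates",
]

#: Category code for genes with no scoring reagent.
CATEGORY_NONE = 0


def call_reagent_hits(
    replicate_z: pd.DataFrame,
    threshold: float = 2.0,
    require_sign_consistency: bool = True,
) -> pd.DataFrame:
    """Call per-reagent hits from a reagent x replicate Z matrix.

    A reagent is a hit iff |Z| >= threshold in every replicate and (when
    ``require_sign_consistency``) all replicate Z share one sign.  Reagents
    with any missing replicate are non-evaluable: ``evaluable`` is False and
    they must be excluded from rate denominators.

    Returns a DataFrame indexed by reagent with columns ``hit`` (bool) and
    ``evaluable`` (bool).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if replicate_z.shape[1] < 1:
        raise ValueError("need at least one replicate column")
    Z = replicate_z.to_numpy(dtype=float)
    evaluable = ~np.isnan(Z).any(axis=1)
    with np.errstate(invalid="ignore"):
        big = np.abs(Z) >= threshold
        all_big = big.all(axis=1)
        same_sign = (Z > 0).all(axis=1) | (Z < 0).all(axis=1)
    hit = all_big & (same_sign if require_sign_consistency else True) & evaluable
    return pd.DataFrame(
        {"hit": hit, "evaluable": evaluable}, index=replicate_z.index.rename("reagent_id")
    )


def category_from_counts(n_reagents: int, n_scoring: int) -> int:
    """Gene category from reagent counts: 1, 2, 3, or 0 (none)."""
    if not 0 <= n_scoring <= n_reagents:
        raise ValueError("need 0 <= n_scoring <= n_reagents")
    if n_scoring == 0:
        return CATEGORY_NONE
    if n_scoring == n_reagents:
        return 1
    if n_scoring >= 2:
        return 2
    return 3


def assign_gene_categories(hits: pd.DataFrame, reagent_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate reagent hit calls to per-gene categories.

    ``hits`` is the output of :func:`call_reagent_hits`; non-evaluable
    reagents do not contribute to either count.  Genes with zero scoring
    reagents are retained with category 0 so that false-negative analyses can
    still see them.
    """
    gene_of = reagent_map.set_index("reagent_id")["gene_id"]
    unmapped = hits.index.difference(gene_of.index)
    if len(unmapped):
        raise KeyError(f"reagents not in map: {list(unmapped[:5])}")
    df = hits.join(gene_of, how="left")
    df = df[df["evaluable"]]
    grouped = df.groupby("gene_id", sort=True)["hit"].agg(["count", "sum"])
    out = pd.DataFrame(
        {
            "gene_id": grouped.index,
            "n_reagents": grouped["count"].astype(int).to_numpy(),
            "n_scoring": grouped["sum"].astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    out["category"] = [
        category_from_counts(nr, ns)
        for nr, ns in zip(out["n_reagents"], out["n_scoring"])
    ]
    return out


def apply_expression_filter(
    categories: pd.DataFrame,
    fpkm: pd.DataFrame,
    line: str,
    threshold: float = 1.0,
    elevated_threshold: float = 5.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Annotate gene categories with expression status in one cell line.

    ``expressed`` is FPKM >= threshold (or > with ``strict=True``; published
    wording supports both comparators) and ``elevated`` uses
    ``elevated_threshold`` the same way.  Genes absent from the FPKM table
    get missing (pd.NA) status — unknown is never counted as unexpressed.
    """
    if line not in fpkm.columns:
        raise KeyError(f"unknown cell line {line!r}")
    values = fpkm[line]
    out = categories.copy()

    def status(gene: str, cutoff: float):
        if gene not in values.index:
            return pd.NA
        v = values.loc[gene]
        return bool(v > cutoff) if strict else bool(v >= cutoff)

    out["expressed"] = [status(g, threshold) for g in out["gene_id"]]
    out["elevated"] = [status(g, elevated_threshold) for g in out["gene_id"]]
    return out


def count_expressed_intersection(
    fpkm: pd.DataFrame, lines: list[str], threshold: float = 1.0
) -> int:
    """Number of genes with FPKM >= threshold in every listed cell line."""
    if not lines:
        raise ValueError("need at least one cell line")
    unknown = [l for l in lines if l not in fpkm.columns]
    if unknown:
        raise KeyError(f"unknown cell lines: {unknown}")
    mask = (fpkm[lines] >= threshold).all(axis=1)
    return int(mask.sum())


@dataclass(frozen=True)
class RateEstimates:
    """Screen-level FP/FN rate estimates with their underlying counts.

    fp_reagent_rate : category-3 genes (their single scoring reagents) over
                      all reagents screened — the library-level FP rate.
    fp_hit_fraction : category-3 genes over all hit genes — the fraction of
                      the hit list at risk of being spurious.
    fn_reagent_rate : non-scoring reagents of category-1/2 genes over all
                      reagents of those genes — reagent-level FN rate among
                      genes corroborated by multiple reagents.
    """

    fp_reagent_rate: float
    fp_hit_fraction: float
    fn_reagent_rate: float
    n_category1: int
    n_category2: int
    n_category3: int
    n_hit_genes: int
    library_size: int
    fn_numerator: int
    fn_denominator: int


def estimate_screen_rates(categories: pd.DataFrame, library_size: int) -> RateEstimates:
    """Screen-level error-rate estimates from gene categories.

    Treats every category-3 gene's lone scoring reagent as a false positive
    (the conservative reading when category 3 shows no expression
    enrichment), and every non-scoring reagent of a category-1/2 gene as a
    false negative (those genes are corroborated hits).
    """
    cat = categories["category"]
    n1, n2, n3 = int((cat == 1).sum()), int((cat == 2).sum()), int((cat == 3).sum())
    n_hits = n1 + n2 + n3
    total_scoring = int(categories["n_scoring"].sum())
    if library_size < total_scoring:
        raise ValueError("library_size smaller than the number of scoring reagents")
    if library_size < 1 or n_hits < 1:
        raise ValueError("zero denominator in rate estimate")
    mask12 = cat.isin([1, 2])
    fn_den = int(categories.loc[mask12, "n_reagents"].sum())
    fn_num = int(
        (categories.loc[mask12, "n_reagents"] - categories.loc[mask12, "n_scoring"]).sum()
    )
    return RateEstimates(
        fp_reagent_rate=n3 / library_size,
        fp_hit_fraction=n3 / n_hits,
        fn_reagent_rate=(fn_num / fn_den) if fn_den else 0.0,
        n_category1=n1,
        n_category2=n2,
        n_category3=n3,
        n_hit_genes=n_hits,
        library_size=int(library_size),
        fn_numerator=fn_num,
        fn_denominator=fn_den,
    )
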