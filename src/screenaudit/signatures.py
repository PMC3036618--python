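"""Cross-screen signature clustering, reagent concordance, and FN-rate estimation.

Reagents targeting components of broadly required complexes (proteasome,
cytosolic ribosome, ...) score in many unrelated screens, so their Z-score
profiles across a panel of screens are mutually correlated.  Hierarchical
clustering of profiles (Pearson correlation distance, average linkage) pulls
these reagents into *signature clusters*; the cluster's *consensus signature*
is the per-screen mean Z of its members.

When a gene has two or more reagents in the matrix, their cluster membership
is a reagent-level consistency check:

* all reagents in the signature cluster  -> concordant (both worked);
* none in                                -> concordant (gene may be
  mis-annotated, redundant, or all reagents failed — indistinguishable);
* some in, some out                      -> discordant.  If the gene's
  functional annotation matches the cluster, the out-of-cluster reagent is an
  ineffective reagent (a false negative); if it does not, the in-cluster
  reagent is the suspect (an off-target false positive).

Counting attributed false-negative reagents over all reagents of genes with
at least one in-cluster reagent estimates the reagent-level false-negative
rate of the library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedCorrelationError",
    "Dendrogram",
    "FnRateEstimate",
    "ConcordanceResult",
    "pearson_profile_similarity",
    "hierarchical_cluster",
    "extract_clusters",
    "consensus_signature",
    "label_clusters",
    "classify_multireagent_genes",
    "estimate_cluster_fn_rate",
    "pooled_nonsignature_rate",
    "concordance_pipeline",
]

#: Cross-screen standard deviation below which a profile is considered flat
#: (noise-free degenerate data; Pearson correlation is undefined on it).
_FLAT_TOL = 1e-12


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson correlation is undefined (too few shared screens or zero variance)."""


def pearson_profile_similarity(a, b) -> float:
    """Pearson r between two Z profiles over their shared (pairwise-complete) screens.

    Requires at least 3 shared non-missing positions and non-zero variance in
    both profiles over those positions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    shared = ~(np.isnan(a) | np.isnan(b))
    if shared.sum() < 3:
        raise UndefinedCorrelationError(
            f"only {int(shared.sum())} shared screens; need >= 3"
        )
    x, y = a[shared], b[shared]
    sx, sy = x.std(), y.std()
    if sx < _FLAT_TOL or sy < _FLAT_TOL:
        raise UndefinedCorrelationError("zero variance in a profile; r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage dendrogram over reagent profiles.

    linkage  : scipy linkage matrix (heights are correlation distances 1 - r)
    leaves   : reagent ids, in matrix row order of the clustered rows
    excluded : reagent ids dropped because their profiles support no correlation
    """

    linkage: np.ndarray
    leaves: tuple[str, ...]
    excluded: tuple[str, ...] = ()


def _correlation_distances(X: np.ndarray) -> np.ndarray:
    """Full pairwise 1 - Pearson r matrix, pairwise-complete over NaNs."""
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
    else:
        masked = np.ma.masked_invalid(X)
        corr = np.ma.corrcoef(masked, allow_masked=True).filled(np.nan)
    corr = np.clip(corr, -1.0, 1.0)
    return 1.0 - corr


def hierarchical_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Cluster reagent profiles by average linkage on Pearson correlation distance.

    Rows whose profiles cannot support a correlation (fewer than 3 observed
    screens, or zero variance across screens) are excluded with a warning.
    Residual undefined pairs (insufficient pairwise overlap between two
    otherwise valid rows) are assigned the maximal distance 2.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        stds = np.nanstd(X, axis=1)
    ok = (n_obs >= 3) & (stds > _FLAT_TOL)
    excluded = tuple(matrix.index[~ok])
    for rid in excluded:
        logger.warning("excluding reagent %s: profile supports no correlation", rid)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable profiles after exclusions")

    Xk = X[ok]
    D = _correlation_distances(Xk)
    np.fill_diagonal(D, 0.0)
    bad = ~np.isfinite(D)
    if bad.any():
        logger.warning("%d reagent pairs lack >=3 shared screens; distance set to 2", int(bad.sum() // 2))
        D[bad] = 2.0
    D = (D + D.T) / 2.0  # enforce exact symmetry for squareform
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(
        linkage=Z, leaves=tuple(matrix.index[ok]), excluded=excluded
    )


def extract_clusters(dendrogram: Dendrogram, cut_height: float) -> dict[str, int]:
    """Flat clusters at a correlation-distance cut: merges at height <= cut join.

    Returns reagent id -> cluster id.  Excluded reagents are absent.
    Cutting below the first merge yields all singletons; above the last, one
    cluster.
    """
    if cut_height < 0:
        raise ValueError("cut_height must be >= 0")
    flat = hierarchy.fcluster(dendrogram.linkage, t=cut_height, criterion="distance")
    return {leaf: int(c) for leaf, c in zip(dendrogram.leaves, flat)}


def consensus_signature(members, matrix: pd.DataFrame) -> pd.Series:
    """Per-screen mean Z over a cluster's member reagents, ignoring missing entries."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    return matrix.loc[members].mean(axis=0, skipna=True)


def label_clusters(
    memberships: dict[str, int],
    reagent_map: pd.DataFrame,
    annotation: pd.DataFrame,
    min_cluster_size: int = 3,
    majority_fraction: float = 0.5,
) -> dict[int, str]:
    """Label each sufficiently large cluster by the majority annotation of its members.

    ``annotation`` maps gene_id -> set_label (e.g. a complex or pathway
    membership).  A cluster is labeled only when one label covers strictly
    more than ``majority_fraction`` of *all* its members — a signature
    cluster must be enriched for the gene set, not merely touch it; chance
    co-clusters of unannotated reagents that happen to contain one annotated
    gene stay unlabeled.  Clusters smaller than ``min_cluster_size`` get no
    label.  Ties break lexicographically for determinism.
    """
    gene_of = dict(zip(reagent_map["reagent_id"], reagent_map["gene_id"]))
    label_of_gene = dict(zip(annotation["gene_id"], annotation["set_label"]))
    by_cluster: dict[int, Counter] = {}
    sizes: Counter = Counter()
    for reagent, cluster in memberships.items():
        sizes[cluster] += 1
        gene = gene_of.get(reagent)
        if gene is None:
            raise KeyError(f"reagent {reagent!r} missing from reagent map")
        lab = label_of_gene.get(gene)
        if lab is not None and not (isinstance(lab, float) and np.isnan(lab)):
            by_cluster.setdefault(cluster, Counter())[lab] += 1
    labels: dict[int, str] = {}
    for cluster, counts in by_cluster.items():
        if sizes[cluster] < min_cluster_size:
            continue
        # deterministic tie-break: highest count, then lexicographically smallest
        best_count = max(counts.values())
        if best_count <= majority_fraction * sizes[cluster]:
            continue
        candidates = sorted(l for l, c in counts.items() if c == best_count)
        labels[cluster] = candidates[0]
    return labels


def classify_multireagent_genes(
    memberships: dict[str, int],
    matrix: pd.DataFrame,
    reagent_map: pd.DataFrame,
    annotation: pd.DataFrame,
    cluster_labels: dict[int, str] | None = None,
    r_threshold: float = 0.5,
    min_cluster_size: int = 3,
    check_consensus_r: bool = True,
) -> pd.DataFrame:
    """Concordance calls for every gene with >= 2 reagents in the matrix.

    The dendrogram cut defines the signature clusters and their consensus
    signatures; whether a reagent *shows* a signature is then judged by
    correlation: a reagent is *in* when its profile correlates with some
    labeled cluster's consensus at r >= r_threshold (ties to the
    best-correlated cluster).  Average-linkage flat clusters are
    conservative at the margin, so membership alone would miss reagents
    whose profiles plainly track the consensus; correlation to the
    consensus is the criterion that generalizes.  With
    ``check_consensus_r=False`` (degenerate, noise-free matrices) cut
    membership itself decides.

    Classification: all reagents in -> ``concordant_in``; none ->
    ``concordant_out``; mixed -> ``discordant``.  Discordant genes are
    attributed ``false_negative`` when the gene's annotation matches the
    cluster label (the out-of-cluster reagent failed), ``false_positive``
    when it does not (the in-cluster reagent is spurious), and ``ambiguous``
    when the in-cluster reagents sit in unlabeled or conflicting clusters.
    """
    gene_of = dict(zip(reagent_map["reagent_id"], reagent_map["gene_id"]))
    for reagent in matrix.index:
        if reagent in memberships and reagent not in gene_of:
            raise KeyError(f"reagent {reagent!r} missing from reagent map")
    label_of_gene = dict(zip(annotation["gene_id"], annotation["set_label"]))
    if cluster_labels is None:
        cluster_labels = label_clusters(
            memberships, reagent_map, annotation, min_cluster_size=min_cluster_size
        )

    consensus: dict[int, pd.Series] = {}
    members_of: dict[int, list[str]] = {}
    for reagent, cluster in memberships.items():
        members_of.setdefault(cluster, []).append(reagent)
    for cluster in cluster_labels:
        consensus[cluster] = consensus_signature(members_of[cluster], matrix)

    genes: dict[str, list[str]] = {}
    for reagent in matrix.index:
        gene = gene_of.get(reagent)
        if gene is not None:
            genes.setdefault(gene, []).append(reagent)

    records = []
    for gene, reagents in sorted(genes.items()):
        if len(reagents) < 2:
            continue
        in_flags: dict[str, bool] = {}
        in_cluster_of: dict[str, int] = {}
        for reagent in reagents:
            if check_consensus_r:
                best_cluster, best_r = None, -np.inf
                for cluster in cluster_labels:
                    try:
                        r = pearson_profile_similarity(
                            matrix.loc[reagent], consensus[cluster]
                        )
                    except UndefinedCorrelationError:
                        continue
                    if r > best_r:
                        best_cluster, best_r = cluster, r
                is_in = best_cluster is not None and best_r >= r_threshold
                if is_in:
                    in_cluster_of[reagent] = best_cluster
            else:
                cluster = memberships.get(reagent)
                is_in = cluster is not None and cluster in cluster_labels
                if is_in:
                    in_cluster_of[reagent] = cluster
            in_flags[reagent] = is_in
        n_in = sum(in_flags.values())
        if n_in == len(reagents):
            classification, attribution = "concordant_in", ""
        elif n_in == 0:
            classification, attribution = "concordant_out", ""
        else:
            classification = "discordant"
            labels = {cluster_labels[c] for c in in_cluster_of.values()}
            if len(labels) != 1:
                attribution = "ambiguous"
            else:
                (cluster_label,) = labels
                gene_label = label_of_gene.get(gene)
                attribution = (
                    "false_negative" if gene_label == cluster_label else "false_positive"
                )
        records.append(
            {
                "gene_id": gene,
                "n_reagents": len(reagents),
                "n_in_cluster": n_in,
                "classification": classification,
                "attribution": attribution,
                "cluster_label": (
                    sorted({cluster_labels[c] for c in in_cluster_of.values()})[0]
                    if in_cluster_of
                    else ""
                ),
                "in_reagents": ";".join(r for r in reagents if in_flags[r]),
                "out_reagents": ";".join(r for r in reagents if not in_flags[r]),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "n_reagents",
            "n_in_cluster",
            "classification",
            "attribution",
            "cluster_label",
            "in_reagents",
            "out_reagents",
        ],
    )


@dataclass(frozen=True)
class FnRateEstimate:
    """Reagent-level false-negative rate with its underlying counts."""

    n_false_negative: int
    total_reagents: int
    rate: float

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def estimate_cluster_fn_rate(calls: pd.DataFrame, total_reagents: int) -> FnRateEstimate:
    """FN rate = (# out-of-cluster reagents of FN-attributed discordant genes) / total reagents."""
    if total_reagents < 1:
        raise ValueError("total_reagents must be >= 1")
    fn_calls = calls[calls["attribution"] == "false_negative"]
    n_fn = int((fn_calls["n_reagents"] - fn_calls["n_in_cluster"]).sum())
    return FnRateEstimate(n_fn, int(total_reagents), n_fn / total_reagents)


def signature_reagent_total(
    calls: pd.DataFrame, annotated_genes: set[str] | None = None
) -> int:
    """Total reagents of multi-reagent genes with >= 1 in-cluster reagent.

    This is the natural denominator for the cluster-based FN-rate estimate:
    genes whose reagents all miss the cluster cannot be attributed (the gene
    may simply not share the signature) and are left out.  When
    ``annotated_genes`` is given the count is further restricted to the
    annotated gene set — the population whose members are *expected* to show
    the signature; unannotated bystanders pulled in by off-target activity
    say nothing about reagent efficacy on set genes.
    """
    mask = calls["classification"].isin(["concordant_in", "discordant"])
    if annotated_genes is not None:
        mask &= calls["gene_id"].isin(annotated_genes)
    return int(calls.loc[mask, "n_reagents"].sum())


def pooled_nonsignature_rate(set_counts: list[tuple[int, int]]) -> float:
    """Pooled fraction of set members lacking the expected signature.

    ``set_counts`` pairs (non-clustering genes, set size) per gene set; the
    pooled rate is the ratio of summed numerators to summed set sizes.  This
    upper-bound FN estimate charges every non-clustering set member as a
    potential false negative.
    """
    if not set_counts:
        raise ValueError("empty input")
    num = sum(c for c, _ in set_counts)
    den = sum(n for _, n in set_counts)
    if den == 0:
        raise ValueError("zero total set size")
    for c, n in set_counts:
        if c > n:
            raise ValueError(f"count {c} exceeds set size {n}")
    return num / den


@dataclass(frozen=True)
class ConcordanceResult:
    """Output of the end-to-end clustering + concordance pipeline."""

    calls: pd.DataFrame
    estimate: FnRateEstimate
    memberships: dict[str, int]
    cluster_labels: dict[int, str]
    dendrogram: Dendrogram | None
    degenerate: bool = False


def concordance_pipeline(
    matrix: pd.DataFrame,
    reagent_map: pd.DataFrame,
    annotation: pd.DataFrame,
    cut_height: float = 0.5,
    r_threshold: float = 0.5,
    min_cluster_size: int = 3,
    z_active_threshold: float = 2.0,
) -> ConcordanceResult:
    """Cluster a Z matrix, call gene concordance, and estimate the FN rate.

    Normal path: average-linkage clustering at ``cut_height`` on correlation
    distance, cluster labeling by majority annotation, concordance calls with
    the consensus-correlation check at ``r_threshold``.

    Degenerate path: a noise-free matrix collapses every profile to a
    cross-screen constant (plate Z-scores remove any common scale), so
    correlation is undefined everywhere.  The pipeline detects this and
    groups reagents by Z level instead: profiles split at the largest gap in
    their mean Z, and the far-from-zero side becomes the candidate signature
    cluster provided the gap spans at least ``z_active_threshold`` Z units.
    In that regime active and inactive reagents are perfectly separated, so
    the estimate is exact.
    """
    X = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        stds = np.nanstd(X, axis=1)
    degenerate = bool(np.all(stds[np.isfinite(stds)] <= _FLAT_TOL))

    if degenerate:
        means = np.nanmean(X, axis=1)
        order = np.argsort(means)
        gaps = np.diff(means[order])
        split = int(np.argmax(gaps)) if len(gaps) else 0
        if len(gaps) and gaps[split] >= z_active_threshold:
            low = np.zeros(len(means), dtype=bool)
            low[order[: split + 1]] = True
            # the signature side is the one farther from Z = 0
            side_low = abs(means[low].mean()) >= abs(means[~low].mean())
            active = low if side_low else ~low
        else:
            active = np.zeros(len(means), dtype=bool)
        memberships = {
            rid: (1 if act else 2 + i)
            for i, (rid, act) in enumerate(zip(matrix.index, active))
        }
        dendro = None
        labels = label_clusters(
            memberships, reagent_map, annotation, min_cluster_size=min_cluster_size
        )
        calls = classify_multireagent_genes(
            memberships,
            matrix,
            reagent_map,
            annotation,
            cluster_labels=labels,
            r_threshold=r_threshold,
            min_cluster_size=min_cluster_size,
            check_consensus_r=False,
        )
    else:
        dendro = hierarchical_cluster(matrix)
        memberships = extract_clusters(dendro, cut_height)
        labels = label_clusters(
            memberships, reagent_map, annotation, min_cluster_size=min_cluster_size
        )
        calls = classify_multireagent_genes(
            memberships,
            matrix,
            reagent_map,
            annotation,
            cluster_labels=labels,
            r_threshold=r_threshold,
            min_cluster_size=min_cluster_size,
        )
    annotated = set(annotation["gene_id"])
    total = signature_reagent_total(calls, annotated_genes=annotated)
    if total == 0:
        estimate = FnRateEstimate(0, 0, float("nan"))
    else:
        estimate = estimate_cluster_fn_rate(calls, total)
    return ConcordanceResult(
        calls=calls,
        estimate=estimate,
        memberships=memberships,
        cluster_labels=labels,
        dendrogram=dendro,
        degenerate=degenerate,
    )
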