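"""Profile correlation, hierarchical clustering, concordance calls, FN-rate estimation."""

import numpy as np
import pandas as pd
import pytest

import screenaudit as sa
from screenaudit import signatures, simdata, normalize
from screenaudit.signatures import UndefinedCorrelationError

from conftest import per_screen_matrix


def brute_force_average_linkage(D: np.ndarray):
    """Independent O(n^3) UPGMA oracle: repeatedly merge the closest pair of
    clusters, where cluster distance is the mean of all member-pair
    dissimilarities from the original matrix.  Returns merge heights."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i_pos, a in enumerate(keys):
            for b in keys[i_pos + 1 :]:
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestPearson:
    def test_self_similarity_is_one(self):
        p = np.array([1.0, 2.0, -1.0, 0.5])
        assert sa.pearson_profile_similarity(p, p) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        p = np.array([1.0, 2.0, -1.0, 0.5])
        assert sa.pearson_profile_similarity(p, -p) == pytest.approx(-1.0)

    def test_orthogonal_sign_patterns(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert sa.pearson_profile_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_complete_over_missing(self):
        a = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        b = np.array([2.0, 4.0, 6.0, 100.0, np.nan])
        assert sa.pearson_profile_similarity(a, b) == pytest.approx(1.0)

    def test_too_few_shared_positions(self):
        a = np.array([1.0, 2.0, np.nan, np.nan])
        b = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            sa.pearson_profile_similarity(a, b)

    def test_zero_variance_profile(self):
        with pytest.raises(UndefinedCorrelationError):
            sa.pearson_profile_similarity(
                np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])
            )


class TestHierarchicalClustering:
    def test_identical_profiles_merge_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 0.0], [1.0, 2.0, 3.0, 0.0]], index=["a", "b"]
        )
        dendro = sa.hierarchical_cluster(mat)
        assert dendro.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profile_merges_last_at_two(self):
        base = [1.0, 2.0, 3.0, 0.0]
        mat = pd.DataFrame(
            [base, base, [-v for v in base]], index=["a", "b", "c"]
        )
        dendro = sa.hierarchical_cluster(mat)
        assert dendro.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert dendro.linkage[1, 2] == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        """Average-linkage merge heights equal an exhaustive UPGMA recomputation."""
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.normal(size=(n, 12)), index=[f"r{i}" for i in range(n)])
        dendro = sa.hierarchical_cluster(mat)
        D = 1.0 - np.corrcoef(mat.to_numpy())
        np.fill_diagonal(D, 0.0)
        want = brute_force_average_linkage(D)
        got = dendro.linkage[:, 2]
        assert got == pytest.approx(want, abs=1e-10)

    def test_flat_rows_excluded_with_warning(self, caplog):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 0.0], [5.0, 5.0, 5.0]],
            index=["a", "b", "flat"],
        )
        with caplog.at_level("WARNING"):
            dendro = sa.hierarchical_cluster(mat)
        assert dendro.excluded == ("flat",)
        assert "flat" in caplog.text

    def test_monotone_heights(self, small_zmatrix):
        dendro = sa.hierarchical_cluster(per_screen_matrix(small_zmatrix))
        h = dendro.linkage[:, 2]
        assert (np.diff(h) >= -1e-12).all()


class TestExtractClusters:
    @pytest.fixture()
    def dendro(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 0.0], [1.1, 2.2, 2.9, 0.2], [3.0, -1.0, 0.5, 2.0]],
            index=["a", "b", "c"],
        )
        return sa.hierarchical_cluster(mat)

    def test_cut_below_first_merge_all_singletons(self, dendro):
        first = dendro.linkage[0, 2]
        clusters = sa.extract_clusters(dendro, first / 2 if first > 0 else -1)
        assert len(set(clusters.values())) == len(clusters)

    def test_cut_above_last_merge_one_cluster(self, dendro):
        clusters = sa.extract_clusters(dendro, dendro.linkage[-1, 2] + 1)
        assert len(set(clusters.values())) == 1

    def test_recovers_planted_blocks(self):
        """Two planted profile blocks separate cleanly at a 0.5 cut."""
        rng = np.random.default_rng(3)
        sig_a = rng.normal(size=10) * 3
        sig_b = rng.normal(size=10) * 3
        rows, labels = [], []
        for i in range(6):
            rows.append(sig_a + rng.normal(size=10) * 0.3)
            labels.append(f"a{i}")
        for i in range(6):
            rows.append(sig_b + rng.normal(size=10) * 0.3)
            labels.append(f"b{i}")
        mat = pd.DataFrame(rows, index=labels)
        clusters = sa.extract_clusters(sa.hierarchical_cluster(mat), 0.5)
        a_ids = {clusters[f"a{i}"] for i in range(6)}
        b_ids = {clusters[f"b{i}"] for i in range(6)}
        assert len(a_ids) == 1 and len(b_ids) == 1 and a_ids != b_ids


class TestConsensus:
    def test_single_member_equals_profile(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=["s1", "s2", "s3"])
        cons = sa.consensus_signature(["a"], mat)
        assert cons.tolist() == [1.0, 2.0, 3.0]

    def test_mean_of_two_profiles(self):
        mat = pd.DataFrame([[1.0, 3.0], [3.0, 1.0]], index=["a", "b"])
        assert sa.consensus_signature(["a", "b"], mat).tolist() == [2.0, 2.0]

    def test_member_order_irrelevant_and_idempotent(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        c1 = sa.consensus_signature(["a", "b", "c"], mat)
        c2 = sa.consensus_signature(["c", "a", "b"], mat)
        pd.testing.assert_series_equal(c1, c2)
        # adding a member identical to the consensus leaves it unchanged
        mat2 = pd.concat([mat, c1.rename("e").to_frame().T])
        c3 = sa.consensus_signature(["a", "b", "c", "e"], mat2)
        assert c3.to_numpy() == pytest.approx(c1.to_numpy())

    def test_empty_set_rejected(self):
        mat = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(ValueError):
            sa.consensus_signature([], mat)


def toy_concordance(flip=None):
    """Six-reagent toy: genes gA/gB (2 reagents, ribosome-annotated), gC
    (2 reagents, unannotated); a 4-reagent ribosome signature cluster."""
    rng = np.random.default_rng(8)
    sig = np.array([5.0, -4.0, 3.0, -5.0, 4.0, -3.0, 2.0, -2.0] * 2)
    n = len(sig)
    rows = {}
    for rid in ["gA_1", "gA_2", "gB_1", "gB_2"]:
        rows[rid] = sig + rng.normal(size=n) * 0.3
    for rid in ["gC_1", "gC_2", "gD_1", "gD_2"]:
        rows[rid] = rng.normal(size=n) * 0.5
    if flip:
        for rid, to_sig in flip.items():
            rows[rid] = (
                sig + rng.normal(size=n) * 0.3 if to_sig else rng.normal(size=n) * 0.5
            )
    mat = pd.DataFrame(rows).T
    reagent_map = pd.DataFrame(
        {
            "reagent_id": list(rows),
            "gene_id": [r.split("_")[0] for r in rows],
        }
    )
    annotation = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "set_label": ["ribosome", "ribosome"]}
    )
    return mat, reagent_map, annotation


class TestClassification:
    def test_both_in_cluster_concordant(self):
        mat, rmap, annot = toy_concordance()
        res = sa.concordance_pipeline(mat, rmap, annot, min_cluster_size=3)
        calls = res.calls.set_index("gene_id")
        assert calls.loc["gA", "classification"] == "concordant_in"
        assert calls.loc["gB", "classification"] == "concordant_in"
        assert calls.loc["gC", "classification"] == "concordant_out"

    def test_discordant_annotated_gene_is_false_negative(self):
        """One reagent shows the signature, the sibling does not, and the gene
        belongs to the signature's functional set: the sibling failed."""
        mat, rmap, annot = toy_concordance(flip={"gB_2": False})
        res = sa.concordance_pipeline(mat, rmap, annot, min_cluster_size=3)
        calls = res.calls.set_index("gene_id")
        assert calls.loc["gB", "classification"] == "discordant"
        assert calls.loc["gB", "attribution"] == "false_negative"
        assert calls.loc["gB", "out_reagents"] == "gB_2"

    def test_discordant_unrelated_gene_is_false_positive(self):
        """A reagent of a gene outside the functional set lands in the
        signature cluster: the in-cluster reagent is the suspect."""
        mat, rmap, annot = toy_concordance(flip={"gC_1": True})
        res = sa.concordance_pipeline(mat, rmap, annot, min_cluster_size=3)
        calls = res.calls.set_index("gene_id")
        assert calls.loc["gC", "classification"] == "discordant"
        assert calls.loc["gC", "attribution"] == "false_positive"

    def test_classification_symmetric_in_reagent_order(self):
        mat, rmap, annot = toy_concordance(flip={"gB_2": False})
        res1 = sa.concordance_pipeline(mat, rmap, annot, min_cluster_size=3)
        perm = mat.iloc[::-1]
        res2 = sa.concordance_pipeline(perm, rmap, annot, min_cluster_size=3)
        c1 = res1.calls.set_index("gene_id")["classification"]
        c2 = res2.calls.set_index("gene_id")["classification"]
        pd.testing.assert_series_equal(c1, c2)


class TestRateArithmetic:
    def test_eight_of_one_hundred_three(self):
        """Eight discordant-FN reagents among 103 signature-set reagents -> ~8%."""
        # 51 genes / 103 reagents (one gene carries 3 reagents): 42 concordant,
        # 9 discordant of which one is attributed false positive -> 8 FN reagents
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(51)],
                "n_reagents": [3] + [2] * 50,
                "n_in_cluster": [3] + [1] * 8 + [1] + [2] * 33 + [0] * 8,
                "classification": ["concordant_in"]
                + ["discordant"] * 9
                + ["concordant_in"] * 33
                + ["concordant_out"] * 8,
                "attribution": [""]
                + ["false_negative"] * 8
                + ["false_positive"]
                + [""] * 41,
            }
        )
        est = sa.estimate_cluster_fn_rate(calls, total_reagents=103)
        assert est.n_false_negative == 8
        assert est.rate == pytest.approx(8 / 103)
        assert round(est.percent) == 8

    def test_no_discordance_zero_rate(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "n_reagents": [2],
                "n_in_cluster": [2],
                "classification": ["concordant_in"],
                "attribution": [""],
            }
        )
        assert sa.estimate_cluster_fn_rate(calls, 2).rate == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sa.estimate_cluster_fn_rate(pd.DataFrame(columns=["attribution", "n_reagents", "n_in_cluster"]), 0)

    def test_pooled_rate_of_two_sets(self):
        """22/94 ribosome-like plus 29/58 proteasome-like pools to ~34%."""
        rate = sa.pooled_nonsignature_rate([(22, 94), (29, 58)])
        assert rate == pytest.approx(51 / 152)
        assert round(100 * rate) == 34

    def test_pooled_rate_single_set(self):
        assert sa.pooled_nonsignature_rate([(22, 94)]) == pytest.approx(22 / 94)
        assert sa.pooled_nonsignature_rate([(0, 10)]) == 0.0

    def test_pooled_rate_validates(self):
        with pytest.raises(ValueError):
            sa.pooled_nonsignature_rate([])
        with pytest.raises(ValueError):
            sa.pooled_nonsignature_rate([(5, 4)])


class TestPlantedRecovery:
    def test_noise_free_recovery_is_exact(self):
        """With no well noise the concordance estimate equals the planted
        inactive fraction among signature genes with an active reagent."""
        params = sa.SimulationParams(
            n_genes=200, n_true_hits=30, reagent_fn_rate=0.1, noise_sd=0.0, seed=21
        )
        rmap, truth = simdata.generate_library(params)
        readings = simdata.generate_screen_plates(rmap, truth, params)
        zmat = normalize.assemble_profile_matrix(normalize.normalize_plates(readings))
        res = sa.concordance_pipeline(
            per_screen_matrix(zmat), rmap, simdata.hit_annotation(truth)
        )
        assert res.degenerate
        t = truth[truth["gene_is_hit"]]
        active = t["effective"] | t["off_target"]
        per_gene = t.assign(a=active).groupby("gene_id")["a"].agg(["sum", "count"])
        seen = per_gene[per_gene["sum"] > 0]
        assert res.estimate.n_false_negative == int((seen["count"] - seen["sum"]).sum())
        assert res.estimate.total_reagents == int(seen["count"].sum())

    def test_noisy_recovery_tracks_planted_rate(self):
        """At 8% planted reagent inefficacy the pipeline estimate lands within
        the planted count's neighbourhood."""
        params = sa.SimulationParams(seed=1)  # defaults: 1000 genes, R_FN=0.08
        rmap, truth = simdata.generate_library(params)
        readings = simdata.generate_screen_plates(rmap, truth, params)
        zmat = normalize.assemble_profile_matrix(normalize.normalize_plates(readings))
        res = sa.concordance_pipeline(
            per_screen_matrix(zmat), rmap, simdata.hit_annotation(truth)
        )
        assert not res.degenerate
        assert 0.03 <= res.estimate.rate <= 0.15
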