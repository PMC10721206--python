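import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from meiomap import celltyping as ct
from meiomap.io import CountMatrix


def make_profiles(mean, frac, clusters=("c1", "c2", "c3"), genes=("gA",)):
    """Build ClusterProfile fixtures from per-cluster mean/frac rows."""
    profiles = []
    for i, cluster in enumerate(clusters):
        profiles.append(
            ct.ClusterProfile(
                cluster=cluster,
                mean_expr=pd.Series(
                    [mean[g][i] for g in genes], index=list(genes)
                ),
                frac_expressing=pd.Series(
                    [frac[g][i] for g in genes], index=list(genes)
                ),
                n_cells=100,
                mean_numi=1000.0,
                mean_nfeature=100.0,
            )
        )
    return profiles


def dummy_matrix(genes, clusters=("c1", "c2", "c3")):
    n = len(clusters) * 2
    counts = sp.csr_matrix(np.ones((n, len(genes)), dtype=int))
    cells = [f"cell{i}" for i in range(n)]
    labels = {c: clusters[i % len(clusters)] for i, c in enumerate(cells)}
    return CountMatrix(cells, list(genes), counts, labels)


class TestNormalize:
    def test_pre_log_values_sum_to_scale(self):
        counts = sp.csr_matrix(np.array([[2, 0, 2]]))
        m = CountMatrix(["c1"], ["g1", "g2", "g3"], counts)
        norm, _ = ct.normalize_counts(m, scale_total=100)
        np.testing.assert_allclose(np.expm1(norm.loc["c1"]), [50, 0, 50])

    def test_depth_invariance_within_cell(self):
        a = CountMatrix(["c1"], ["g1", "g2"], sp.csr_matrix(np.array([[3, 7]])))
        b = CountMatrix(["c1"], ["g1", "g2"], sp.csr_matrix(np.array([[6, 14]])))
        na, _ = ct.normalize_counts(a)
        nb, _ = ct.normalize_counts(b)
        pd.testing.assert_frame_equal(na, nb)

    def test_all_zero_cell_dropped(self):
        counts = sp.csr_matrix(np.array([[1, 1], [0, 0]]))
        m = CountMatrix(["keep", "drop"], ["g1", "g2"], counts)
        with pytest.warns(UserWarning, match="all-zero"):
            norm, dropped = ct.normalize_counts(m)
        assert dropped == ["drop"] and list(norm.index) == ["keep"]

    def test_bad_scale(self, toy_matrix):
        with pytest.raises(ValueError):
            ct.normalize_counts(toy_matrix, scale_total=0)


class TestFilterCandidateMarkers:
    def test_two_criteria_brute_force_case(self):
        # mean (10, 4, 6), expressed in 30% everywhere:
        # max = 10; criterion 2 passes where mean > 5 -> c1 and c3
        profiles = make_profiles(
            {"gA": (10.0, 4.0, 6.0)}, {"gA": (0.3, 0.3, 0.3)}
        )
        m = dummy_matrix(["gA"])
        kn = [ct.MarkerKnowledge("gA", "ref", frozenset({"SPT"}))]
        (call,) = ct.filter_candidate_markers(m, kn, profiles=profiles)
        assert call.marked_clusters == {"c1", "c3"}
        assert call.status == "enriched"

    def test_exact_ten_percent_fails_strict(self):
        profiles = make_profiles({"gA": (10.0, 1.0, 1.0)}, {"gA": (0.1, 0.1, 0.1)})
        m = dummy_matrix(["gA"])
        kn = [ct.MarkerKnowledge("gA", "ref", frozenset({"SPT"}))]
        (call,) = ct.filter_candidate_markers(m, kn, profiles=profiles)
        assert call.status == "candidate" and call.marked_clusters == set()

    def test_idempotent_and_order_independent(self):
        genes = ["gA", "gB", "gC"]
        mean = {"gA": (10, 4, 6), "gB": (1, 9, 2), "gC": (3, 3, 3)}
        frac = {"gA": (0.3, 0.3, 0.3), "gB": (0.5, 0.5, 0.05), "gC": (0.2, 0.2, 0.2)}
        kn = [ct.MarkerKnowledge(g, f"r{g}", frozenset({"SPT"})) for g in genes]
        ref = {
            c.gene_target: c.marked_clusters
            for c in ct.filter_candidate_markers(
                dummy_matrix(genes), kn, profiles=make_profiles(mean, frac, genes=genes)
            )
        }
        for perm in itertools.permutations(genes):
            perm_kn = [ct.MarkerKnowledge(g, f"r{g}", frozenset({"SPT"}))
                       for g in perm]
            got = {
                c.gene_target: c.marked_clusters
                for c in ct.filter_candidate_markers(
                    dummy_matrix(list(perm)), perm_kn,
                    profiles=make_profiles(mean, frac, genes=perm),
                )
            }
            assert got == ref

    def test_no_knowledge_gene_in_matrix(self):
        m = dummy_matrix(["gA"])
        kn = [ct.MarkerKnowledge("absent", "ref", frozenset({"SPT"}))]
        with pytest.raises(ValueError, match="no knowledge gene"):
            ct.filter_candidate_markers(m, kn)

    def test_one_to_one_orthology_enforced(self):
        m = dummy_matrix(["gA", "gB"])
        kn = [
            ct.MarkerKnowledge("gA", "ref", frozenset({"SPT"})),
            ct.MarkerKnowledge("gB", "ref", frozenset({"SPT"})),
        ]
        with pytest.raises(ValueError, match="one-to-one"):
            ct.filter_candidate_markers(m, kn)


class TestAssignClusterTypes:
    def test_single_vote(self):
        kn = [ct.MarkerKnowledge("gA", "r", frozenset({"eSPG"}))]
        calls = [ct.MarkerCall("gA", {"c1"}, "enriched")]
        (a,) = ct.assign_cluster_types(calls, kn)
        assert a.cell_type == "eSPG" and a.vote_counts == {"eSPG": 1}

    def test_tie_gives_unassigned(self):
        kn = [
            ct.MarkerKnowledge(f"g{i}", f"r{i}", frozenset({t}))
            for i, t in enumerate(["SPT"] * 4 + ["sSPT"] * 4)
        ]
        calls = [ct.MarkerCall(f"g{i}", {"c1"}, "enriched") for i in range(8)]
        (a,) = ct.assign_cluster_types(calls, kn)
        assert a.cell_type == ct.UNASSIGNED
        assert a.vote_counts == {"SPT": 4, "sSPT": 4}

    def test_argmax_matches_exhaustive_scan(self, rng):
        types = ["eSPG", "aSPG", "eSPC"]
        clusters = ["c1", "c2", "c3"]
        kn, calls = [], []
        g = 0
        table = {c: dict.fromkeys(types, 0) for c in clusters}
        for c in clusters:
            for t in types:
                n = int(rng.integers(0, 4))
                table[c][t] = n
                for _ in range(n):
                    kn.append(
                        ct.MarkerKnowledge(f"g{g}", f"r{g}", frozenset({t}))
                    )
                    calls.append(ct.MarkerCall(f"g{g}", {c}, "enriched"))
                    g += 1
        for a in ct.assign_cluster_types(calls, kn):
            counts = table[a.cluster]
            best = max(counts.values())
            winners = [t for t, v in counts.items() if v == best]
            expected = winners[0] if len(winners) == 1 and best > 0 else ct.UNASSIGNED
            assert a.cell_type == expected


class TestPruneMarkers:
    @staticmethod
    def scenario(n_marked: int, n_unsupported: int):
        """One gene marking n_marked cell types, n_unsupported of them
        outside its reference support; heavy anchor genes pin the vote."""
        types = [f"T{i}" for i in range(n_marked)]
        clusters = [f"c{i}" for i in range(n_marked)]
        supported = frozenset(types[: n_marked - n_unsupported]) or frozenset({"Tx"})
        kn = [ct.MarkerKnowledge("gene", "ref", supported)]
        calls = [ct.MarkerCall("gene", set(clusters), "enriched")]
        for i, (c, t) in enumerate(zip(clusters, types)):
            for j in range(5):  # anchors dominate the vote
                name = f"anchor{i}_{j}"
                kn.append(ct.MarkerKnowledge(name, f"r{name}", frozenset({t})))
                calls.append(ct.MarkerCall(name, {c}, "enriched"))
        assignment = ct.assign_cluster_types(calls, kn)
        return calls, assignment, kn

    @pytest.mark.parametrize(
        "n_marked,n_unsupported",
        [(n, u) for n in range(1, 6) for u in range(0, n + 1)],
    )
    def test_rule_by_enumeration(self, n_marked, n_unsupported):
        calls, assignment, kn = self.scenario(n_marked, n_unsupported)
        result = {
            c.gene_target: c.status
            for c in ct.prune_markers(calls, assignment, kn)
        }
        if n_marked == 1:
            expected = "retained" if n_unsupported == 0 else "pruned"
        else:
            expected = "retained" if n_unsupported <= 2 else "pruned"
        assert result["gene"] == expected

    def test_fixed_point_and_order_invariance(self, rng):
        types = ["A", "B", "C"]
        clusters = ["c1", "c2", "c3"]
        kn, calls = [], []
        for i in range(12):
            marked = set(
                rng.choice(clusters, size=int(rng.integers(1, 4)), replace=False)
            )
            support = frozenset(
                rng.choice(types, size=int(rng.integers(1, 3)), replace=False)
            )
            kn.append(ct.MarkerKnowledge(f"g{i}", f"r{i}", support))
            calls.append(ct.MarkerCall(f"g{i}", marked, "enriched"))
        assignment = ct.assign_cluster_types(calls, kn)
        ref = sorted(
            (c.gene_target, c.status)
            for c in ct.prune_markers(calls, assignment, kn)
        )
        order = rng.permutation(len(calls))
        got = sorted(
            (c.gene_target, c.status)
            for c in ct.prune_markers(
                [calls[i] for i in order], assignment, [kn[i] for i in order]
            )
        )
        assert got == ref

    def test_missing_assignment_is_error(self):
        kn = [ct.MarkerKnowledge("gA", "r", frozenset({"SPT"}))]
        calls = [ct.MarkerCall("gA", {"c9"}, "enriched")]
        with pytest.raises(ValueError, match="no assignment"):
            ct.prune_markers(calls, [], kn)


class TestClusterCorrelation:
    def test_perfect_linearity_and_diagonal(self):
        profiles = make_profiles(
            {"g1": (1, 2, 1), "g2": (2, 4, 2), "g3": (3, 6, 9)},
            {"g1": (0.5,) * 3, "g2": (0.5,) * 3, "g3": (0.5,) * 3},
            genes=("g1", "g2", "g3"),
        )
        corr = ct.cluster_correlation(profiles)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        # c1 mean vector (1,2,3); c2 (2,4,6) = 2x -> r = 1
        assert corr.loc["c1", "c2"] == pytest.approx(1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_matches_brute_force(self, rng):
        values = rng.normal(size=(5, 3))  # 5 genes x 3 clusters
        profiles = make_profiles(
            {f"g{i}": tuple(values[i]) for i in range(5)},
            {f"g{i}": (0.5,) * 3 for i in range(5)},
            genes=tuple(f"g{i}" for i in range(5)),
        )
        corr = ct.cluster_correlation(profiles)
        for i in range(3):
            for j in range(3):
                x, y = values[:, i], values[:, j]
                xm, ym = x - x.mean(), y - y.mean()
                r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
                assert abs(corr.iloc[i, j] - (1.0 if i == j else r)) < 1e-12

    def test_zero_variance_profile_rejected(self):
        profiles = make_profiles(
            {"g1": (1, 1, 1), "g2": (1, 1, 2), "g3": (1, 1, 3)},
            {"g1": (0.5,) * 3, "g2": (0.5,) * 3, "g3": (0.5,) * 3},
            genes=("g1", "g2", "g3"),
        )
        with pytest.raises(ValueError, match="zero-variance"):
            ct.cluster_correlation(profiles)


class TestRankSumDeg:
    def test_identical_distributions_no_calls(self, rng):
        counts = rng.poisson(5.0, size=(40, 10))
        cells = [f"c{i}" for i in range(40)]
        m = CountMatrix(
            cells, [f"g{j}" for j in range(10)], sp.csr_matrix(counts),
            {c: "in" if i < 20 else "out" for i, c in enumerate(cells)},
        )
        df = ct.rank_sum_deg(m, "in")
        assert not df["significant"].any()

    def test_separated_gene_called(self, rng):
        counts = rng.poisson(2.0, size=(40, 5)) + 1
        counts[:20, 0] += 50
        cells = [f"c{i}" for i in range(40)]
        m = CountMatrix(
            cells, [f"g{j}" for j in range(5)], sp.csr_matrix(counts),
            {c: "in" if i < 20 else "out" for i, c in enumerate(cells)},
        )
        df = ct.rank_sum_deg(m, "in")
        top = df.iloc[0]
        assert top["gene"] == "g0" and top["significant"]

    def test_all_zero_gene_excluded(self, rng):
        counts = rng.poisson(2.0, size=(12, 3)) + 1
        counts[:, 2] = 0
        cells = [f"c{i}" for i in range(12)]
        m = CountMatrix(
            cells, ["g0", "g1", "gzero"], sp.csr_matrix(counts),
            {c: "in" if i < 6 else "out" for i, c in enumerate(cells)},
        )
        df = ct.rank_sum_deg(m, "in")
        assert "gzero" not in set(df["gene"])

    def test_unknown_cluster(self, labeled_matrix):
        with pytest.raises(ValueError, match="unknown cluster"):
            ct.rank_sum_deg(labeled_matrix, "nope")


class TestHypergeomEnrichment:
    def test_category_equals_background(self):
        bg = {f"g{i}" for i in range(30)}
        hits = {f"g{i}" for i in range(5)}
        k, p = ct.hypergeom_enrichment(hits, bg, bg)
        assert k == 5 and p == pytest.approx(1.0)

    def test_perfect_overlap_exact_p(self):
        bg = {f"g{i}" for i in range(20)}
        cat = {f"g{i}" for i in range(5)}
        k, p = ct.hypergeom_enrichment(cat, cat, bg)
        assert k == 5 and p == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_p_near_one(self):
        bg = {f"g{i}" for i in range(40)}
        hits = {f"g{i}" for i in range(10)}
        cat = {f"g{i}" for i in range(20, 30)}
        k, p = ct.hypergeom_enrichment(hits, cat, bg)
        assert k == 0 and p > 0.99

    def test_empty_background(self):
        with pytest.raises(ValueError, match="background"):
            ct.hypergeom_enrichment(set(), set(), set())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    counts=st.lists(
        st.integers(min_value=0, max_value=20), min_size=6, max_size=6
    )
)
def test_hypergeom_between_zero_and_one(counts):
    n_bg, n_cat, n_hit, k = 30, counts[0], counts[1], 0
    bg = {f"g{i}" for i in range(n_bg)}
    cat = set(list(bg)[: n_cat])
    hit = set(list(bg)[: n_hit])
    _, p = ct.hypergeom_enrichment(hit, cat, bg)
    assert 0.0 <= p <= 1.0
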