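"""Presence thresholding, clade weights, exact tree search vs enumeration oracle."""

import itertools
import re

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticophylo.cohort_io import SampleVariantSet
from corticophylo.pti import (
    PhylogenyInference,
    PtiConfig,
    ScoredTree,
    _all_topologies,
    best_tree,
    characterize_clades,
    clade_weight,
    enumerate_trees_oracle,
    presence_from_counts,
    presence_from_membership,
    to_newick,
)

from conftest import make_variant, random_presence


def _strip_support(newick: str) -> str:
    return re.sub(r"\)\d+", ")", newick)


class TestPresenceFromCounts:
    def _profiles(self, vafs):
        out = []
        for sid, entries in vafs.items():
            recs = [
                make_variant(v, mut=int(round(f * 100)), refr=100 - int(round(f * 100)))
                for v, f in entries.items()
            ]
            out.append(SampleVariantSet(sid, recs))
        return out

    def test_threshold_boundary_is_inclusive(self):
        profiles = self._profiles(
            {"a": {"v1": 0.05, "v2": 0.04}, "b": {"v1": 0.5}}
        )
        m = presence_from_counts(profiles, PtiConfig(af_threshold=0.05))
        assert "v1" in m.variants
        assert "v2" not in m.variants  # 0.04 fails, present nowhere, dropped

    def test_zero_threshold_is_raw_occurrence(self):
        profiles = self._profiles({"a": {"v1": 0.01}, "b": {"v2": 0.9}})
        m = presence_from_counts(profiles, PtiConfig(af_threshold=0.0))
        assert set(m.variants) == {"v1", "v2"}

    def test_records_without_counts_always_present(self):
        from corticophylo.cohort_io import VariantRecord

        profiles = [
            SampleVariantSet("a", [VariantRecord("v1")]),
            SampleVariantSet("b", [make_variant("v2")]),
        ]
        m = presence_from_counts(profiles, PtiConfig(af_threshold=0.99))
        assert "v1" in m.variants

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            presence_from_counts(self._profiles({"a": {"v1": 0.5}}))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_presence(self, seed):
        rng = np.random.default_rng(seed)
        profiles = []
        for i in range(4):
            recs = []
            for j in range(8):
                if rng.random() < 0.7:
                    mut = int(rng.integers(0, 30))
                    recs.append(make_variant(f"v{j}", mut=mut, refr=100 - mut))
            profiles.append(SampleVariantSet(f"s{i}", recs))
        lo = presence_from_counts(profiles, PtiConfig(af_threshold=0.02))
        hi = presence_from_counts(profiles, PtiConfig(af_threshold=0.10))
        lo_calls = {
            (s, v) for s in lo.samples for v in lo.variants
            if lo.present[lo.samples.index(s), lo.variants.index(v)]
        }
        hi_calls = {
            (s, v) for s in hi.samples for v in hi.variants
            if hi.present[hi.samples.index(s), hi.variants.index(v)]
        }
        assert hi_calls <= lo_calls


class TestCladeWeight:
    def test_trunk_variant_counts_for_full_set_only(self, perfect_phylogeny_matrix):
        m = perfect_phylogeny_matrix
        assert clade_weight(m, {"s1", "s2", "s3", "s4"}) == 2
        assert clade_weight(m, {"s1"}) == 1
        # a variant carried by {s1, s2} contributes nothing to {s1}
        assert clade_weight(m, {"s1", "s2"}) == 1

    def test_empty_clade_rejected(self, perfect_phylogeny_matrix):
        with pytest.raises(ValueError):
            clade_weight(perfect_phylogeny_matrix, set())

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_partition_total_variant_count(self, seed):
        rng = np.random.default_rng(seed)
        m = random_presence(rng, 4, 12)
        total = sum(
            clade_weight(m, set(c))
            for r in range(1, 5)
            for c in itertools.combinations(m.samples, r)
        )
        assert total == m.n_variants


class TestOracle:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_topology_counts_double_factorial(self, n, expected):
        assert len(_all_topologies(tuple(f"s{i}" for i in range(n)))) == expected

    def test_oracle_rejects_large_n(self):
        m = presence_from_membership(
            np.ones((7, 1), bool),
            samples=[f"s{i}" for i in range(7)], variants=["v"],
        )
        with pytest.raises(ValueError):
            enumerate_trees_oracle(m)


class TestBestTree:
    def test_two_samples_single_topology(self):
        m = presence_from_membership(
            {"a": {"t": True, "pa": True}, "b": {"t": True, "pb": True}}
        )
        t = best_tree(m)
        assert t.score == 3
        assert t.root.clade_support == 1
        assert to_newick(t) == "(a,b)1;"

    def test_perfect_phylogeny_attains_upper_bound(self, perfect_phylogeny_matrix):
        t = best_tree(perfect_phylogeny_matrix)
        assert t.score == perfect_phylogeny_matrix.n_variants
        assert _strip_support(to_newick(t)) == "((s1,s2),(s3,s4));"
        assert t.incompatible_variants == []
        oracle_best, _ = enumerate_trees_oracle(perfect_phylogeny_matrix)
        assert oracle_best == t.score

    def test_homoplasy_reported_incompatible(self):
        # 2 variants on {s2,s3}, 1 on {s1,s2}: the latter fits no clade of the optimum
        m = presence_from_membership(
            {
                "s1": {"x": True},
                "s2": {"a": True, "b": True, "x": True},
                "s3": {"a": True, "b": True},
            }
        )
        t = best_tree(m)
        oracle_best, _ = enumerate_trees_oracle(m)
        assert t.score == oracle_best == 2
        assert _strip_support(to_newick(t)) == "(s1,(s2,s3));"
        assert t.incompatible_variants == ["x"]

    @pytest.mark.parametrize("n", [3, 4, 5])
    @pytest.mark.filterwarnings("ignore:samples with no variants")
    def test_matches_enumeration_oracle_on_random_matrices(self, n):
        rng = np.random.default_rng(42 + n)
        for _ in range(30):
            m = random_presence(rng, n, int(rng.integers(3, 15)))
            t = best_tree(m)
            oracle_best, _ = enumerate_trees_oracle(m)
            assert t.score == oracle_best
            assert t.score <= m.n_variants

    def test_score_upper_bound_equality_iff_laminar(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = random_presence(rng, 4, 10)
            t = best_tree(m)
            carriers = [frozenset(
                s for s, p in zip(m.samples, m.present[:, j]) if p
            ) for j in range(m.n_variants)]
            laminar = all(
                a <= b or b <= a or not (a & b)
                for a in carriers for b in carriers
            )
            assert (t.score == m.n_variants) == laminar

    def test_determinism_under_input_permutation(self):
        rng = np.random.default_rng(3)
        arr = rng.random((5, 10)) < 0.5
        arr[:, ~arr.any(axis=0)] = True
        samples = [f"s{i}" for i in range(5)]
        variants = [f"v{j}" for j in range(10)]
        m1 = presence_from_membership(arr, samples=samples, variants=variants)
        perm = rng.permutation(5)
        m2 = presence_from_membership(
            arr[perm], samples=[samples[i] for i in perm], variants=variants
        )
        assert to_newick(best_tree(m1)) == to_newick(best_tree(m2))

    def test_too_many_samples_advises_filtering(self):
        m = presence_from_membership(
            np.ones((4, 2), bool),
            samples=[f"s{i}" for i in range(4)], variants=["v1", "v2"],
        )
        with pytest.raises(ValueError, match="threshold"):
            best_tree(m, PtiConfig(max_exhaustive_n=3))

    def test_zero_variant_sample_kept_as_leaf_with_warning(self):
        arr = np.array([[True, True], [True, False], [False, False]]).T
        # samples x variants: build explicitly
        arr = np.array([[True, True], [True, True], [False, False]])
        m = presence_from_membership(
            arr, samples=["a", "b", "c"], variants=["v1", "v2"]
        )
        with pytest.warns(UserWarning, match="no variants"):
            t = best_tree(m)
        assert t.root.clade == frozenset({"a", "b", "c"})


class TestCladeCharacterization:
    def test_genes_attach_to_their_clade(self):
        m = presence_from_membership(
            {
                "s1": {"v1": True, "v2": True},
                "s2": {"v1": True, "v2": True},
                "s3": {"v1": True},
            },
            genes=None,
        )
        m.genes = ["MSH3", "ATF7IP"]  # v1 trunk-like, v2 on {s1,s2}
        t = best_tree(m)
        labels = characterize_clades(t, m)
        assert labels[frozenset({"s1", "s2", "s3"})] == ["MSH3"]
        assert labels[frozenset({"s1", "s2"})] == ["ATF7IP"]

    def test_trunk_labels_sorted(self):
        m = presence_from_membership(
            {"a": {"v1": True, "v2": True}, "b": {"v1": True, "v2": True}}
        )
        m.genes = ["TP53", "MSH3"]
        labels = characterize_clades(best_tree(m), m)
        assert labels[frozenset({"a", "b"})] == ["MSH3", "TP53"]

    def test_incompatible_variants_label_no_clade(self):
        m = presence_from_membership(
            {
                "s1": {"x": True},
                "s2": {"a": True, "x": True},
                "s3": {"a": True},
            }
        )
        m.genes = ["GOOD", "BAD"]  # a -> GOOD, x -> BAD
        m.genes = [
            {"a": "GOOD", "x": "BAD"}[v] for v in m.variants
        ]
        t = best_tree(m)
        labels = characterize_clades(t, m)
        flat = {g for gs in labels.values() for g in gs}
        incompat_genes = {
            dict(zip(m.variants, m.genes))[v] for v in t.incompatible_variants
        }
        assert not (flat & incompat_genes)


class TestNewick:
    def test_round_trip_through_dendropy(self, perfect_phylogeny_matrix):
        t = best_tree(perfect_phylogeny_matrix)
        nwk = to_newick(t)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == {"s1", "s2", "s3", "s4"}
        # bipartition structure preserved
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in tree.preorder_node_iter()
        }
        assert frozenset({"s1", "s2"}) in clades
        assert frozenset({"s3", "s4"}) in clades

    def test_collapse_zero_support_flag(self):
        m = presence_from_membership(
            {"a": {"v": True}, "b": {"v": True}, "c": {"v": True}}
        )
        t = best_tree(m)
        assert ")0" not in to_newick(t, collapse_zero_support=True)


class TestEstimatorFacade:
    def test_fit_sets_trailing_underscore_attributes(self, perfect_phylogeny_matrix):
        est = PhylogenyInference().fit(perfect_phylogeny_matrix)
        assert est.score_ == perfect_phylogeny_matrix.n_variants
        assert est.newick_.endswith(";")
        assert est.incompatible_variants_ == []

    def test_get_set_params_round_trip(self):
        est = PhylogenyInference(af_threshold=0.1)
        assert est.get_params()["af_threshold"] == 0.1
        est.set_params(af_threshold=0.2, tie_break="report_all")
        assert est.get_params()["af_threshold"] == 0.2
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_accepts_boolean_array(self):
        arr = np.array([[True, True, False], [True, False, True]])
        est = PhylogenyInference().fit(arr, sample_ids=["a", "b"])
        assert est.tree_.root.clade == frozenset({"a", "b"})
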