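"""Within-pathway co-expression clusters: C/K/O detection and classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import diffcoex as dc
from diffcoex import clusters

from test_expression import make_design, make_matrix


def block_matrix(block_sizes, n_samples=8, noise=0.01, seed=0):
    """Genes in the same block follow one shared profile (within-block r ≈ 1)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b, size in enumerate(block_sizes):
        profile = rng.standard_normal(n_samples) * 2
        for _ in range(size):
            rows.append(profile + rng.normal(0, noise, n_samples))
    return make_matrix(np.array(rows), scale="log2ratio")


def two_cond_design(n_samples):
    half = n_samples // 2
    return make_design(half, n_samples - half)


class TestClusterCondition:
    def test_two_perfect_blocks_recovered_exactly(self):
        m = block_matrix([10, 8], n_samples=8, noise=1e-6)
        design = dc.SampleDesign({f"s{j}": "control" for j in range(8)})
        out = clusters.cluster_condition(
            m, set(m.gene_ids), "control", design, min_avg_r=0.65, min_size=5
        )
        assert [c.size for c in out] == [10, 8]
        assert out[0].cluster_id == "C1" and out[1].cluster_id == "C2"
        for c in out:
            assert c.avg_r_control == pytest.approx(1.0, abs=1e-6)
        assert out[0].genes == frozenset(f"g{i}" for i in range(10))

    def test_identical_profiles_form_single_cluster(self):
        m = block_matrix([12], n_samples=6, noise=1e-9)
        design = dc.SampleDesign({f"s{j}": "knockdown" for j in range(6)})
        out = clusters.cluster_condition(m, set(m.gene_ids), "knockdown", design)
        assert len(out) == 1
        assert out[0].cluster_id == "K1"
        assert out[0].size == 12

    def test_pure_noise_yields_no_clusters(self, rng):
        m = make_matrix(rng.standard_normal((25, 12)), scale="log2ratio")
        design = dc.SampleDesign({f"s{j}": "control" for j in range(12)})
        out = clusters.cluster_condition(m, set(m.gene_ids), "control", design)
        assert out == []

    def test_small_gene_set_warns_empty(self):
        m = block_matrix([3], n_samples=6)
        design = dc.SampleDesign({f"s{j}": "control" for j in range(6)})
        with pytest.warns(UserWarning):
            out = clusters.cluster_condition(m, set(m.gene_ids), "control", design)
        assert out == []

    def test_average_r_matches_brute_force_pair_mean(self):
        m = block_matrix([8, 6], n_samples=10, noise=0.3, seed=3)
        design = dc.SampleDesign({f"s{j}": "control" for j in range(10)})
        out = clusters.cluster_condition(
            m, set(m.gene_ids), "control", design, min_avg_r=0.3, min_size=5
        )
        assert out
        vals = m.values
        for c in out:
            genes = sorted(c.genes)
            rs = [
                np.corrcoef(vals.loc[a], vals.loc[b])[0, 1]
                for i, a in enumerate(genes)
                for b in genes[i + 1:]
            ]
            assert c.avg_r_control == pytest.approx(np.mean(rs), abs=1e-9)


def make_cluster(cid, cond, genes):
    return clusters.CoexpressionCluster(cid, cond, frozenset(genes))


class TestFindOverlapClusters:
    def test_intersection_of_size_five_reported(self):
        c1 = make_cluster("C1", "control", "abcdef")
        k1 = make_cluster("K1", "knockdown", "abcdeg")
        out = clusters.find_overlap_clusters([c1], [k1], min_size=5)
        assert len(out) == 1
        assert out[0].cluster_id == "O1"
        assert out[0].genes == frozenset("abcde")
        assert out[0].source == ("C1", "K1")

    def test_disjoint_clusters_give_no_overlap(self):
        out = clusters.find_overlap_clusters(
            [make_cluster("C1", "control", "abcde")],
            [make_cluster("K1", "knockdown", "fghij")],
        )
        assert out == []

    def test_subset_case_returns_whole_subset(self):
        c1 = make_cluster("C1", "control", "abcde")
        k1 = make_cluster("K1", "knockdown", "abcdefgh")
        out = clusters.find_overlap_clusters([c1], [k1])
        assert out[0].genes == c1.genes

    def test_each_overlap_within_one_c_and_one_k(self, module_scenario):
        _, ratios, design, truth = module_scenario
        genes = set(truth.module_membership) | {f"g{i:05d}" for i in range(560, 580)}
        cl_c = clusters.cluster_condition(ratios, genes, "control", design)
        cl_k = clusters.cluster_condition(ratios, genes, "knockdown", design)
        ov = clusters.find_overlap_clusters(cl_c, cl_k, ratios, design)
        for o in ov:
            assert sum(o.genes <= c.genes for c in cl_c) == 1
            assert sum(o.genes <= k.genes for k in cl_k) == 1
            assert o.avg_r_control is not None and o.avg_r_knockdown is not None


class TestClassifyCoexpression:
    def test_definitions_on_toy_clusters(self):
        cl_c = [make_cluster("C1", "control", "abcde"), make_cluster("C2", "control", "xyzuv")]
        cl_k = [make_cluster("K1", "knockdown", "abcdef")]
        ov = clusters.find_overlap_clusters(cl_c, cl_k)
        labels = clusters.classify_coexpression("abcdexyzuvw", cl_c, cl_k, ov)
        assert labels["a"] == "conserved"      # in O1
        assert labels["x"] == "divergent"      # C2 only
        assert labels["w"] == "unclustered"
        # the three labels partition the gene set
        assert set(labels.index) == set("abcdexyzuvw")

    def test_planted_modules_classified_correctly(self, module_scenario):
        _, ratios, design, truth = module_scenario
        gene_set = set(truth.module_membership)
        cl_c = clusters.cluster_condition(ratios, gene_set, "control", design)
        cl_k = clusters.cluster_condition(ratios, gene_set, "knockdown", design)
        ov = clusters.find_overlap_clusters(cl_c, cl_k, ratios, design)
        labels = clusters.classify_coexpression(gene_set, cl_c, cl_k, ov)
        both = [g for g, m in truth.module_membership.items()
                if m in ("conserved_a", "conserved_b")]
        ctl_only = [g for g, m in truth.module_membership.items()
                    if m == "ctl_specific"]
        assert (labels[both] == "conserved").mean() >= 0.9
        assert (labels[ctl_only] == "divergent").mean() >= 0.9

    def test_conserved_modules_recovered_as_overlap_clusters(self, module_scenario):
        """Adjusted Rand index of planted conserved modules vs O clusters."""
        _, ratios, design, truth = module_scenario
        gene_set = sorted(set(truth.module_membership))
        cl_c = clusters.cluster_condition(ratios, gene_set, "control", design)
        cl_k = clusters.cluster_condition(ratios, gene_set, "knockdown", design)
        ov = clusters.find_overlap_clusters(cl_c, cl_k, ratios, design)
        true_labels = [
            truth.module_membership[g]
            if truth.module_membership[g] in ("conserved_a", "conserved_b")
            else "other"
            for g in gene_set
        ]
        pred = []
        for g in gene_set:
            hits = [o.cluster_id for o in ov if g in o.genes]
            pred.append(hits[0] if hits else "other")
        assert adjusted_rand_score(true_labels, pred) >= 0.8


class TestSummarizePathway:
    def test_de_split_counts(self):
        cl = make_cluster("C1", "control", [f"g{i}" for i in range(10)])
        de = pd.DataFrame(
            {
                "fold_change": [2.0, 1.6, 1.5, 1.8, 1.7, 1.2, 1.0, 1.1, 1.3, 1.4],
                "direction": ["up_in_control"] * 4 + ["up_in_knockdown"] + ["none"] * 5,
            },
            index=[f"g{i}" for i in range(10)],
        )
        out = clusters.summarize_pathway([cl], de)
        assert out.loc[0, "de_split"] == "4/1"
        assert out.loc[0, "n_de_under"] + out.loc[0, "n_de_over"] <= cl.size

    def test_no_de_genes_gives_zero_split(self):
        cl = make_cluster("K1", "knockdown", "abcde")
        de = pd.DataFrame(
            {"fold_change": [1.0] * 5, "direction": ["none"] * 5},
            index=list("abcde"),
        )
        out = clusters.summarize_pathway([cl], de)
        assert out.loc[0, "de_split"] == "0/0"
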