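import itertools

import numpy as np
import pandas as pd
import pytest

from subsetseq.evaluation import signature_recovery
from subsetseq.io import AnnotationTable, SampleTable
from subsetseq.linmod import ContrastTable
from subsetseq.normalize import NormalizedMatrix
from subsetseq.signatures import (
    biotype_subset,
    cluster_order,
    pca_top_variable,
    qpcr_delta_ct,
    row_zscores,
    spider_values,
    subset_signatures,
)

SUBSETS = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


def _norm_from(values, gene_ids, sample_ids):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        gene_ids, sample_ids, values, np.ones_like(values),
        np.ones(len(sample_ids)), np.full(len(sample_ids), 10_000),
    )


def _samples_one_per_subset():
    return SampleTable(
        pd.DataFrame(
            {"sample_id": list(SUBSETS), "subset": list(SUBSETS), "donor": ["d1"] * 6}
        )
    )


def _pairwise_from_rules(gene_ids, winners):
    """Synthetic pairwise tables: gene g 'wins' S vs T iff winners[g] == S."""
    tables = {}
    for a, b in itertools.combinations(SUBSETS, 2):
        rows = []
        for g in gene_ids:
            if winners.get(g) == a:
                rows.append((g, 2.0, 5.0, 1e-6, 1e-5))
            elif winners.get(g) == b:
                rows.append((g, -2.0, -5.0, 1e-6, 1e-5))
            else:
                rows.append((g, 0.0, 0.1, 0.9, 0.95))
        tables[(a, b)] = ContrastTable(
            f"{a}_vs_{b}",
            pd.DataFrame(rows, columns=["gene_id", "log2_fc", "t", "p", "adj_p"]),
        )
    return tables


class TestSubsetSignatures:
    def test_conjunction_assigns_winners(self):
        gene_ids = ["gA", "gB", "gC"]
        winners = {"gA": "ILC2", "gB": "ILCP"}
        tables = _pairwise_from_rules(gene_ids, winners)
        norm = _norm_from(np.zeros((3, 6)), gene_ids, list(SUBSETS))
        sig = subset_signatures(tables, list(SUBSETS), norm, _samples_one_per_subset())
        assert sig.members["ILC2"] == ["gA"]
        assert sig.members["ILCP"] == ["gB"]
        assert all(not sig.members[s] for s in ("ILC1", "Th1", "Th2", "Th17"))

    def test_gene_up_in_four_but_flat_in_fifth_excluded(self):
        gene_ids = ["gA"]
        tables = _pairwise_from_rules(gene_ids, {"gA": "ILC2"})
        # break exactly one of ILC2's five comparisons
        flat = tables[("ILC2", "Th17")].frame.copy()
        flat.loc[:, ["log2_fc", "t", "p", "adj_p"]] = [0.0, 0.1, 0.9, 0.95]
        tables[("ILC2", "Th17")] = ContrastTable("ILC2_vs_Th17", flat)
        norm = _norm_from(np.zeros((1, 6)), gene_ids, list(SUBSETS))
        sig = subset_signatures(tables, list(SUBSETS), norm, _samples_one_per_subset())
        assert sig.members["ILC2"] == []

    def test_no_significant_genes_all_empty(self):
        gene_ids = ["gA", "gB"]
        tables = _pairwise_from_rules(gene_ids, {})
        norm = _norm_from(np.zeros((2, 6)), gene_ids, list(SUBSETS))
        sig = subset_signatures(tables, list(SUBSETS), norm, _samples_one_per_subset())
        assert all(not g for g in sig.members.values())

    def test_missing_pair_rejected(self):
        gene_ids = ["gA"]
        tables = _pairwise_from_rules(gene_ids, {})
        del tables[("ILC1", "Th2")]
        norm = _norm_from(np.zeros((1, 6)), gene_ids, list(SUBSETS))
        with pytest.raises(ValueError, match="ILC1.*Th2"):
            subset_signatures(tables, list(SUBSETS), norm, _samples_one_per_subset())

    def test_planted_recovery_correct_and_disjoint(self):
        rates = signature_recovery(n_seeds=3, seed=77)
        assert rates["precision"] == 1.0
        assert rates["spider_diagonal_rate"] == 1.0


class TestSpiderValues:
    def test_constant_gene_constant_row(self):
        norm = _norm_from(np.full((1, 6), 2.0), ["gA"], list(SUBSETS))
        spider = spider_values({"ILC1": ["gA"]}, norm, _samples_one_per_subset(), list(SUBSETS))
        assert (spider.loc["ILC1"] == 2.0).all()

    def test_empty_signature_marked_missing(self):
        norm = _norm_from(np.zeros((1, 6)), ["gA"], list(SUBSETS))
        spider = spider_values(
            {"ILC1": [], "ILC2": ["gA"]}, norm, _samples_one_per_subset(), list(SUBSETS)
        )
        assert spider.loc["ILC1"].isna().all()
        assert spider.loc["ILC2"].notna().all()

    def test_values_in_plausible_log_cpm_range(self, fitted_bundle):
        # spreads comparable to log2-cpm axes of real spider charts
        spider = spider_values(
            {"all": fitted_bundle["norm"].gene_ids[:50]},
            fitted_bundle["norm"],
            fitted_bundle["samples"],
            list(SUBSETS),
        )
        assert spider.to_numpy().min() > -10
        assert spider.to_numpy().max() < 20


class TestZScoresAndClustering:
    def test_three_point_row(self):
        assert np.allclose(row_zscores(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zero(self):
        assert (row_zscores(np.array([[5.0, 5.0, 5.0]])) == 0).all()

    def test_row_means_and_sds(self, fitted_bundle):
        z = row_zscores(fitted_bundle["norm"].log_cpm[:100])
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        sds = z.std(axis=1, ddof=1)
        assert np.all((np.abs(sds - 1) < 1e-10) | (sds == 0))

    def test_two_cluster_toy_recovered(self):
        pts = np.array(
            [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [5.0, 5.0], [5.1, 5.0], [5.0, 5.1]]
        )
        order = cluster_order(pts)
        first3 = set(order[:3])
        assert first3 in ({0, 1, 2}, {3, 4, 5})

    def test_merge_heights_match_brute_force_complete_linkage(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 3))
        heights = sorted(linkage(pts, method="complete")[:, 2])
        # brute-force agglomeration: repeatedly merge the closest pair of
        # clusters under max-distance linkage
        clusters = [[i] for i in range(6)]
        dist = lambda a, b: max(
            np.linalg.norm(pts[i] - pts[j]) for i in a for j in b
        )
        got = []
        while len(clusters) > 1:
            best = min(
                ((i, j) for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
                key=lambda ij: dist(clusters[ij[0]], clusters[ij[1]]),
            )
            i, j = best
            got.append(dist(clusters[i], clusters[j]))
            merged = clusters[i] + clusters[j]
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        assert np.allclose(sorted(got), heights, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_order(np.ones((1, 3)))


class TestPca:
    def test_variance_fractions_sum_to_one_nonincreasing(self, fitted_bundle):
        pca = pca_top_variable(fitted_bundle["norm"], n_top=200)
        assert pca.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(pca.variance_fraction) <= 1e-12).all()
        assert (pca.variance_fraction >= 0).all()

    def test_planted_lineage_separates_on_pc1(self, fitted_bundle):
        from sklearn.metrics import silhouette_score

        pca = pca_top_variable(fitted_bundle["norm"], n_top=100)
        samples = fitted_bundle["samples"]
        lineage = [
            "ILC" if samples.subset_of(s).startswith("ILC") else "Th"
            for s in pca.scores.index
        ]
        score = silhouette_score(pca.scores[["PC1"]].to_numpy(), lineage)
        assert score > 0.8

    def test_gene_order_invariance(self, fitted_bundle):
        norm = fitted_bundle["norm"]
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(norm.gene_ids))
        shuffled = NormalizedMatrix(
            [norm.gene_ids[i] for i in perm], norm.sample_ids,
            norm.log_cpm[perm], norm.weights[perm], norm.tmm_factors, norm.lib_sizes,
        )
        a = pca_top_variable(norm, n_top=100)
        b = pca_top_variable(shuffled, n_top=100)
        assert np.allclose(a.variance_fraction, b.variance_fraction, atol=1e-10)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-8)

    def test_too_few_genes_rejected(self, fitted_bundle):
        with pytest.raises(ValueError):
            pca_top_variable(fitted_bundle["norm"], n_top=1)


class TestBiotypeSubset:
    def test_partition_identity(self, fitted_bundle):
        table = fitted_bundle["pairwise"][("ILC2", "Th2")]
        annotation = fitted_bundle["annotation"]
        labels = sorted(set(annotation.frame["biotype"]))
        parts = [biotype_subset(table, annotation, b).frame for b in labels]
        union = pd.concat(parts).sort_values("gene_id").reset_index(drop=True)
        full = table.frame.sort_values("gene_id").reset_index(drop=True)
        assert union.equals(full)

    def test_no_lncrnas_empty_table(self, fitted_bundle):
        table = fitted_bundle["pairwise"][("ILC2", "Th2")]
        ann = AnnotationTable(
            pd.DataFrame(
                {
                    "gene_id": table.frame["gene_id"],
                    "symbol": table.frame["gene_id"],
                    "biotype": "protein_coding",
                }
            )
        )
        assert biotype_subset(table, ann, "lncRNA").frame.empty

    def test_unknown_biotype_lists_available(self, fitted_bundle):
        table = fitted_bundle["pairwise"][("ILC2", "Th2")]
        with pytest.raises(ValueError, match="protein_coding"):
            biotype_subset(table, fitted_bundle["annotation"], "miRNA")

    def test_adjusted_p_not_recomputed(self, fitted_bundle):
        table = fitted_bundle["pairwise"][("ILC2", "Th2")]
        sub = biotype_subset(table, fitted_bundle["annotation"], "lncRNA")
        merged = sub.frame.merge(table.frame, on="gene_id", suffixes=("_sub", "_full"))
        assert np.allclose(merged["adj_p_sub"], merged["adj_p_full"])

    def test_planted_lncrnas_recovered(self):
        # large planted effects on lncRNA-labelled genes are found significant
        from subsetseq.linmod import build_design, fit_models, test_contrast
        from subsetseq.normalize import filter_low_expression, log_cpm_and_weights, tmm_factors
        from subsetseq.simulate import SimulationConfig, simulate_counts

        cfg = SimulationConfig(
            n_genes=1000, effect_size_log2=4.0, lncrna_fraction=0.3, seed=23
        )
        counts, samples, annotation, truth = simulate_counts(cfg)
        filt = filter_low_expression(counts)
        design = build_design(samples, "subset")
        norm = log_cpm_and_weights(filt, tmm_factors(filt), design.matrix)
        fit = fit_models(norm, design)
        table = test_contrast(fit, design.contrast({"ILC2": 1, "Th2": -1}), "ILC2_vs_Th2")
        lnc = biotype_subset(table, annotation, "lncRNA")
        eff = truth.effects.loc[lnc.frame["gene_id"]]
        truly = (eff["ILC2"] != eff["Th2"]).to_numpy()
        assert truly.sum() >= 10
        recovered = (lnc.frame["adj_p"] < 0.05).to_numpy()[truly].mean()
        assert recovered >= 0.75


class TestQpcr:
    def test_closed_form(self):
        assert qpcr_delta_ct([25, 25, 25], [20, 20, 20]) == pytest.approx(0.03125)

    def test_equal_means_one(self):
        assert qpcr_delta_ct([22, 23, 24], [23, 23, 23]) == pytest.approx(1.0)

    def test_one_cycle_decrease_doubles(self):
        lo = qpcr_delta_ct([24, 24, 24], [20, 20, 20])
        hi = qpcr_delta_ct([23, 23, 23], [20, 20, 20])
        assert hi == pytest.approx(2 * lo)

    @pytest.mark.parametrize("bad", [[0, 25, 25], [46, 25, 25], [np.nan, 25, 25], []])
    def test_invalid_ct_rejected(self, bad):
        with pytest.raises(ValueError):
            qpcr_delta_ct(bad, [20, 20, 20])
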