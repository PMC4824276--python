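"""Coalescent simulator: analytic calibration, filters, hybrid merge."""

import numpy as np
import pytest

from hetscan.matrices import GenotypeMatrix, LocusMatrix
from hetscan.simulate import (
    HYBRID_SCENARIOS,
    HybridSpec,
    HybridTruth,
    LocusBudgetError,
    SpeciesTreeModel,
    make_hybrid_dataset,
    simulate_aflp_dataset,
    simulate_gene_tree,
    simulate_gene_trees,
    simulate_snp_dataset,
    single_population_model,
    tropheini_like_model,
)


class TestGeneTrees:
    def test_structure_invariants(self):
        model = tropheini_like_model(theta=0.0005)
        gt = simulate_gene_tree(model, seed=1)
        n = gt.n_tips
        assert n == 19 * 4
        # exactly n - 1 coalescent events, every non-root node has a parent
        assert len(gt.parent) == 2 * n - 1
        assert gt.parent[-1] == -1
        assert (gt.parent[:-1] >= n).all() or n == 1
        # times increase along ancestry
        p = gt.parent[:-1]
        assert (gt.time[p] > gt.time[:-1] - 1e-18).all()
        assert gt.total_length > 0

    def test_within_population_divergence_matches_theta(self):
        """E[pairwise divergence] = theta for two haplotypes in one
        population (2 * T2, T2 ~ Exp(2/theta))."""
        theta = 0.0005
        model = single_population_model(theta, n_haplotypes=2)
        trees = simulate_gene_trees(model, 4000, seed=3)
        div = np.array([t.pairwise_divergence(0, 1) for t in trees])
        se = theta / np.sqrt(len(div))  # sd(2*T2) = theta
        assert abs(div.mean() - theta) < 3 * se

    def test_between_taxon_divergence_two_t_plus_theta(self):
        """With instant within-taxon coalescence, cross-taxon divergence
        averages 2*t_split + theta_ancestral."""
        t_split, theta_anc = 1e-4, 5e-4
        model = SpeciesTreeModel(
            names=["A", "B", "anc"],
            parent=np.array([2, 2, -1]),
            tau=np.array([0.0, 0.0, t_split]),
            theta=np.array([1e-12, 1e-12, theta_anc]),
            samples_per_taxon=1,
        )
        trees = simulate_gene_trees(model, 4000, seed=9)
        div = np.array([t.pairwise_divergence(0, 2) for t in trees])
        expect = 2 * t_split + theta_anc
        se = theta_anc / np.sqrt(len(div))
        assert abs(div.mean() - expect) < 3 * se

    def test_tiny_theta_recovers_species_tree(self):
        """In the low-coalescent-noise limit the gene tree mirrors the
        species tree: r-q divergence < r-k < r-o in >= 99% of trees."""
        model = tropheini_like_model(theta=1e-12, samples_per_taxon=1)
        taxa = model.taxa
        i_r, i_q, i_k, i_o = (2 * taxa.index(t) for t in "rqko")
        trees = simulate_gene_trees(model, 300, seed=5)
        ok = 0
        for t in trees:
            drq = t.pairwise_divergence(i_r, i_q)
            drk = t.pairwise_divergence(i_r, i_k)
            dro = t.pairwise_divergence(i_r, i_o)
            ok += drq < drk < dro
        assert ok >= 297

    def test_newick_export_parses(self):
        import dendropy

        model = single_population_model(0.001, n_haplotypes=4)
        gt = simulate_gene_tree(model, seed=2)
        tree = dendropy.Tree.get(data=gt.to_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 4


class TestSNPDatasets:
    def test_every_locus_polymorphic(self):
        g = simulate_snp_dataset(tropheini_like_model(theta=0.0005), 150,
                                 seed=4)
        assert isinstance(g, GenotypeMatrix)
        assert g.n_loci == 150
        # >= 2 observed alleles per locus
        present = (g.counts.sum(axis=0) > 0)
        assert (present.sum(axis=1) >= 2).all()

    def test_budget_error_reports_yield(self):
        model = single_population_model(1e-12, n_haplotypes=8)
        with pytest.raises(LocusBudgetError, match="0 polymorphic"):
            simulate_snp_dataset(model, 10, seed=1, raw_budget=500)

    def test_polymorphic_fraction_increases_with_theta(self):
        from hetscan import _coalescent as _kern

        fracs = []
        n = 12_000
        for theta in (0.00001, 0.0005):
            model = tropheini_like_model(theta=theta)
            arrays = model._kernel_arrays()
            n_tips = arrays[-1]
            out = np.empty((n, n_tips), dtype=np.int8)
            poly = np.empty(n, dtype=np.bool_)
            _kern.snp_batch(123, n, *arrays[:-1], n_tips, out, poly)
            fracs.append(poly.mean())
        # larger theta -> longer gene trees -> more polymorphic loci
        assert fracs[1] > fracs[0] > 0

    def test_seed_determinism(self):
        model = tropheini_like_model(theta=0.0005)
        g1 = simulate_snp_dataset(model, 60, seed=42)
        g2 = simulate_snp_dataset(model, 60, seed=42)
        np.testing.assert_array_equal(g1.counts, g2.counts)


class TestAFLPDatasets:
    def test_binary_polymorphic_output(self):
        m = simulate_aflp_dataset(tropheini_like_model(theta=0.0005), 120,
                                  seed=6)
        assert isinstance(m, LocusMatrix)
        assert set(np.unique(m.values)) <= {0, 1}
        assert (m.values.min(axis=0) == 0).all()
        assert (m.values.max(axis=0) == 1).all()

    def test_no_mutation_means_no_polymorphism(self):
        model = single_population_model(1e-12, n_haplotypes=8)
        with pytest.raises(LocusBudgetError):
            simulate_aflp_dataset(model, 10, seed=1, raw_budget=500)

    def test_band_loss_rate_matches_ten_site_target(self):
        """Between two haplotypes split t ago, P(band states differ) is
        close to 2 * (1 - e^(-10 * t)) for small t (each lineage loses the
        band roughly independently at the 10-site mutation rate)."""
        from hetscan import _coalescent as _kern

        t = 2e-3
        model = SpeciesTreeModel(
            names=["A", "B", "anc"],
            parent=np.array([2, 2, -1]),
            tau=np.array([0.0, 0.0, t]),
            theta=np.array([1e-12, 1e-12, 1e-12]),
            samples_per_taxon=1,
        )
        arrays = model._kernel_arrays()
        n_tips = arrays[-1]
        n = 40_000
        out = np.empty((n, n_tips // 2), dtype=np.int8)
        poly = np.empty(n, dtype=np.bool_)
        _kern.aflp_batch(7, n, *arrays[:-1], n_tips, 10, out, poly)
        # one site per haplotype path of length ~t mutates away from the
        # ancestral state with prob ~ (3/4)(1 - e^{-4/3 * t}) ~= t; with 10
        # sites and both branches, P(band difference) ~= 2 * p * (1 - p)
        p_loss = 1 - np.exp(-10 * t)
        expect = 2 * p_loss * (1 - p_loss)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(poly.mean() - expect) < 4 * se


class TestHybridDatasets:
    def test_equal_contribution_symmetry(self):
        """The hybrid is equidistant from both parents on average (paired
        over merged replicates)."""
        from hetscan.distances import allele_sharing_distance

        model = tropheini_like_model(theta=0.0005)
        diffs = []
        for seed in (1, 2, 3):
            mx, truth = make_hybrid_dataset(
                model, HYBRID_SCENARIOS["l_x_s"], 1000, seed=seed
            )
            d = allele_sharing_distance(mx)
            ids = mx.sample_ids

            def mean_d(g1, g2):
                i1 = [i for i, s in enumerate(ids) if s.endswith("_" + g1)]
                i2 = [i for i, s in enumerate(ids) if s.endswith("_" + g2)]
                return np.mean([d.values[i, j] for i in i1 for j in i2])

            diffs.append(mean_d("hyb", "l") - mean_d("hyb", "s"))
        assert abs(np.mean(diffs)) < 0.01

    def test_truth_record_and_roundtrip(self, tmp_path):
        model = tropheini_like_model(theta=0.0005)
        _, truth = make_hybrid_dataset(model, HYBRID_SCENARIOS["rq_x_lmn"],
                                       100, seed=1)
        assert truth.parent_taxa == (("q", "r"), ("l", "m", "n"))
        p = tmp_path / "truth.tsv"
        truth.to_tsv(p)
        back = HybridTruth.from_tsv(p)
        assert back == truth

    def test_odd_locus_count_rounded_up(self):
        model = tropheini_like_model(theta=0.0005)
        with pytest.warns(UserWarning, match="rounded up"):
            mx, _ = make_hybrid_dataset(model, HYBRID_SCENARIOS["l_x_s"],
                                        51, seed=1)
        assert mx.n_loci == 52

    def test_tau_h_outside_branch_rejected(self):
        model = tropheini_like_model(theta=0.0005)
        with pytest.raises(ValueError, match="tau_h"):
            model.with_hybrid("l", "hyb", 0.001)


class TestModelConstruction:
    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau"):
            SpeciesTreeModel(
                names=["A", "B", "anc"],
                parent=np.array([2, 2, -1]),
                tau=np.array([0.0, 0.1, 0.05]),
                theta=np.array([1e-4] * 3),
            )

    def test_newick_parsing_and_grouping(self):
        model = tropheini_like_model()
        assert len(model.taxa) == 19
        assert model.outgroup == "out"
        g = model.grouping()
        assert len(g.ingroup_groups()) == 18
        assert g.outgroup == "out"

    def test_mrca_lookup(self):
        model = tropheini_like_model()
        v = model.node_by(("r", "q"))
        assert set(model.descendant_taxa()[v]) == {"r", "q"}
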