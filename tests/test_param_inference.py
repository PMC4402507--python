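import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdriver.deregulation import DeregulationProfile
from netdriver.io_model import MutationMatrix, ParameterSet
from netdriver.param_inference import (
    ParameterGrid,
    frequency_spectrum,
    infer_parameters,
    js_divergence,
    normalize_spectrum,
    permute_gene_labels,
)
from netdriver.synthetic import generate_cohort, generate_network

from conftest import make_mutations


class TestJSDivergence:
    def test_identical_vectors_give_zero(self):
        assert js_divergence([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_point_mass_vs_uniform(self):
        # closed form: H((0.75, 0.25)) - (H(P) + H(Q)) / 2 = 0.8112781 - 0.5
        assert js_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.3112781, abs=1e-6)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            js_divergence([1.1, -0.1], [0.5, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        p = rng.random(n)
        q = rng.random(n)
        p, q = p / p.sum(), q / q.sum()
        d = js_divergence(p, q)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(js_divergence(q, p), abs=1e-12)


class TestFrequencySpectrum:
    def test_counts_cover_all_network_genes(self, chain_network):
        spec = frequency_spectrum({"B": 0.5, "Z": 1.0}, n_samples=4, network=chain_network)
        assert spec.sum() == 3  # A, B, C; Z is outside the network
        assert spec[2] == 1  # B explained in 2 of 4 samples
        assert spec[0] == 2  # A and C never explained
        assert normalize_spectrum(spec).sum() == pytest.approx(1.0)


class TestPermuteGeneLabels:
    def _profiles(self):
        return {
            "S1": DeregulationProfile("S1", {"G1": 2.0, "G2": -3.0}),
            "S2": DeregulationProfile("S2", {"G2": 2.5}),
        }

    def test_counts_and_frequencies_preserved(self):
        genes = [f"G{i}" for i in range(10)]
        mut = make_mutations(
            [("G1", "S1"), ("G2", "S1"), ("G3", "S2")], genes, ["S1", "S2"]
        )
        pm, pp = permute_gene_labels(mut, self._profiles(), seed=5, expression_genes=genes)
        # per-sample counts are untouched
        assert pm.data.sum(axis=0).tolist() == mut.data.sum(axis=0).tolist()
        # per-gene cross-sample frequencies travel with the permuted labels
        assert sorted(pm.data.sum(axis=1)) == sorted(mut.data.sum(axis=1))
        for s in pp:
            assert pp[s].n_dereg == self._profiles()[s].n_dereg
            assert sorted(pp[s].dereg.values()) == sorted(self._profiles()[s].dereg.values())

    def test_deterministic_and_seed_sensitive(self):
        genes = [f"G{i}" for i in range(20)]
        mut = make_mutations([(f"G{i}", "S1") for i in range(5)], genes, ["S1"])
        a1, _ = permute_gene_labels(mut, self._profiles(), seed=1, expression_genes=genes)
        a2, _ = permute_gene_labels(mut, self._profiles(), seed=1, expression_genes=genes)
        b, _ = permute_gene_labels(mut, self._profiles(), seed=2, expression_genes=genes)
        assert a1.mutated_genes("S1") == a2.mutated_genes("S1")
        assert a1.mutated_genes("S1") != b.mutated_genes("S1")


class TestInferParameters:
    @pytest.fixture(scope="class")
    def clean_cohort(self):
        # confounder-free planted cohort: radius-2 effects, no hotspots
        net = generate_network(n_genes=400, seed=21)
        sc = generate_cohort(
            net, n_samples=24, n_normals=16, seed=21,
            driver_pool_size=4, hotspot_passengers=0,
        )
        return net, sc

    def test_single_feasible_cell_is_returned(self, clean_cohort):
        net, sc = clean_cohort
        grid = ParameterGrid(L=(2,), D=(50,), F=(2.0,))
        res = infer_parameters(
            sc.cohort, net, grid=grid, n_random=2, seed=0, min_median_dereg=5
        )
        assert res.best == ParameterSet(L=2, D=50, F=2.0)

    def test_all_cells_infeasible_reports_medians(self, clean_cohort):
        net, sc = clean_cohort
        grid = ParameterGrid(L=(2,), D=(50,), F=(2.0,))
        with pytest.raises(ValueError, match="median"):
            infer_parameters(
                sc.cohort, net, grid=grid, n_random=2, seed=0,
                min_median_dereg=10**6,
            )

    def test_recovers_planted_path_length_within_one_step(self):
        # the generator perturbs radius-2 neighborhoods; inferred L should sit
        # within one grid step of 2 in the majority of replicates
        grid = ParameterGrid(L=(2, 4, 6), D=(50,), F=(1.0, 2.0, 3.0))
        hits = 0
        for seed in range(5):
            net = generate_network(n_genes=400, seed=seed)
            sc = generate_cohort(
                net, n_samples=24, n_normals=16, seed=seed,
                driver_pool_size=4, hotspot_passengers=0,
            )
            res = infer_parameters(
                sc.cohort, net, grid=grid, n_random=3, seed=seed,
                min_median_dereg=10, de_method="ttest",
            )
            hits += res.best.L in (2, 4)
        assert hits >= 3

    def test_planted_structure_scores_above_label_permuted_null(self, clean_cohort):
        net, sc = clean_cohort
        grid = ParameterGrid(L=(2,), D=(50,), F=(2.0,))
        real = infer_parameters(
            sc.cohort, net, grid=grid, n_random=3, seed=3, min_median_dereg=5,
            de_method="ttest",
        )
        # destroy the mutation-deregulation coupling and re-score
        from netdriver.io_model import Cohort

        rng = np.random.default_rng(3)
        genes = np.array(sc.mutations.genes)
        perm = dict(zip(genes, genes[rng.permutation(len(genes))]))
        shuffled = sc.mutations.data.copy()
        shuffled.index = [perm[g] for g in genes]
        null_cohort = Cohort(
            type(sc.mutations)(shuffled.sort_index()), sc.tumors, sc.normals
        )
        null = infer_parameters(
            null_cohort, net, grid=grid, n_random=3, seed=3, min_median_dereg=5,
            de_method="ttest",
        )
        key = (2, 50, 2.0)
        assert real.scores[key] > null.scores[key]
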