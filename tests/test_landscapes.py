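import numpy as np
import pytest

from cpmnext import (
    FitnessLandscape,
    RestrictionDAG,
    build_fitness_graph,
    count_peaks,
    dag_compatible_genotypes,
    gamma_statistic,
    generate_restriction_dag,
    genotype_from_str,
    genotype_str,
    make_local_maxima_landscape,
    make_representable_landscape,
    make_rmf_landscape,
    rse_fraction,
)


def additive_landscape(effects):
    """f(g) = 1 + sum of per-locus effects: zero epistasis by construction."""
    G = len(effects)
    f = np.array(
        [1.0 + sum(e for i, e in enumerate(effects) if (g >> i) & 1) for g in range(1 << G)]
    )
    return FitnessLandscape(G=G, fitness=f, kind="custom")


class TestRestrictionDAG:
    def test_compatible_genotypes_and_gate(self, fig_dag):
        comp = dag_compatible_genotypes(fig_dag)
        # exhaustive: gene 3 present implies genes 1 and 2 present
        expected = {
            g for g in range(16) if not ((g >> 3) & 1) or ((g >> 1) & 1 and (g >> 2) & 1)
        }
        assert comp == expected
        assert len(comp) == 10

    def test_empty_dag_allows_everything(self):
        dag = RestrictionDAG(G=3, parents={})
        assert len(dag_compatible_genotypes(dag)) == 8

    def test_chain_allows_only_prefixes(self, chain_dag):
        comp = {genotype_str(g, 3) for g in dag_compatible_genotypes(chain_dag)}
        assert comp == {"000", "100", "110", "111"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            RestrictionDAG(G=2, parents={0: frozenset({1}), 1: frozenset({0})})

    def test_generator_density_zero_and_determinism(self):
        dag = generate_restriction_dag(5, 0.0, seed=1)
        assert all(not dag.parents[i] for i in range(5))
        a = generate_restriction_dag(6, 0.4, seed=7)
        b = generate_restriction_dag(6, 0.4, seed=7)
        assert a.parents == b.parents
        with pytest.raises(ValueError):
            generate_restriction_dag(4, 1.5)

    def test_json_roundtrip(self, fig_dag):
        assert RestrictionDAG.from_json(fig_dag.to_json()).parents == fig_dag.parents


class TestRepresentable:
    def test_multiplicative_closed_form(self):
        dag = RestrictionDAG(G=2, parents={})
        ls = make_representable_landscape(dag, [0.1, 0.1])
        assert ls.fitness[0b11] == pytest.approx(1.21)
        assert build_fitness_graph(ls).peaks == {0b11}

    def test_chain_blocks_off_path_genotypes(self):
        dag = RestrictionDAG(G=2, parents={1: frozenset({0})})
        ls = make_representable_landscape(dag, [0.2, 0.1])
        assert ls.fitness[genotype_from_str("01")] == 0.0
        graph = build_fitness_graph(ls)
        assert set(graph.nodes) == {0b00, 0b01, 0b11}  # 00 -> 10 -> 11 only

    def test_single_peak_at_maximal_compatible(self, fig_dag, rep_landscape):
        graph = build_fitness_graph(rep_landscape)
        assert set(graph.nodes) == dag_compatible_genotypes(fig_dag)
        assert graph.peaks == {0b1111}

    @pytest.mark.parametrize("seed", range(4))
    def test_random_dags_keep_single_peak(self, seed):
        rng = np.random.default_rng(seed)
        dag = generate_restriction_dag(6, 0.35, seed=seed)
        ls = make_representable_landscape(dag, rng.uniform(0.05, 0.3, 6))
        graph = build_fitness_graph(ls)
        assert set(graph.nodes) == dag_compatible_genotypes(dag)
        assert len(graph.peaks) == 1

    def test_rejects_nonpositive_effects(self, fig_dag):
        with pytest.raises(ValueError):
            make_representable_landscape(fig_dag, [0.1, -0.1, 0.2, 0.2])


class TestLocalMaxima:
    def test_enforces_two_peaks_and_compatible_set(self, fig_dag):
        ls = make_local_maxima_landscape(
            fig_dag, [0.2, 0.2, 0.2, 0.2], noise_sd=0.25, seed=5
        )
        graph = build_fitness_graph(ls)
        assert set(graph.nodes) == dag_compatible_genotypes(fig_dag)
        assert len(graph.peaks) >= 2

    def test_vanishing_noise_exhausts_tries(self, fig_dag):
        with pytest.raises(RuntimeError):
            make_local_maxima_landscape(
                fig_dag, [0.2, 0.2, 0.2, 0.2], noise_sd=1e-9, seed=0, max_tries=5
            )

    def test_seed_reproducible(self, fig_dag):
        a = make_local_maxima_landscape(fig_dag, [0.2] * 4, noise_sd=0.25, seed=3)
        b = make_local_maxima_landscape(fig_dag, [0.2] * 4, noise_sd=0.25, seed=3)
        np.testing.assert_array_equal(a.fitness, b.fitness)


class TestRMF:
    def test_no_noise_single_peak_at_reference(self):
        ls = make_rmf_landscape(4, c=0.3, reference=0b1111, noise_sd=0.0, seed=0)
        assert build_fitness_graph(ls).peaks == {0b1111}
        assert np.all(ls.fitness > 0)

    def test_house_of_cards_is_multipeaked_on_average(self):
        counts = [
            count_peaks(make_rmf_landscape(3, c=0.0, noise_sd=1.0, seed=s))
            for s in range(30)
        ]
        assert np.mean(counts) > 1

    def test_seed_reproducible(self):
        a = make_rmf_landscape(5, c=0.2, noise_sd=0.4, seed=9)
        b = make_rmf_landscape(5, c=0.2, noise_sd=0.4, seed=9)
        np.testing.assert_array_equal(a.fitness, b.fitness)


class TestFitnessGraph:
    def test_one_gene_cases(self):
        up = FitnessLandscape(G=1, fitness=np.array([1.0, 2.0]), kind="custom")
        g = build_fitness_graph(up)
        assert g.nodes == {0, 1} and g.children[0] == [1]
        down = FitnessLandscape(G=1, fitness=np.array([1.0, 0.5]), kind="custom")
        g = build_fitness_graph(down)
        assert g.nodes == {0} and g.peaks == {0}


class TestStatistics:
    def test_gamma_one_for_additive(self):
        ls = additive_landscape([0.1, 0.25, 0.4])
        assert gamma_statistic(ls) == pytest.approx(1.0)

    def test_gamma_degenerate_returns_nan(self):
        f = np.array([1.0, 1.1, 1.1, 1.0])  # both x-effects identical
        ls = FitnessLandscape(G=2, fitness=f, kind="custom")
        assert np.isnan(gamma_statistic(ls))

    def test_gamma_near_zero_for_house_of_cards(self):
        vals = [
            gamma_statistic(make_rmf_landscape(5, c=0.0, noise_sd=1.0, seed=s))
            for s in range(20)
        ]
        assert abs(np.mean(vals)) < 0.15

    def test_rse_zero_for_additive_and_multiplicative(self, rep_landscape):
        assert rse_fraction(additive_landscape([0.1, 0.2, 0.3])) == 0.0
        assert rse_fraction(rep_landscape) == 0.0

    def test_rse_detects_reciprocal_sign_epistasis(self):
        f = np.array([1.0, 0.9, 0.9, 1.2])
        ls = FitnessLandscape(G=2, fitness=f, kind="custom")
        assert rse_fraction(ls) == 1.0
        assert rse_fraction(ls, per_square=True) == 1.0

    def test_count_peaks_hand_case(self):
        f = np.array([1.0, 1.2, 1.1, 1.05])
        ls = FitnessLandscape(G=2, fitness=f, kind="custom")
        assert count_peaks(ls) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_statistics_invariant_under_gene_relabeling(self, seed):
        ls = make_rmf_landscape(4, c=0.2, noise_sd=0.5, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(4)
        remap = np.zeros(16, dtype=int)
        for g in range(16):
            h = 0
            for i in range(4):
                if (g >> i) & 1:
                    h |= 1 << perm[i]
            remap[h] = g
        permuted = FitnessLandscape(G=4, fitness=ls.fitness[remap], kind="custom")
        assert gamma_statistic(permuted) == pytest.approx(gamma_statistic(ls))
        assert rse_fraction(permuted) == pytest.approx(rse_fraction(ls))
        assert count_peaks(permuted) == count_peaks(ls)
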