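import numpy as np
import pytest

from radscape.errors import ConfigurationError
from radscape.scenarios import MergeEvent, Scenario
from radscape.simulate import (
    ObservationModel,
    SampleDesign,
    apply_observation_model,
    draw_coalescent_tree,
    mutate_locus,
    planted_het_catalog,
    simulate_dataset,
    simulate_marker,
)
from radscape.stats import pairwise_fst, summary_stats, tajimas_d


def one_deme(ne: float = 1000.0) -> Scenario:
    return Scenario("panmixia", ("A",), (), {"A": ne})


def two_demes(t: float, ne: float = 1000.0) -> Scenario:
    return Scenario("split", ("A", "B"), (MergeEvent(t, "B", "A"),), {"A": ne, "B": ne})


def pair_design(**kw) -> SampleDesign:
    return SampleDesign(marker="rad", samples={"A": 2}, n_loci=1, **kw)


class TestCoalescentTree:
    def test_pair_tmrca_matches_closed_form(self):
        # haploid-pair coalescence at rate 1/(2N) -> E[T2] = 2N generations
        ne = 500.0
        scenario = one_deme(ne)
        design = pair_design()
        reps = 4000
        tm = np.array(
            [draw_coalescent_tree(scenario, design, s).tmrca() for s in range(reps)]
        )
        expected = 2 * ne
        mc_sd = tm.std(ddof=1) / np.sqrt(reps)
        assert abs(tm.mean() - expected) < 3 * mc_sd

    def test_mito_pair_tmrca_uses_quarter_size(self):
        # fourfold smaller effective number: E[T2] = 2 * (N/4) = N/2
        ne = 2000.0
        scenario = one_deme(ne)
        design = SampleDesign(marker="mito", samples={"A": 2}, n_loci=1,
                              locus_length=658, invariant_fraction=0.95)
        reps = 4000
        tm = np.array(
            [draw_coalescent_tree(scenario, design, s).tmrca() for s in range(reps)]
        )
        mc_sd = tm.std(ddof=1) / np.sqrt(reps)
        assert abs(tm.mean() - ne / 2) < 3 * mc_sd

    def test_no_cross_region_coalescence_before_merge(self):
        t = 50_000.0
        scenario = two_demes(t)
        design = SampleDesign(marker="rad", samples={"A": 4, "B": 4}, n_loci=1)
        for seed in range(25):
            tree = draw_coalescent_tree(scenario, design, seed)
            assert tree.min_cross_region_height() >= t

    def test_seed_determinism(self):
        scenario = two_demes(1000.0)
        design = SampleDesign(marker="rad", samples={"A": 4, "B": 4}, n_loci=1)
        assert (
            draw_coalescent_tree(scenario, design, 7).newick()
            == draw_coalescent_tree(scenario, design, 7).newick()
        )

    def test_unknown_region_rejected(self):
        with pytest.raises(ConfigurationError):
            draw_coalescent_tree(
                one_deme(), SampleDesign(marker="rad", samples={"Z": 2}), 0
            )


class TestMutateLocus:
    def test_zero_rate_gives_identical_haplotypes(self):
        tree = draw_coalescent_tree(one_deme(), pair_design(mutation_rate=0.0), 3)
        hap = mutate_locus(tree, tree.design, 3)
        assert len(set(hap.sequences())) == 1

    def test_fully_invariant_locus_never_segregates(self):
        design = pair_design(mutation_rate=1e-4, invariant_fraction=1.0)
        for seed in range(10):
            tree = draw_coalescent_tree(one_deme(), design, seed)
            assert len(mutate_locus(tree, design, seed).snp_positions) == 0

    def test_expected_pairwise_differences(self):
        # E[diffs] = 2 * E[T2] * mu * L_var for a sampled pair
        ne, mu = 400.0, 5e-6
        design = pair_design(mutation_rate=mu, invariant_fraction=0.9)  # L_var = 10
        l_var = design.n_variable_sites
        reps = 3000
        diffs = []
        for seed in range(reps):
            tree = draw_coalescent_tree(one_deme(ne), design, seed)
            hap = mutate_locus(tree, design, seed + 10_000)
            diffs.append(np.sum(hap.matrix[0] != hap.matrix[1]))
        diffs = np.asarray(diffs, dtype=float)
        expected = 2 * (2 * ne) * mu * l_var
        mc_sd = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean() - expected) < 3 * mc_sd


class TestSimulateDataset:
    def test_study_shaped_catalog_dimensions(self):
        scenario = Scenario(
            "flat", ("BF", "CM", "MC", "PY"),
            (MergeEvent(1e5, "BF", "MC"), MergeEvent(2e5, "MC", "PY"),
             MergeEvent(3e5, "PY", "CM")),
            {r: 1000.0 for r in ("BF", "CM", "MC", "PY")},
        )
        rad = SampleDesign(marker="rad", samples={"BF": 20, "MC": 4, "PY": 4, "CM": 6},
                           n_loci=40)
        mito = SampleDesign(marker="mito", samples={"BF": 8, "MC": 2, "PY": 2, "CM": 3},
                            n_loci=1, locus_length=658, invariant_fraction=0.95,
                            mutation_rate=1e-6)
        catalog, alignment = simulate_dataset(scenario, rad, mito, 11)
        assert catalog.n_individuals == 17  # Black Forest 10, MC 2, PY 2, CM 3
        assert catalog.n_loci == 40
        assert alignment.n == 15
        assert alignment.length == 658

    def test_panmixia_limit_fst_near_zero(self):
        scenario = Scenario("flat2", ("A", "B"), (MergeEvent(1.0, "B", "A"),),
                            {"A": 1000.0, "B": 1000.0})
        design = SampleDesign(marker="rad", samples={"A": 12, "B": 12}, n_loci=400,
                              mutation_rate=2e-6)
        vals = [
            pairwise_fst(simulate_marker(scenario, design, s), "A", "B")
            for s in range(6)
        ]
        assert abs(float(np.mean(vals))) < 0.05

    def test_deep_split_gives_reciprocal_monophyly(self):
        # t >> 4N: within-region coalescence completes long before the merge
        ne, t = 100.0, 200_000.0
        scenario = two_demes(t, ne)
        design = SampleDesign(marker="rad", samples={"A": 4, "B": 4}, n_loci=1)
        mono = 0
        reps = 200
        for seed in range(reps):
            tree = draw_coalescent_tree(scenario, design, seed)
            mono += tree.min_cross_region_height() >= t
        assert mono / reps > 0.95

    def test_catalog_seed_determinism(self):
        scenario = two_demes(1e4)
        design = SampleDesign(marker="rad", samples={"A": 4, "B": 4}, n_loci=30,
                              mutation_rate=1e-6)
        assert simulate_marker(scenario, design, 5) == simulate_marker(scenario, design, 5)


class TestNeutralCalibration:
    def test_watterson_and_tajima_over_many_loci(self):
        # panmictic constant size: E[pi] = theta = 4*N*mu per site; mean D ~ 0
        ne, mu, n_loci = 800.0, 5e-6, 1200
        scenario = one_deme(ne)
        design = SampleDesign(marker="rad", samples={"A": 16}, n_loci=n_loci,
                              mutation_rate=mu, invariant_fraction=0.9)
        catalog = simulate_marker(scenario, design, 99)
        mat, _ = catalog.haplotype_matrix()
        l_var = design.n_variable_sites
        theta = 4 * ne * mu

        from radscape.stats import pairwise_difference_matrix

        diffs, _ = pairwise_difference_matrix(mat)
        iu = np.triu_indices(mat.shape[0], 1)
        pi_per_site = diffs[iu].mean() / (l_var * n_loci)
        # Monte-Carlo SE over loci for per-locus pi
        per_locus = []
        for li in range(n_loci):
            cols = catalog.snp_locus == li
            sub = mat[:, cols]
            d, _ = pairwise_difference_matrix(sub)
            per_locus.append(d[iu].mean() / l_var if sub.shape[1] else 0.0)
        per_locus = np.asarray(per_locus)
        se = per_locus.std(ddof=1) / np.sqrt(n_loci)
        assert abs(pi_per_site - theta) < 3 * se

        d_vals = []
        for li in range(n_loci):
            cols = catalog.snp_locus == li
            if cols.any():
                d = tajimas_d(mat[:, cols])
                if np.isfinite(d):
                    d_vals.append(d)
        assert len(d_vals) > 300
        assert -0.2 < float(np.mean(d_vals)) < 0.2


class TestObservationModel:
    def test_zero_min_depth_changes_nothing(self):
        catalog = planted_het_catalog(n_loci=50, rng_seed=1)
        model = ObservationModel(min_depth=0)
        out = apply_observation_model(catalog, model, 2)
        assert np.array_equal(out.geno, catalog.geno)
        assert np.array_equal(out.called, catalog.called)

    def test_forced_shallow_depth_masks_everything(self):
        catalog = planted_het_catalog(n_loci=50, rng_seed=1)
        model = ObservationModel(constant_depth=4, min_depth=5)
        out = apply_observation_model(catalog, model, 2)
        assert not out.called.any()
        assert (out.geno == -1).all()

    def test_masked_fraction_matches_depth_cdf(self):
        catalog = planted_het_catalog(n_loci=3000, rng_seed=1)
        model = ObservationModel(mean_depth=20.0, dispersion=3.0, min_depth=5)
        out = apply_observation_model(catalog, model, 7)
        frac = 1.0 - out.called.mean()
        expected = model.masked_fraction()
        n = out.called.size
        mc_sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * mc_sd


def test_summary_stats_deterministic_given_dataset():
    scenario = two_demes(5e4)
    design = SampleDesign(marker="rad", samples={"A": 6, "B": 6}, n_loci=40,
                          mutation_rate=1e-6)
    catalog = simulate_marker(scenario, design, 21)
    v1, v2 = summary_stats(catalog), summary_stats(catalog)
    assert v1.names == v2.names
    np.testing.assert_array_equal(v1.values, v2.values)
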