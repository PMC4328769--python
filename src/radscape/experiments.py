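"""Canonical desk-scale experiments over the synthetic study design.

Each function fixes one set of study conditions (sample sizes, locus
numbers, scenario parameters, replicate counts) so the analysis scripts,
the test suite and the acceptance script all run the same experiment.
Problem sizes are desk-scale versions of the study design: 17 individuals
in 4 regions, hundreds-to-thousands of loci, 10^4 ABC reference rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abc import abc_direct, abc_logistic, build_reference_table, rad_prior
from .saturation import het_saturation, topology_saturation
from .scenarios import scenario_library
from .simulate import SampleDesign, planted_het_catalog, simulate_marker
from .stats import pairwise_difference_matrix, summary_stats, tajimas_d
from .trees import study_constraint

#: moderate-divergence demonstration scenario for tree-based diagnostics
#: (keeps SNP-column K2P distances inside the log domain)
SATURATION_NE = 5_000.0
SATURATION_TIMES = (2e4, 5e4, 1.2e5)
SATURATION_MU = 2e-6

#: individual heterozygosity extremes reported for the study's two
#: reference specimens (Cantabrian Mountains 14.5 %, Black Forest 2.5 %)
HET_RATES = {"BF": 0.025, "MC": 0.114, "PY": 0.035, "CM": 0.145}


def study_rad_design(n_loci: int, mutation_rate: float = 1e-7) -> SampleDesign:
    return SampleDesign(
        marker="rad",
        samples={"BF": 20, "MC": 4, "PY": 4, "CM": 6},
        n_loci=n_loci,
        locus_length=100,
        mutation_rate=mutation_rate,
        invariant_fraction=0.98,
        sites_per_region={"BF": 3, "MC": 1, "PY": 2, "CM": 2},
    )


def neutral_calibration(
    rng_seed: int, ne: float = 800.0, mu: float = 5e-6, n_loci: int = 1500, n_hap: int = 16
) -> dict:
    """Panmictic constant-size check: E[pi] = 4*N*mu per site, mean D ~ 0."""
    from .scenarios import Scenario

    scenario = Scenario("panmixia", ("A",), (), {"A": ne})
    design = SampleDesign(marker="rad", samples={"A": n_hap}, n_loci=n_loci,
                          mutation_rate=mu, invariant_fraction=0.9)
    catalog = simulate_marker(scenario, design, rng_seed)
    mat, _ = catalog.haplotype_matrix()
    l_var = design.n_variable_sites
    iu = np.triu_indices(mat.shape[0], 1)

    per_locus_pi = np.zeros(n_loci)
    d_vals = []
    for li in range(n_loci):
        cols = catalog.snp_locus == li
        if cols.any():
            sub = mat[:, cols]
            d, _ = pairwise_difference_matrix(sub)
            per_locus_pi[li] = d[iu].mean() / l_var
            taj = tajimas_d(sub)
            if np.isfinite(taj):
                d_vals.append(taj)
    theta = 4 * ne * mu
    pi_hat = float(per_locus_pi.mean())
    pi_se = float(per_locus_pi.std(ddof=1) / np.sqrt(n_loci))
    return {
        "theta": theta,
        "pi_hat": pi_hat,
        "pi_se": pi_se,
        "pi_over_theta": pi_hat / theta,
        "tajima_mean": float(np.mean(d_vals)),
        "tajima_se": float(np.std(d_vals, ddof=1) / np.sqrt(len(d_vals))),
        "n_polymorphic_loci": len(d_vals),
        "n_loci": n_loci,
    }


def het_contrast_experiment(
    n_runs: int = 20, rng_seed: int = 0, n_loci: int = 1500
) -> dict:
    """Band-separation runs for the two extreme individuals.

    Each run regenerates a planted-contrast catalog and reruns the
    individual-level saturation procedure (grid 10..1000 by 10, 100
    replicates, per the study's protocol); reports the fraction of runs in
    which the mean +/- SD bands separate at some L <= 1000.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * n_runs, dtype=np.uint32)
    grid = np.arange(10, 1001, 10)
    seps = []
    for run in range(n_runs):
        catalog = planted_het_catalog(rates=HET_RATES, n_loci=n_loci,
                                      rng_seed=int(seeds[2 * run]))
        curve = het_saturation(
            catalog, grid=grid, reps=100, level="individual",
            track=["CM001", "BF001"], rng_seed=int(seeds[2 * run + 1]),
        )
        seps.append(curve.convergence["band_separation_L"])
    ok = [s for s in seps if s is not None and s <= 1000]
    return {
        "separation_L": seps,
        "fraction_separated": len(ok) / n_runs,
        "median_separation_L": float(np.median(ok)) if ok else float("nan"),
        "n_runs": n_runs,
    }


def topology_saturation_experiment(
    rng_seed: int = 0, n_loci: int = 2000, reps: int = 20
) -> dict:
    """Topology saturation on a moderately diverged synthetic catalog."""
    scenario = scenario_library(ne=SATURATION_NE, times=SATURATION_TIMES)["scenario_17"]
    design = study_rad_design(n_loci, mutation_rate=SATURATION_MU)
    seeds = np.random.SeedSequence(rng_seed).generate_state(2, dtype=np.uint32)
    catalog = simulate_marker(scenario, design, int(seeds[0]))
    reference = study_constraint(catalog.popmap)
    curve, convergence = topology_saturation(
        catalog, reference, grid=np.arange(100, 1001, 100), reps=reps,
        rng_seed=int(seeds[1]),
    )
    return {
        "curve": curve,
        "convergence_L": convergence,
        "mean_final": float(curve.mean("rf")[-1]),
        "n_loci": n_loci,
    }


def abc_recovery_experiment(
    rng_seed: int = 0,
    n_table_rows: int = 10_000,
    n_replicates: int = 50,
    n_loci: int = 30,
    n_closest: int = 500,
) -> dict:
    """Scenario-recovery experiment for the three built-in scenarios.

    The reference table draws all parameters from the log-uniform priors;
    pseudo-observed datasets are simulated under the deep-split default
    parameterization of the colonization-from-the-Cantabrian scenario.
    """
    scenarios = scenario_library()  # deep-split defaults
    design = study_rad_design(n_loci)
    n_per = n_table_rows // len(scenarios)
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 + n_replicates,
                                                            dtype=np.uint32)
    table = build_reference_table(scenarios, rad_prior(), design, n_per, int(seeds[0]))

    true = "scenario_17"
    rows = []
    for rep in range(n_replicates):
        dataset = simulate_marker(scenarios[true], design, int(seeds[2 + rep]))
        vec = summary_stats(dataset)
        direct = abc_direct(vec, table, n_closest)
        logistic = abc_logistic(vec, table, n_closest, ci=False)
        rows.append(
            {
                "replicate": rep,
                "direct_best": direct.best(),
                "logistic_best": logistic.best(),
                "direct_p_true": direct.probabilities[table.scenario_names.index(true)],
                "logistic_p_true": logistic.probabilities[table.scenario_names.index(true)],
                "direct_sum": float(direct.probabilities.sum()),
                "logistic_sum": float(logistic.probabilities.sum()),
            }
        )
    df = pd.DataFrame(rows)
    return {
        "table": table,
        "results": df,
        "direct_recovery": float((df["direct_best"] == true).mean()),
        "logistic_recovery": float((df["logistic_best"] == true).mean()),
        "max_prob_sum_error": float(
            np.max(np.abs(np.concatenate([df["direct_sum"], df["logistic_sum"]]) - 1.0))
        ),
        "n_table_rows": n_per * len(scenarios),
        "n_replicates": n_replicates,
    }
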