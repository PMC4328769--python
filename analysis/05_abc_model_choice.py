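#!/usr/bin/env python
"""ABC model choice among the three built-in divergence scenarios.

Builds a reference table from the log-uniform priors, simulates one
pseudo-observed RAD dataset under the colonization-from-the-Cantabrian
scenario, and reports direct (rejection) and logistic-regression posterior
probabilities with confidence intervals, plus a scenario-recovery summary
over repeated pseudo-observations.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from radscape.abc import abc_direct, abc_logistic, build_reference_table, rad_prior
from radscape.experiments import abc_recovery_experiment, study_rad_design
from radscape.scenarios import scenario_library
from radscape.simulate import simulate_marker
from radscape.stats import summary_stats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-per-scenario", type=int, default=1000,
                        help="reference simulations per scenario")
    parser.add_argument("--n-closest", type=int, default=500)
    parser.add_argument("--recovery-reps", type=int, default=20)
    args = parser.parse_args()

    root = Path(__file__).resolve().parent.parent
    results = root / "results"
    results.mkdir(exist_ok=True)

    scenarios = scenario_library()
    design = study_rad_design(n_loci=30)
    print(f"building reference table: {len(scenarios)} scenarios x "
          f"{args.n_per_scenario} simulations, 17 individuals, {design.n_loci} loci")
    table = build_reference_table(scenarios, rad_prior(), design,
                                  args.n_per_scenario, args.seed)

    observed = simulate_marker(scenarios["scenario_17"], design, args.seed + 1)
    vec = summary_stats(observed)
    direct = abc_direct(vec, table, n_closest=args.n_closest)
    logistic = abc_logistic(vec, table, n_retained=args.n_closest, ci=True)

    report = direct.as_frame().rename(
        columns={"probability": "direct", "ci_low": "direct_lo", "ci_high": "direct_hi"}
    )
    lg = logistic.as_frame().rename(
        columns={"probability": "logistic", "ci_low": "logistic_lo",
                 "ci_high": "logistic_hi"}
    )
    report = report.merge(lg, on="scenario")
    report.to_csv(results / "abc_posteriors.tsv", sep="\t", index=False,
                  float_format="%.4f")
    print("\nposterior probabilities for a pseudo-observed dataset "
          "(truth: scenario_17):")
    print(report.round(4).to_string(index=False))

    rec = abc_recovery_experiment(
        rng_seed=args.seed + 2,
        n_table_rows=3 * args.n_per_scenario,
        n_replicates=args.recovery_reps,
    )
    rec["results"].to_csv(results / "abc_recovery.tsv", sep="\t", index=False,
                          float_format="%.4f")
    print(f"\nrecovery over {rec['n_replicates']} pseudo-observed replicates: "
          f"logistic picks the true scenario in "
          f"{100 * rec['logistic_recovery']:.0f}% of runs "
          f"(direct: {100 * rec['direct_recovery']:.0f}%)")


if __name__ == "__main__":
    main()
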