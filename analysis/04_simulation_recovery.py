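#!/usr/bin/env python
"""Planted-truth recovery on synthetic prPBL-like cohorts.

Simulates seeded cohorts with known drivers and signature mixtures,
runs the full pipeline, and reports: (a) drivers planted above the
filter thresholds are recovered as recommendations at 100%; (b) drivers
planted below the 5% VAF filter are recovered at 0%; (c) refitted
signature mixtures track the planted Dirichlet draws.  Writes
results/simulation_recovery.json.
"""

import json
from pathlib import Path

from mtbmatch import load_knowledge_base, paper_kb_path
from mtbmatch.simulate import (
    DEFAULT_DRIVER_RATES,
    SimulationConfig,
    recovery_experiment,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    kb = load_knowledge_base(paper_kb_path())
    all_driver = {g: 1.0 for g in DEFAULT_DRIVER_RATES}
    scenarios = {
        "default": SimulationConfig(n_cases=14, seed=SEED,
                                    catalog_mutations=2000),
        "drivers_above_thresholds": SimulationConfig(
            n_cases=6, seed=SEED, variants_per_case=60.0,
            catalog_mutations=2000, pop_af_contaminant_rate=0.0,
            driver_vaf=0.35, driver_rates=all_driver),
        "drivers_below_vaf_filter": SimulationConfig(
            n_cases=6, seed=SEED, variants_per_case=60.0,
            catalog_mutations=2000, driver_vaf=0.03,
            driver_rates=all_driver),
    }
    results = {}
    for name, config in scenarios.items():
        r = recovery_experiment(config, kb)
        results[name] = {k: v for k, v in r.items() if k != "per_case"}
        print(f"{name}: recovery "
              f"{r['driver_recovery'] if r['driver_recovery'] is not None else 'n/a'}"
              f" ({r['recovered_drivers']}/{r['planted_drivers']}),"
              f" max signature error {r['max_signature_error']:.3f}")
    OUT.mkdir(exist_ok=True)
    (OUT / "simulation_recovery.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
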