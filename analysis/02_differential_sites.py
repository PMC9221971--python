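#!/usr/bin/env python
"""Differential-succinylation calling on the simulated experiment.

Runs centralization, median normalization, fold change and t-test on the
same seeded dataset as 01, calls sites at FC > 1.5 or < 0.67 with p < 0.05,
and checks the calls against the planted ground truth.
"""

from pathlib import Path

import pandas as pd

from succinylome.io import write_tsv
from succinylome.quantify import DssThresholds, differential_sites
from succinylome.simulate import SimulationConfig, simulate_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = SimulationConfig(n_proteins=300, seed=SEED)
    data = simulate_experiment(config, n_spiked=30, spike_fc=2.0)
    report = differential_sites(
        data.intensities, data.sample_sheet, "8h", "0h", thresholds=DssThresholds()
    )
    report["true_fc"] = [data.truth.fold_changes[s] for s in report.index]
    write_tsv(report.reset_index(), RESULTS / "02_dss_report.tsv", params={"seed": SEED})

    spiked = report[report["true_fc"] == 2.0]
    null = report[report["true_fc"] == 1.0]
    calls = report["call"].value_counts().to_dict()
    summary = pd.DataFrame(
        [
            {"quantity": "sites_total", "value": len(report)},
            {"quantity": "sites_testable", "value": int(report["fold_change"].notna().sum())},
            {"quantity": "called_up", "value": calls.get("up", 0)},
            {"quantity": "called_down", "value": calls.get("down", 0)},
            {"quantity": "spiked_mean_fc", "value": round(float(spiked["fold_change"].mean()), 4)},
            {"quantity": "spiked_recall", "value": round(float((spiked["call"] == "up").mean()), 4)},
            {"quantity": "null_fpr_at_0.05", "value": round(float((null["p_value"].dropna() < 0.05).mean()), 4)},
        ]
    )
    write_tsv(summary, RESULTS / "02_dss_summary.tsv", params={"seed": SEED})
    for _, row in summary.iterrows():
        print(f"{row['quantity']}: {row['value']}")


if __name__ == "__main__":
    main()
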