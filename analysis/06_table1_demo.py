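#!/usr/bin/env python
"""The published worked example: nine differentially succinylated sites.

Loads the bundled transcription of the study's differential-site table and
re-applies the decision rule (fold change > 1.5 or < 0.67, p < 0.05) to the
printed fold changes; the p-values are below threshold by the table's
construction.  Writes the per-site calls and prints the classification
summary.
"""

from pathlib import Path

from succinylome.io import read_table1_fixture, write_tsv
from succinylome.pipeline import demo_table1
from succinylome.quantify import DssThresholds, call_dss

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = read_table1_fixture()
    thresholds = DssThresholds()
    table["call"] = [
        call_dss(fc, thresholds.alpha / 2, thresholds) for fc in table["fold_change"]
    ]
    out = table[["protein_accession", "description", "dss", "fold_change", "call"]]
    write_tsv(out, RESULTS / "06_table1_calls.tsv")

    summary = demo_table1()
    print(f"{summary['n_dss']} differential sites on {summary['n_proteins']} proteins")
    print(f"classified: {summary['n_up']} up, {summary['n_down']} down")
    print(f"fold-change range: {summary['min_fold_change']} - {summary['max_fold_change']}")
    print(f"sites-per-protein histogram over the listed site lists: "
          f"{summary['sites_per_protein']}")


if __name__ == "__main__":
    main()
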