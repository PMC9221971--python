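#!/usr/bin/env python
"""Cross-species conservation of the simulated differential sites.

Derives synthetic homologs from a handful of reference proteins (point
substitutions at 5% plus short indels — a stand-in for real Brassicaceae
orthologs), aligns each reference against its homologs with the global
affine-gap aligner, maps every site through the alignment, and flags
domain co-location for synthetic domain intervals.
"""

from pathlib import Path

import numpy as np

from succinylome.conservation import conservation_report, report_table
from succinylome.io import write_tsv
from succinylome.simulate import SimulationConfig, generate_proteome, generate_sites

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0
SPECIES = ["speciesA", "speciesB", "speciesC", "speciesD"]
AA = list("ACDEFGHIKLMNPQRSTVWY")


def mutate(seq: str, rng: np.random.Generator) -> str:
    """Synthetic homolog: 5% substitutions, one short indel."""
    chars = [rng.choice(AA) if rng.random() < 0.05 else ch for ch in seq]
    pos = int(rng.integers(1, len(chars)))
    if rng.random() < 0.5:
        chars[pos:pos] = list(rng.choice(AA, size=int(rng.integers(1, 4))))
    else:
        del chars[pos : pos + int(rng.integers(1, 4))]
    return "".join(chars)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = SimulationConfig(n_proteins=300, seed=SEED)
    proteome = generate_proteome(config)
    sites = generate_sites(proteome, config)
    rng = np.random.default_rng(SEED)

    # ten reference proteins and their sites, as a DSS-sized demonstration
    refs = sorted({s.protein for s in sites})[:10]
    subset = [s for s in sites if s.protein in refs]
    homolog_sets = {
        acc: [(sp, mutate(proteome[acc], rng)) for sp in SPECIES] for acc in refs
    }
    domains = {
        acc: [("synthetic_core", len(proteome[acc]) // 4, 3 * len(proteome[acc]) // 4)]
        for acc in refs
    }
    reports = conservation_report(subset, proteome, homolog_sets, domains)
    table = report_table(reports)
    write_tsv(table, RESULTS / "05_conservation.tsv", params={"seed": SEED})

    fractions = [r.conserved_fraction for r in reports if r.conserved_fraction is not None]
    in_domain = sum(r.in_domain for r in reports)
    print(f"{len(reports)} sites on {len(refs)} proteins vs {len(SPECIES)} homologs each")
    print(f"mean conserved fraction: {np.mean(fractions):.2f} "
          f"(5% substitution rate -> ~0.95 expected at K sites)")
    print(f"sites inside the synthetic core domain: {in_domain}/{len(reports)}")


if __name__ == "__main__":
    main()
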