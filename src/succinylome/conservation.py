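"""Cross-homolog conservation of modified sites.

Each differentially succinylated site is mapped from its reference protein
onto homologous sequences from related species via pairwise global
(Needleman–Wunsch) alignment under BLOSUM62 with affine gaps (a gap of
length L scores −10 − 0.5·(L−1)); a site is conserved in a homolog when the
aligned residue is also a lysine.  Pairwise alignment of the reference
against each homolog is used instead of a progressive multiple alignment:
site mapping only needs the pairwise columns.  A pre-aligned mode accepts
gapped sequence pairs directly for users who ran Clustal/MAFFT themselves.

Non-standard residues are treated as 'X' and score 0 against everything
(with a warning).  Domain co-location uses user-supplied 1-based inclusive
residue intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SiteRecord

GAP_OPEN = -10.0    # score of the first residue of a gap
GAP_EXTEND = -0.5   # score of each subsequent gap residue

GAP = "gap"


@lru_cache(maxsize=1)
def _scoring_matrix():
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    x = matrix.alphabet.index("X")
    arr[x, :] = 0.0
    arr[:, x] = 0.0
    return substitution_matrices.Array(alphabet=matrix.alphabet, dims=2, data=arr)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _scoring_matrix()
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _sanitize(seq: str, label: str) -> str:
    alphabet = set(_scoring_matrix().alphabet)
    cleaned = []
    replaced = set()
    for ch in seq.upper():
        if ch in alphabet and ch != "*":
            cleaned.append(ch)
        else:
            cleaned.append("X")
            replaced.add(ch)
    if replaced:
        warnings.warn(
            f"{label}: non-standard residues {sorted(replaced)} treated as 'X' "
            "(score 0 against anything)",
            stacklevel=3,
        )
    return "".join(cleaned)


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global alignment of two protein sequences.

    Returns the two gapped strings (equal length; removing '-' recovers the
    inputs) and the alignment score.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a_clean, b_clean = _sanitize(a, "sequence a"), _sanitize(b, "sequence b")
    aligner = _make_aligner()
    alignment = aligner.align(a_clean, b_clean)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    # Report the original residues in the gapped strings, not the X stand-ins.
    gapped_a = _restore(gapped_a, a)
    gapped_b = _restore(gapped_b, b)
    return gapped_a, gapped_b, float(alignment.score)


def _restore(gapped: str, original: str) -> str:
    out, i = [], 0
    for ch in gapped:
        if ch == "-":
            out.append(ch)
        else:
            out.append(original[i])
            i += 1
    return "".join(out)


def map_site(gapped_ref: str, gapped_hom: str, ref_position: int) -> int | str:
    """Map a 1-based reference position through an alignment.

    Returns the 1-based homolog position aligned to the reference residue,
    or ``"gap"`` when the reference column faces a gap.
    """
    ungapped_len = sum(1 for ch in gapped_ref if ch != "-")
    if not 1 <= ref_position <= ungapped_len:
        raise IndexError(
            f"reference position {ref_position} outside 1..{ungapped_len}"
        )
    ref_seen = hom_seen = 0
    for ref_ch, hom_ch in zip(gapped_ref, gapped_hom):
        if hom_ch != "-":
            hom_seen += 1
        if ref_ch != "-":
            ref_seen += 1
            if ref_seen == ref_position:
                return hom_seen if hom_ch != "-" else GAP
    raise AssertionError("unreachable: position not found")  # pragma: no cover


@dataclass
class HomologMatch:
    species: str
    aligned_position: int | str     # 1-based, or "gap"
    aligned_residue: str | None     # None when gap
    conserved: bool                 # aligned residue is K


@dataclass
class SiteConservationReport:
    site: SiteRecord
    homologs: list[HomologMatch] = field(default_factory=list)
    in_domain: bool = False
    domains: list[str] = field(default_factory=list)

    @property
    def conserved_fraction(self) -> float | None:
        if not self.homologs:
            return None
        return sum(h.conserved for h in self.homologs) / len(self.homologs)


def conservation_report(
    sites: Sequence[SiteRecord],
    sequences: Mapping[str, str],
    homolog_sets: Mapping[str, Sequence[tuple[str, str]]],
    domains: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    prealigned: Mapping[str, Sequence[tuple[str, str, str]]] | None = None,
) -> list[SiteConservationReport]:
    """Per-site conservation across homologs plus domain co-location.

    ``homolog_sets`` maps a reference accession to (species, sequence) pairs;
    a protein without homologs is reported with an empty homolog list.  When
    ``prealigned`` provides (species, gapped_ref, gapped_hom) triples for a
    protein, the alignment step is skipped for it.  ``domains`` maps
    accessions to (name, start, end) intervals, 1-based inclusive.
    """
    domains = domains or {}
    prealigned = prealigned or {}
    # Align each reference/homolog pair once, not once per site.
    alignments: dict[str, list[tuple[str, str, str]]] = {}
    for acc in {s.protein for s in sites}:
        if acc in prealigned:
            alignments[acc] = list(prealigned[acc])
        elif acc in homolog_sets and acc in sequences:
            alignments[acc] = []
            for species, hom_seq in homolog_sets[acc]:
                gapped_ref, gapped_hom, _ = global_align(sequences[acc], hom_seq)
                alignments[acc].append((species, gapped_ref, gapped_hom))
    reports = []
    for site in sites:
        report = SiteConservationReport(site=site)
        for species, gapped_ref, gapped_hom in alignments.get(site.protein, []):
            mapped = map_site(gapped_ref, gapped_hom, site.position)
            if mapped == GAP:
                report.homologs.append(HomologMatch(species, GAP, None, False))
            else:
                residue = gapped_hom.replace("-", "")[mapped - 1]
                report.homologs.append(
                    HomologMatch(species, mapped, residue, residue == "K")
                )
        hits = [
            name
            for name, start, end in domains.get(site.protein, [])
            if start <= site.position <= end
        ]
        report.domains = hits
        report.in_domain = bool(hits)
        reports.append(report)
    return reports


def report_table(reports: Sequence[SiteConservationReport]) -> pd.DataFrame:
    """Flatten the reports: one row per (site, homolog), sites without
    homologs included with blank homolog columns."""
    rows = []
    for rep in reports:
        base = {
            "site_id": rep.site.site_id,
            "protein": rep.site.protein,
            "position": rep.site.position,
            "conserved_fraction": rep.conserved_fraction,
            "in_domain": rep.in_domain,
            "domains": ";".join(rep.domains),
        }
        if not rep.homologs:
            rows.append({**base, "species": "", "aligned_position": "",
                         "aligned_residue": "", "conserved": ""})
        for hom in rep.homologs:
            rows.append(
                {
                    **base,
                    "species": hom.species,
                    "aligned_position": hom.aligned_position,
                    "aligned_residue": hom.aligned_residue or "-",
                    "conserved": hom.conserved,
                }
            )
    return pd.DataFrame(rows)
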