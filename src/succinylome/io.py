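"""Readers, writers and in-memory containers for the pipeline's external formats.

All tabular formats are UTF-8 tab-separated text with ``.`` as the decimal
separator.  Lines starting with ``#`` are treated as comments; every writer
emits a small comment header recording the tool version and the parameters
used.  Site coordinates are 1-based and residue-inclusive throughout, matching
the conventional "K150"-style notation for modified residues.
"""

from __future__ import annotations

import hashlib
import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__

logger = logging.getLogger(__name__)

#: The 20 standard residues; 'X' is additionally accepted as an unknown/pad.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(STANDARD_AA + "X")

ANNOTATION_CATEGORIES = ("KEGG", "GO-BP", "GO-MF", "GO-CC", "domain", "subcellular")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SiteRecord:
    """A succinylated lysine: protein accession plus 1-based residue position."""

    protein: str
    position: int

    @property
    def site_id(self) -> str:
        return f"{self.protein}:K{self.position}"


@dataclass
class SampleSheet:
    """Sample → (group label, replicate index) assignment."""

    samples: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.samples:
            raise FormatError("sample sheet is empty")
        groups: dict[str, int] = {}
        for sample, (group, _rep) in self.samples.items():
            groups[group] = groups.get(group, 0) + 1
        if any(n < 1 for n in groups.values()):  # pragma: no cover - construction
            raise FormatError("every group needs at least one sample")
        self._groups = groups

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    @property
    def groups(self) -> list[str]:
        return list(self._groups)

    def samples_in_group(self, group: str) -> list[str]:
        hits = [s for s, (g, _r) in self.samples.items() if g == group]
        if not hits:
            raise KeyError(f"no samples in group {group!r}")
        return hits

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"sample", "group", "replicate"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"sample sheet {path} must have columns {sorted(required)}"
            )
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in {path}")
        return cls(
            {
                row["sample"]: (row["group"], int(row["replicate"]))
                for _, row in df.iterrows()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"sample": s, "group": g, "replicate": r}
            for s, (g, r) in self.samples.items()
        ]
        write_tsv(pd.DataFrame(rows), path, params={"n_samples": len(rows)})


@dataclass
class IntensityMatrix:
    """Raw (or relative) peptide/site intensities.

    ``values`` has one row per quantified succinylated peptide/site form and
    one column per sample; missing observations are ``NaN`` (never zero).
    ``features`` is indexed like ``values`` and carries the protein accession
    and 1-based site position of each row.
    """

    values: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.features.index):
            raise FormatError("values and features must share a row index")
        if self.values.index.duplicated().any():
            raise FormatError("row ids must be unique")
        if (self.values < 0).any().any():
            raise FormatError("negative intensities are not allowed")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def validate_sequences(sequences: Mapping[str, str], *, source: str = "input") -> None:
    for acc, seq in sequences.items():
        if not seq:
            raise FormatError(f"{source}: empty sequence for {acc!r}")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{source}: sequence {acc!r} contains non-standard residues {sorted(bad)}"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an accession → uppercase sequence mapping.

    Duplicate accessions are rejected; an empty file yields an empty mapping
    with a warning.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate accession {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    validate_sequences(sequences, source=str(path))
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    params: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with a comment header recording tool version and parameters."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# succinylome v{__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def _finalize_matrix(
    values: pd.DataFrame, features: pd.DataFrame, sheet: SampleSheet
) -> IntensityMatrix:
    unknown = set(values.columns) - set(sheet.sample_ids)
    if unknown:
        raise FormatError(f"intensity table references unknown samples {sorted(unknown)}")
    missing = set(sheet.sample_ids) - set(values.columns)
    if missing:
        raise FormatError(f"declared samples absent from intensity table: {sorted(missing)}")
    values = values[sheet.sample_ids].astype(float)
    values.index.name = "site_id"
    features.index.name = "site_id"
    # MaxQuant writes 0 for "not quantified"; zeros would corrupt the means
    # and medians downstream, so both 0 and blank become missing.
    if (values < 0).any().any():
        raise FormatError("negative intensity encountered")
    values = values.mask(values == 0)
    return IntensityMatrix(values=values, features=features)


def read_intensity_table(path: str | Path, sheet: SampleSheet) -> IntensityMatrix:
    """Read a site/peptide intensity table in either supported dialect.

    Two dialects are accepted:

    * **long** — columns ``site_id``, ``protein``, ``position``, ``sample``,
      ``intensity``; one row per observed (site, sample) pair.
    * **wide / MaxQuant-sites-like** — columns ``Protein``, ``Position`` and
      one ``Intensity <sample>`` column per sample; extra columns are
      ignored.

    Intensities of 0 and empty cells are mapped to missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if {"sample", "intensity"}.issubset(cols):
        return _read_long(df, sheet)
    wide_cols = [c for c in df.columns if c.startswith("Intensity ")]
    if {"Protein", "Position"}.issubset(cols) and wide_cols:
        return _read_wide(df, wide_cols, sheet)
    raise FormatError(
        f"{path}: unrecognized intensity-table dialect (need long columns "
        "site_id/protein/position/sample/intensity or MaxQuant-like "
        "Protein/Position/'Intensity <sample>')"
    )


def _read_long(df: pd.DataFrame, sheet: SampleSheet) -> IntensityMatrix:
    required = {"site_id", "protein", "position", "sample", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"long intensity table must have columns {sorted(required)}")
    values = df.pivot_table(
        index="site_id", columns="sample", values="intensity", aggfunc="first"
    )
    values.columns.name = None
    observed_samples = set(df["sample"])
    for sample in sheet.sample_ids:
        if sample not in values.columns and sample in observed_samples:
            continue  # pragma: no cover
        if sample not in values.columns:
            values[sample] = float("nan")
    unknown = observed_samples - set(sheet.sample_ids)
    if unknown:
        raise FormatError(f"intensity table references unknown samples {sorted(unknown)}")
    features = (
        df[["site_id", "protein", "position"]]
        .drop_duplicates("site_id")
        .set_index("site_id")
    )
    features["position"] = features["position"].astype(int)
    features = features.loc[values.index]
    return _finalize_matrix(values, features, sheet)


def _read_wide(
    df: pd.DataFrame, wide_cols: list[str], sheet: SampleSheet
) -> IntensityMatrix:
    sample_names = [c[len("Intensity ") :] for c in wide_cols]
    ids = df["Protein"].astype(str) + ":K" + df["Position"].astype(int).astype(str)
    if ids.duplicated().any():
        raise FormatError("duplicate (Protein, Position) rows in wide intensity table")
    values = df[wide_cols].copy()
    values.columns = sample_names
    values.index = ids
    features = pd.DataFrame(
        {"protein": df["Protein"].astype(str).values, "position": df["Position"].astype(int).values},
        index=ids,
    )
    return _finalize_matrix(values, features, sheet)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write an intensity matrix in the long dialect (missing rows omitted)."""
    long = matrix.values.stack().rename("intensity").reset_index()
    long.columns = ["site_id", "sample", "intensity"]
    long = long.merge(
        matrix.features.reset_index().rename(columns={"index": "site_id"}),
        on="site_id",
    )[["site_id", "protein", "position", "sample", "intensity"]]
    write_tsv(long, path, params={"n_rows": matrix.n_rows})


@dataclass
class AnnotationTable:
    """Term → (name, category, member accessions) functional annotation map."""

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"term_id", "term_name", "category", "protein"}
        if not required.issubset(df.columns):
            raise FormatError(f"annotation table must have columns {sorted(required)}")
        bad = set(df["category"]) - set(ANNOTATION_CATEGORIES)
        if bad:
            raise FormatError(f"unknown annotation categories {sorted(bad)}")
        terms: dict[str, tuple[str, str, frozenset[str]]] = {}
        for (term_id, name, cat), grp in df.groupby(["term_id", "term_name", "category"]):
            members = frozenset(grp["protein"])
            if not members:  # pragma: no cover - groupby yields nonempty groups
                raise FormatError(f"term {term_id} has no members")
            terms[term_id] = (name, cat, members)
        return cls(terms)


def read_domain_table(path: str | Path, sequences: Mapping[str, str] | None = None):
    """Read domain coordinates: protein → list of (domain, start, end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein": str, "domain": str})
    required = {"protein", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"domain table must have columns {sorted(required)}")
    domains: dict[str, list[tuple[str, int, int]]] = {}
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if not 1 <= start <= end:
            raise FormatError(
                f"invalid domain interval [{start}, {end}] for {row['protein']}"
            )
        if sequences is not None and row["protein"] in sequences:
            if end > len(sequences[row["protein"]]):
                raise FormatError(
                    f"domain end {end} beyond length of {row['protein']}"
                )
        domains.setdefault(row["protein"], []).append((row["domain"], start, end))
    return domains


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an interaction edge list (protein_a, protein_b, combined_score)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_a", "protein_b", "combined_score"}
    if not required.issubset(df.columns):
        raise FormatError(f"edge list must have columns {sorted(required)}")
    return df[["protein_a", "protein_b", "combined_score"]]


# ---------------------------------------------------------------------------
# Bundled worked example: the nine differentially succinylated sites.

_TABLE1_RESOURCE = "table1_dss.tsv"
#: sha256 of the bundled fixture, frozen so silent edits are caught.
_TABLE1_SHA256 = "fb2cd230907e68907ca71a6b7fc1c484da876f508dbc2f46faafb4ef9bb17962"

_SITE_TOKEN = re.compile(r"^K ?(\d+)$")


def read_table1_fixture() -> pd.DataFrame:
    """Load the bundled table of nine differentially succinylated sites.

    The fixture is a verbatim transcription of the published summary table
    (accession, description, localization, protein size, full site list, the
    differential site, and its 8 h / 0 h fold change).  One printed site token
    contains a stray space ("K 171"); it is normalized to K171 and the
    normalization is logged.  Returns a DataFrame with the parsed ``sites``
    (list of int positions) and ``dss_position`` columns added.
    """
    ref = resources.files("succinylome.data").joinpath(_TABLE1_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FormatError(
            f"packaged fixture {_TABLE1_RESOURCE} checksum mismatch "
            f"(got {digest[:12]}…, expected {_TABLE1_SHA256[:12]}…)"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(raw.decode("utf-8")), sep="\t", comment="#")

    def parse_sites(tokens: str) -> list[int]:
        positions = []
        for token in tokens.split("/"):
            token = token.strip()
            m = _SITE_TOKEN.match(token)
            if m is None:
                raise FormatError(f"unparsable site token {token!r} in fixture")
            if " " in token:
                logger.info("normalized fixture site token %r to K%s", token, m.group(1))
            positions.append(int(m.group(1)))
        return positions

    df["sites"] = df["succinylated_sites"].map(parse_sites)
    df["dss_position"] = df["dss"].str.lstrip("K").astype(int)
    return df
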