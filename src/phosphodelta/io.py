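"""Reading, writing and coordinate mapping for SILAC phosphopeptide tables.

The quantification tables consumed here are the output of an upstream
database-search / quantification engine: one row per peptide and enrichment
method, carrying the heavy/light (H/L) SILAC ratio, the phosphosite positions
within the peptide, their localization probabilities, the protein accession
and the identification q-value.  Heavy is the wild type, light the mutant, so
an H/L ratio below 1 means the phosphopeptide is more abundant (the site more
phosphorylated) in the mutant.

Canonical on-disk dialect is UTF-8 TSV with a header row; CSV and xlsx are
accepted and converted on ingestion.  Columns::

    peptide  method  hl_ratio  log2_ratio  sites  probs  protein  q_value

``sites`` is a semicolon list like ``"S3;T7"`` (1-based positions within the
peptide), ``probs`` the matching semicolon list of localization
probabilities.  Either ``hl_ratio`` or ``log2_ratio`` may be omitted; the
missing one is reconstructed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

METHODS = ("SIMAC", "TiO2", "TiSH")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_PROTEIN_ALPHABET = set(AMINO_ACIDS + "X")

_REQUIRED_COLUMNS = ("peptide", "sites", "probs", "protein", "q_value")


class FormatError(ValueError):
    """A table is structurally unusable (e.g. a mandatory column is missing)."""


class MappingError(ValueError):
    """A peptide could not be located within its parent protein sequence."""


@dataclass(frozen=True)
class RowError:
    """One rejected table row, with its 1-based line number and reason."""

    line: int
    reason: str


@dataclass
class PhosphopeptideMeasurement:
    """A single peptide x enrichment-method quantification.

    ``site_positions`` are 1-based within ``sequence``; ``hl_ratio`` and
    ``log2_ratio`` are kept consistent (``log2_ratio == log2(hl_ratio)``).
    """

    sequence: str
    method: str
    hl_ratio: float
    site_positions: list[int]
    site_residues: list[str]
    localization_probs: list[float]
    protein_acc: str
    q_value: float
    log2_ratio: float = math.nan
    scan_ratios: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.method not in METHODS:
            raise ValueError(f"unknown enrichment method {self.method!r}")
        if not self.hl_ratio > 0:
            raise ValueError(f"H/L ratio must be positive, got {self.hl_ratio}")
        if math.isnan(self.log2_ratio):
            self.log2_ratio = math.log2(self.hl_ratio)
        elif abs(self.log2_ratio - math.log2(self.hl_ratio)) > 1e-9:
            raise ValueError("hl_ratio and log2_ratio disagree")
        n = len(self.site_positions)
        if not (len(self.site_residues) == len(self.localization_probs) == n):
            raise ValueError("site positions, residues and probabilities differ in length")
        for pos, res, prob in zip(
            self.site_positions, self.site_residues, self.localization_probs
        ):
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"site position {pos} outside peptide")
            if res not in "STY":
                raise ValueError(f"phosphosite residue must be S/T/Y, got {res!r}")
            if self.sequence[pos - 1] != res:
                raise ValueError(
                    f"residue at peptide position {pos} is "
                    f"{self.sequence[pos - 1]!r}, expected {res!r}"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"localization probability {prob} outside [0, 1]")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q-value {self.q_value} outside [0, 1]")

    @property
    def peptide_id(self) -> str:
        """Identity key: upper-case sequence plus sorted site positions."""
        sites = ",".join(str(p) for p in sorted(self.site_positions))
        return f"{self.sequence}|{sites}"

    def with_log2(self, new_log2: float) -> "PhosphopeptideMeasurement":
        """Copy with a shifted log2 ratio (H/L updated consistently)."""
        return replace(self, log2_ratio=new_log2, hl_ratio=2.0**new_log2)


@dataclass(frozen=True)
class ProteinSequenceRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        bad = set(self.sequence.upper()) - _VALID_PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.accession}")


@dataclass(frozen=True)
class AbundanceMeasurement:
    """One non-enriched (whole extract) peptide H/L ratio."""

    peptide_id: str
    protein_acc: str
    hl_ratio: float

    def __post_init__(self) -> None:
        if not self.hl_ratio > 0:
            raise ValueError("H/L ratio must be positive")


@dataclass(frozen=True, order=True)
class ProteinSite:
    """A phosphosite in protein coordinates (1-based)."""

    protein_acc: str
    position: int
    residue: str


def _split_sites(sites_field: str, probs_field: str):
    positions, residues = [], []
    for token in str(sites_field).split(";"):
        token = token.strip()
        if not token:
            continue
        residues.append(token[0].upper())
        positions.append(int(token[1:]))
    probs = [float(t) for t in str(probs_field).split(";") if t.strip() != ""]
    return positions, residues, probs


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_quant_table(
    path: str | Path,
    method_label: str,
    *,
    assume_localized: bool = False,
) -> tuple[list[PhosphopeptideMeasurement], list[RowError]]:
    """Parse one quantification table into measurements.

    Returns ``(records, errors)``; malformed rows are reported in ``errors``
    with their 1-based data line number and never abort the parse.  A missing
    mandatory column aborts with :class:`FormatError`.  If only a
    ``log2_ratio`` column is present, H/L is reconstructed as ``2**log2``.
    Rows without localization probabilities are dropped unless
    ``assume_localized`` is set, in which case every site gets probability 1.0
    (with a warning).
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col == "probs" and assume_localized and "probs" not in df.columns:
            continue
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    has_hl = "hl_ratio" in df.columns
    has_log2 = "log2_ratio" in df.columns
    if not (has_hl or has_log2):
        raise FormatError(f"need an 'hl_ratio' or 'log2_ratio' column in {path}")

    records: list[PhosphopeptideMeasurement] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            hl = float(row["hl_ratio"]) if has_hl and pd.notna(row.get("hl_ratio")) else None
            log2 = (
                float(row["log2_ratio"])
                if has_log2 and pd.notna(row.get("log2_ratio"))
                else None
            )
            if hl is None and log2 is None:
                raise ValueError("no ratio value")
            if hl is None:
                hl = 2.0**log2
            if log2 is None:
                log2 = math.log2(hl) if hl > 0 else math.nan
            probs_field = row.get("probs")
            if probs_field is None or (
                isinstance(probs_field, float) and math.isnan(probs_field)
            ):
                if not assume_localized:
                    raise ValueError("missing localization probabilities")
                positions, residues, _ = _split_sites(row["sites"], "")
                probs = [1.0] * len(positions)
                log.warning("line %d: assuming full localization", i)
            else:
                positions, residues, probs = _split_sites(row["sites"], probs_field)
            records.append(
                PhosphopeptideMeasurement(
                    sequence=str(row["peptide"]),
                    method=method_label,
                    hl_ratio=hl,
                    log2_ratio=log2,
                    site_positions=positions,
                    site_residues=residues,
                    localization_probs=probs,
                    protein_acc=str(row["protein"]),
                    q_value=float(row["q_value"]),
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(RowError(line=i, reason=str(exc)))
    return records, errors


def write_quant_table(records: Iterable[PhosphopeptideMeasurement], path: str | Path) -> None:
    """Serialize measurements back to the canonical TSV dialect."""
    rows = []
    for m in records:
        rows.append(
            {
                "peptide": m.sequence,
                "method": m.method,
                "hl_ratio": repr(m.hl_ratio),
                "log2_ratio": repr(m.log2_ratio),
                "sites": ";".join(
                    f"{r}{p}" for r, p in zip(m.site_residues, m.site_positions)
                ),
                "probs": ";".join(repr(p) for p in m.localization_probs),
                "protein": m.protein_acc,
                "q_value": repr(m.q_value),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "peptide", "method", "hl_ratio", "log2_ratio",
            "sites", "probs", "protein", "q_value",
        ],
    ).to_csv(path, sep="\t", index=False)


def filter_high_confidence(
    records: Sequence[PhosphopeptideMeasurement], q_max: float = 0.01
) -> list[PhosphopeptideMeasurement]:
    """Keep identifications at or below the q-value cutoff (FDR control)."""
    return [m for m in records if m.q_value <= q_max]


def filter_localization(
    records: Sequence[PhosphopeptideMeasurement], min_prob: float = 0.75
) -> list[PhosphopeptideMeasurement]:
    """Keep records whose every site is localized with probability >= min_prob."""
    return [
        m for m in records if all(p >= min_prob for p in m.localization_probs)
    ]


def read_fasta(path: str | Path) -> dict[str, ProteinSequenceRecord]:
    """Read a protein FASTA into an accession -> record map.

    The accession is the first whitespace-delimited word of the header.
    Duplicate accessions and empty files are errors.
    """
    proteins: dict[str, ProteinSequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in proteins:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        proteins[acc] = ProteinSequenceRecord(accession=acc, sequence=str(rec.seq).upper())
    if not proteins:
        raise FormatError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Mapping[str, ProteinSequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc in proteins:
            seq = proteins[acc].sequence
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def map_sites_to_protein(
    m: PhosphopeptideMeasurement,
    proteins: Mapping[str, ProteinSequenceRecord],
) -> list[ProteinSite]:
    """Map peptide-level phosphosites to 1-based protein coordinates.

    The peptide is located by exact substring search in its parent protein;
    if it occurs more than once the first occurrence is used and a warning is
    logged.  Absolute position = peptide offset + site position - 1.
    """
    if m.protein_acc not in proteins:
        raise MappingError(f"protein {m.protein_acc!r} not in proteome")
    protein = proteins[m.protein_acc]
    offset = protein.sequence.find(m.sequence)
    if offset < 0:
        raise MappingError(
            f"peptide {m.sequence!r} not found in protein {m.protein_acc!r}"
        )
    if protein.sequence.find(m.sequence, offset + 1) >= 0:
        log.warning(
            "peptide %s occurs more than once in %s; using first occurrence",
            m.sequence, m.protein_acc,
        )
    return [
        ProteinSite(protein_acc=m.protein_acc, position=offset + pos, residue=res)
        for pos, res in zip(m.site_positions, m.site_residues)
    ]


def unique_sites(
    records: Iterable[PhosphopeptideMeasurement],
    proteins: Mapping[str, ProteinSequenceRecord],
) -> set[ProteinSite]:
    """The set of distinct protein-coordinate phosphosites across records."""
    sites: set[ProteinSite] = set()
    for m in records:
        sites.update(map_sites_to_protein(m, proteins))
    return sites


def read_abundance_table(path: str | Path) -> list[AbundanceMeasurement]:
    """Read the non-enriched (whole extract) peptide abundance table.

    Columns: ``peptide``, ``protein``, ``hl_ratio``.
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("peptide", "protein", "hl_ratio"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    return [
        AbundanceMeasurement(
            peptide_id=str(r.peptide), protein_acc=str(r.protein), hl_ratio=float(r.hl_ratio)
        )
        for r in df.itertuples(index=False)
    ]
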