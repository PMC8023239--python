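"""Readers/writers for the pipeline's on-disk formats and core containers.

Formats are deliberately plain: a 12-column tabular similarity-hit table
(the de facto interchange dialect of all-vs-all nucleotide searches), a
contig catalog (id, length), an integer count matrix (contig x sample),
and a study-metadata table. RPKM is always computed internally from raw
counts so that normalization provenance is single-sourced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the 12-column tabular hit dialect, in order.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

ROLES = ("donor", "control", "non_responder", "responder")
RECIPIENT_ROLES = ("control", "non_responder", "responder")
TREATED_ROLES = ("non_responder", "responder")


class FormatError(ValueError):
    """A file violated its declared dialect or an invariant."""


# ---------------------------------------------------------------------------
# AbundanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """A non-negative (contig or HV-group) x sample matrix with a unit.

    Parameters
    ----------
    values
        DataFrame, rows indexed by contig/HV ids, columns by sample ids.
    unit
        One of ``raw_count``, ``rpkm``, ``relative``.
    lengths
        Per-row lengths in bp; required when ``unit == "raw_count"`` if RPKM
        is to be computed downstream.
    """

    values: pd.DataFrame
    unit: str = "raw_count"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("raw_count", "rpkm", "relative"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate row ids in abundance matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in abundance matrix")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative abundance at row {self.values.index[i]!r}, "
                f"column {self.values.columns[j]!r}"
            )
        if self.unit == "relative" and arr.size:
            sums = arr.sum(axis=0)
            bad = np.abs(sums[sums > 0] - 1.0) > 1e-9
            if bad.any():
                raise FormatError("relative-abundance columns must sum to 1")
        if self.lengths is not None:
            missing = self.values.index.difference(self.lengths.index)
            if len(missing):
                raise FormatError(f"lengths missing for rows: {sorted(missing)[:5]}")
            self.lengths = self.lengths.loc[self.values.index].astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame, unit: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values, unit or self.unit, self.lengths)


# ---------------------------------------------------------------------------
# StudyDesign
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Subjects, roles, donor pairing, week schedule and clinical outcome.

    ``samples`` has one row per sequenced sample with columns
    ``sample_id, subject_id, role, paired_donor_id, week``; ``rd_increase_pct``
    maps recipient subjects to their percent increase in glucose disappearance
    rate (Rd), the trial's insulin-sensitivity outcome.
    """

    samples: pd.DataFrame
    rd_increase_pct: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "role", "paired_donor_id", "week"}
        missing = required - set(self.samples.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown roles: {sorted(bad_roles)}")
        if self.samples.duplicated(["subject_id", "week"]).any():
            row = self.samples[self.samples.duplicated(["subject_id", "week"])].iloc[0]
            raise FormatError(
                f"subject {row.subject_id!r} sampled twice at week {row.week}"
            )
        roles = self.roles
        donors = {s for s, r in roles.items() if r == "donor"}
        for subj, role in roles.items():
            pairing = self._pairings().get(subj)
            if role in TREATED_ROLES:
                if pairing is None:
                    raise FormatError(f"treated recipient {subj!r} lacks paired_donor_id")
                if pairing not in donors:
                    raise FormatError(
                        f"recipient {subj!r} paired with {pairing!r}, not a donor"
                    )
            elif pairing is not None:
                raise FormatError(f"{role} {subj!r} must not have a paired donor")

    def _pairings(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {}
        for _, row in self.samples.iterrows():
            d = row["paired_donor_id"]
            if pd.isna(d) or d in ("", None):
                d = None
            prev = out.get(row["subject_id"], d)
            if prev != d and row["subject_id"] in out:
                raise FormatError(f"inconsistent pairing for subject {row['subject_id']!r}")
            out[row["subject_id"]] = d
        return out

    @property
    def roles(self) -> dict[str, str]:
        return dict(zip(self.samples["subject_id"], self.samples["role"]))

    def subjects(self, role: str | Iterable[str] | None = None) -> list[str]:
        roles = [role] if isinstance(role, str) else (list(role) if role else list(ROLES))
        seen: list[str] = []
        for _, row in self.samples.iterrows():
            if row["role"] in roles and row["subject_id"] not in seen:
                seen.append(row["subject_id"])
        return seen

    def donor_of(self, subject: str) -> str | None:
        return self._pairings().get(subject)

    def sample_id(self, subject: str, week: int) -> str | None:
        hit = self.samples[
            (self.samples["subject_id"] == subject) & (self.samples["week"] == week)
        ]
        return None if hit.empty else hit["sample_id"].iloc[0]

    def weeks_of(self, subject: str) -> list[int]:
        return sorted(self.samples.loc[self.samples["subject_id"] == subject, "week"])

    def responder_flags(self, threshold: float = 10.0) -> pd.Series:
        """Responder = >``threshold``% increase in Rd (trial definition)."""
        return self.rd_increase_pct > threshold


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tabular hit table into a validated DataFrame."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str}, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if df.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 columns, found {df.shape[1]}")
    int_cols = {"length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"}
    for col in HIT_COLUMNS[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise FormatError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = vals.astype(np.int64 if col in int_cols else float)
    if (df["evalue"] < 0).any():
        line = int(df.index[df["evalue"] < 0][0]) + 1
        raise FormatError(f"{path}: negative e-value at line {line}")
    if (df["length"] < 1).any():
        line = int(df.index[df["length"] < 1][0]) + 1
        raise FormatError(f"{path}: alignment length < 1 at line {line}")
    return df


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.loc[:, HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False,
                                    float_format="%.17g")


# ---------------------------------------------------------------------------
# Contig catalog
# ---------------------------------------------------------------------------

def read_contigs(path: str | Path) -> pd.Series:
    """Read the contig catalog, returning lengths (bp) indexed by contig id."""
    df = pd.read_csv(path, sep="\t")
    if not {"contig_id", "length"} <= set(df.columns):
        raise FormatError(f"{path}: need columns contig_id, length")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise FormatError(f"{path}: duplicate contig id {dup!r}")
    lengths = pd.to_numeric(df["length"], errors="coerce")
    if lengths.isna().any() or (lengths <= 0).any():
        raise FormatError(f"{path}: contig lengths must be positive integers")
    index = pd.Index(df["contig_id"].astype(str))
    index.name = None
    return pd.Series(lengths.to_numpy(dtype=float), index=index, name="length")


def write_contigs(lengths: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"contig_id": lengths.index, "length": lengths.astype(int).values})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, lengths: pd.Series | None = None) -> AbundanceMatrix:
    """Read an integer contig x sample count matrix (first column = contig id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = vals.index[vals.isna()][0]
            raise FormatError(f"{path}: non-numeric count at row {row!r}, column {col!r}")
        if (vals < 0).any():
            row = vals.index[vals < 0][0]
            raise FormatError(f"{path}: negative count at row {row!r}, column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = vals.index[~np.isclose(vals, np.round(vals))][0]
            raise FormatError(f"{path}: non-integer count at row {row!r}, column {col!r}")
        df[col] = vals.astype(np.int64)
    return AbundanceMatrix(df, unit="raw_count", lengths=lengths)


def write_counts(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("contig_id").to_csv(path, sep="\t")


def write_matrix(values: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    """Write a real-valued matrix with a stable float format (byte-reproducible)."""
    values.rename_axis(index_name).to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "role", "paired_donor_id", "week"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(int)
    rd = pd.Series(dtype=float)
    if "rd_increase_pct" in df.columns:
        per_subject = df.dropna(subset=["rd_increase_pct"]).drop_duplicates("subject_id")
        rd = pd.Series(per_subject["rd_increase_pct"].to_numpy(dtype=float),
                       index=per_subject["subject_id"].to_numpy())
    design = StudyDesign(df[sorted(required)].copy(), rd)
    return design


def write_metadata(design: StudyDesign, path: str | Path) -> None:
    df = design.samples.copy()
    df["rd_increase_pct"] = df["subject_id"].map(design.rd_increase_pct)
    cols = ["sample_id", "subject_id", "role", "paired_donor_id", "week", "rd_increase_pct"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Misc small formats
# ---------------------------------------------------------------------------

def read_flags(path: str | Path) -> set[str]:
    """Read a one-id-per-line flag list (e.g. contigs with 16S rDNA hits)."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_flags(flags: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in sorted(flags)))


def read_taxa(path: str | Path) -> dict[str, str]:
    """Read a contig -> taxon marker-gene call table (contig_id, taxon)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"contig_id", "taxon"} <= set(df.columns):
        raise FormatError(f"{path}: need columns contig_id, taxon")
    return dict(zip(df["contig_id"], df["taxon"]))


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
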