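"""Readers and writers for the tabular and sequence formats the pipeline touches.

In-memory containers are plain pandas objects, in the style of most
genomics tooling:

* ``CountMatrix``   — ``DataFrame`` of non-negative integers, peptides x samples,
  index ``peptide_id``, columns ``sample_id``.
* ``PeptideLibrary`` — ``DataFrame`` indexed by ``peptide_id`` with columns
  ``gene_id``, ``protein_name``, ``start_pos`` (0-based residue offset of the
  fragment in its full-length protein) and ``aa_seq``.
* ``SampleSheet``   — ``DataFrame`` indexed by ``sample_id`` with a ``role``
  column (one of ``pre_control``, ``comparator``, ``case``, ``mock_ip``),
  boolean phenotype flags in columns prefixed ``phenotype_`` and free-form
  covariate columns (e.g. ``sex``, ``hiv_status``).
* ``Proteome``      — ``DataFrame`` indexed by ``protein_id`` with columns
  ``description`` and ``aa_seq``; read from / written to FASTA.

All tabular files are plain text with a header row; the delimiter is chosen
from the extension (``.csv`` → comma, anything else → tab).  Writers prepend a
``#`` comment line recording the tool version and the writing function so every
artifact is self-describing; readers skip ``#`` lines.
"""

from __future__ import annotations

import io as _stdio
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ConsistencyError, FormatError

ROLES = frozenset({"pre_control", "comparator", "case", "mock_ip"})
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PHENOTYPE_PREFIX = "phenotype_"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _comment(what: str) -> str:
    return f"# phipkit {__version__} | {what}\n"


def _read_table(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype={index_col: str})
    if index_col not in df.columns:
        raise FormatError(f"{path}: missing required first column '{index_col}'")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate {index_col} '{dup}'")
    return df.set_index(index_col)


def _write_table(df: pd.DataFrame, path, what: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment(what))
        df.to_csv(fh, sep=_sep_for(path))


# ---------------------------------------------------------------- count matrix

def read_counts(path) -> pd.DataFrame:
    """Read a peptide x sample read-count matrix.

    First column is ``peptide_id``; remaining header entries are sample ids.
    Cells must be non-negative integers; duplicates in either axis are
    rejected with a :class:`FormatError` naming the offender.
    """
    df = _read_table(path, "peptide_id")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in header")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: cell ({row}, {col}) is not a non-negative integer"
            )
    return df.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    if (counts.to_numpy() < 0).any():
        raise FormatError("count matrix contains negative values")
    df = counts.copy()
    df.index.name = "peptide_id"
    _write_table(df, path, "read counts (peptides x samples)")


def read_matrix(path) -> pd.DataFrame:
    """Read a derived float matrix (gene percentages, fold change, z scores).

    Same layout as a count matrix but values are floats; scientific notation
    is accepted.  The first column header names the row axis (e.g. ``gene_id``).
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    df = pd.read_csv(_stdio.StringIO("".join(lines)), sep=_sep_for(path))
    idx = df.columns[0]
    if df[idx].duplicated().any():
        raise FormatError(f"{path}: duplicate {idx}")
    return df.set_index(idx).astype(float)


def write_matrix(matrix: pd.DataFrame, path, what: str = "derived matrix") -> None:
    df = matrix.copy()
    if df.index.name is None:
        df.index.name = "gene_id"
    _write_table(df, path, what)


# --------------------------------------------------------------- peptide library

_LIBRARY_COLS = ("gene_id", "protein_name", "start_pos", "aa_seq")


def _clean_seq(seq: str, where: str) -> str:
    """Uppercase; map letters outside the 20-letter alphabet to X, warning once."""
    seq = seq.upper()
    cleaned = []
    replaced = set()
    for ch in seq:
        if ch in AA_ALPHABET or ch == "X":
            cleaned.append(ch)
        else:
            replaced.add(ch)
            cleaned.append("X")
    if replaced:
        warnings.warn(
            f"{where}: unknown residue letter(s) {sorted(replaced)} mapped to X"
        )
    return "".join(cleaned)


def read_library(path) -> pd.DataFrame:
    """Read a peptide library annotation table.

    Columns: ``peptide_id``, ``gene_id``, ``protein_name``, ``start_pos``
    (0-based), ``aa_seq``.
    """
    df = _read_table(path, "peptide_id")
    missing = [c for c in _LIBRARY_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: library missing column(s) {missing}")
    df = df[list(_LIBRARY_COLS)].copy()
    df["start_pos"] = pd.to_numeric(df["start_pos"], errors="coerce")
    if df["start_pos"].isna().any() or (df["start_pos"] < 0).any():
        raise FormatError(f"{path}: start_pos must be a non-negative integer")
    df["start_pos"] = df["start_pos"].astype(int)
    df["aa_seq"] = [
        _clean_seq(str(s), f"{path} peptide {pid}")
        for pid, s in df["aa_seq"].items()
    ]
    return df


def write_library(library: pd.DataFrame, path) -> None:
    df = library.copy()
    df.index.name = "peptide_id"
    _write_table(df, path, "peptide library (peptide -> gene/protein, 0-based start_pos)")


# ----------------------------------------------------------------- sample sheet

def read_samplesheet(path) -> pd.DataFrame:
    """Read the sample sheet.

    Columns: ``sample_id``, ``role`` (``pre_control`` / ``comparator`` /
    ``case`` / ``mock_ip``), any number of boolean ``phenotype_*`` flag
    columns, and any other columns treated as covariates.
    """
    df = _read_table(path, "sample_id")
    if "role" not in df.columns:
        raise FormatError(f"{path}: sample sheet missing 'role' column")
    bad = set(df["role"]) - ROLES
    if bad:
        raise FormatError(
            f"{path}: unknown role token(s) {sorted(bad)}; expected one of {sorted(ROLES)}"
        )
    for col in df.columns:
        if col.startswith(PHENOTYPE_PREFIX):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or not vals.isin([0, 1]).all():
                raise FormatError(f"{path}: phenotype column '{col}' must be 0/1")
            df[col] = vals.astype(bool)
    return df


def write_samplesheet(sheet: pd.DataFrame, path) -> None:
    df = sheet.copy()
    df.index.name = "sample_id"
    for col in df.columns:
        if col.startswith(PHENOTYPE_PREFIX):
            df[col] = df[col].astype(int)
    _write_table(df, path, "sample sheet (role, phenotype_* flags, covariates)")


def phenotype_labels(sheet: pd.DataFrame) -> list[str]:
    """Phenotype labels present in the sheet (without the column prefix)."""
    return [
        c[len(PHENOTYPE_PREFIX):]
        for c in sheet.columns
        if c.startswith(PHENOTYPE_PREFIX)
    ]


# --------------------------------------------------------------------- proteome

def read_proteome(path) -> pd.DataFrame:
    """Read a protein FASTA into a DataFrame indexed by ``protein_id``."""
    ids, descs, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        descs.append(rec.description)
        seqs.append(_clean_seq(str(rec.seq), f"{path} record {rec.id}"))
    if not ids:
        raise FormatError(f"{path}: no FASTA records found")
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate protein ids in FASTA")
    if any(len(s) == 0 for s in seqs):
        raise FormatError(f"{path}: empty sequence in FASTA")
    return pd.DataFrame(
        {"description": descs, "aa_seq": seqs},
        index=pd.Index(ids, name="protein_id"),
    )


def write_proteome(proteome: pd.DataFrame, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(row.aa_seq), id=str(pid), description="")
        for pid, row in proteome.iterrows()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ----------------------------------------------------------------- ground truth

def write_ground_truth(truth, path) -> None:
    """Write planted-antigen reactivity as tabular text (antigen, sample_id, reactive)."""
    df = truth.to_frame()
    with open(path, "w") as fh:
        fh.write(_comment("simulation ground truth (antigen, sample_id, reactive)"))
        df.to_csv(fh, sep=_sep_for(path), index=False)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype={"antigen": str, "sample_id": str})
    need = {"antigen", "sample_id", "reactive"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: ground truth needs columns {sorted(need)}")
    df["reactive"] = df["reactive"].astype(bool)
    return df


# ------------------------------------------------------------------ consistency

def validate_consistency(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    samplesheet: pd.DataFrame,
    require_mock_ip: bool = True,
    require_pre_control: bool = True,
) -> None:
    """Cross-validate the three core inputs; raise :class:`ConsistencyError` on mismatch."""
    orphans = counts.index.difference(library.index)
    if len(orphans):
        raise ConsistencyError(
            f"peptide(s) in counts absent from library: {list(orphans[:5])}"
        )
    missing = counts.columns.difference(samplesheet.index)
    if len(missing):
        raise ConsistencyError(
            f"sample(s) in counts absent from sample sheet: {list(missing[:5])}"
        )
    roles = samplesheet.loc[counts.columns, "role"]
    if require_mock_ip and not (roles == "mock_ip").any():
        raise ConsistencyError("no mock_ip samples: fold-change over mock IP needs >= 1")
    if require_pre_control and not (roles == "pre_control").any():
        raise ConsistencyError("no pre_control samples: z-scoring needs a reference cohort")
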