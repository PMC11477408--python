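"""Readers and writers for the formats every pipeline stage touches.

Sequences travel as FASTA (nucleotide, protein, or aligned protein),
expression as a tab-separated TPM table (transcript x sample), and the
clinical cohort as two tab-separated tables: specific-IgE concentrations
(subject x analyte, kUA/L) and oral-food-challenge outcomes (subject,
fish, allergic/tolerant).  All tables are UTF-8, tab-separated, with a
'.' decimal point; parsing is locale-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
ALIGNED_PROTEIN_ALPHABET = PROTEIN_ALPHABET | {"-"}

_ALPHABETS = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
    "aligned-protein": ALIGNED_PROTEIN_ALPHABET,
}

OFC_LABELS = frozenset({"allergic", "tolerant", "untested"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record: unique id, free-text description, residues."""

    id: str
    description: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AllergenRecord:
    """A reference allergen protein with its name and source organism."""

    id: str
    name: str
    organism: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CohortTable:
    """Subject x analyte sIgE values (kUA/L) joined with OFC outcomes.

    ``sige`` is indexed by subject with one column per analyte.  ``ofc``
    is indexed by subject with one column per challenged fish, each cell
    one of {"allergic", "tolerant", "untested"}.
    """

    sige: pd.DataFrame
    ofc: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def subjects(self) -> list[str]:
        return list(self.sige.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.sige.columns)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file, validating ids and the declared alphabet.

    Parameters
    ----------
    path:
        FASTA file.  An empty file yields an empty list with a warning.
    alphabet:
        "nucleotide", "protein" or "aligned-protein".  For
        "aligned-protein" all records must have equal length and gaps
        ('-') are legal.

    Raises
    ------
    FormatError
        On duplicate record ids, illegal characters (the error names the
        record and 1-based position), or a ragged alignment.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}; expected one of {sorted(_ALPHABETS)}")
    allowed = _ALPHABETS[alphabet]
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"{path}: record {rec.id!r} position {pos}: "
                    f"character {ch!r} not in {alphabet} alphabet"
                )
        records.append(SequenceRecord(id=rec.id, description=rec.description, seq=seq))
    if not records:
        logger.warning("%s: FASTA file contains no records", path)
    if alphabet == "aligned-protein" and records:
        width = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != width:
                raise FormatError(
                    f"{path}: ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {width}"
                )
    return records


def write_fasta(records: list[SequenceRecord] | list[AllergenRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines to ``width`` columns."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = getattr(rec, "description", "") or rec.id
            if isinstance(rec, AllergenRecord):
                header = f"{rec.id}|{rec.name}|{rec.organism}"
            elif not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def load_allergen_db(path: str | Path, metadata: str | Path | None = None) -> list[AllergenRecord]:
    """Load a reference allergen protein FASTA.

    Headers of the form ``ID|allergen_name|source_organism`` are parsed
    directly; plain ids require a sidecar tab-separated ``metadata``
    table with columns ``id``, ``allergen_name``, ``organism`` (covers
    arbitrary database exports whose header layout is unknown).
    """
    records = read_fasta(path, alphabet="protein")
    meta: dict[str, tuple[str, str]] = {}
    if metadata is not None:
        mtab = pd.read_csv(metadata, sep="\t", dtype=str)
        required = {"id", "allergen_name", "organism"}
        if not required.issubset(mtab.columns):
            raise FormatError(f"{metadata}: sidecar metadata needs columns {sorted(required)}")
        meta = {r["id"]: (r["allergen_name"], r["organism"]) for _, r in mtab.iterrows()}
    out: list[AllergenRecord] = []
    for rec in records:
        if "|" in rec.id:
            # the organism field may contain spaces, so parse the full
            # header line, not the whitespace-truncated id token
            parts = rec.description.split("|")
            if len(parts) != 3:
                raise FormatError(
                    f"allergen header {rec.description!r} must be 'ID|allergen_name|organism'"
                )
            acc, name, organism = (p.strip() for p in parts)
        elif rec.id in meta:
            acc = rec.id
            name, organism = meta[rec.id]
        else:
            raise FormatError(
                f"allergen {rec.id!r}: header carries no name/organism and no "
                "sidecar metadata row was found"
            )
        out.append(AllergenRecord(id=acc, name=name, organism=organism, seq=rec.seq))
    return out


def read_tpm_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript x sample TPM table (tab-separated, header row).

    Returns a float DataFrame indexed by transcript id.  Negative or
    non-numeric cells and duplicated transcript ids are hard errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate transcript ids {dups}")
    if raw.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample columns")
    if len(raw.columns) == 0:
        raise FormatError(f"{path}: no sample columns found")
    try:
        table = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            for tid, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric TPM {cell!r} at transcript {tid!r}, sample {col!r}"
                    ) from None
        raise
    if table.isna().any().any():
        raise FormatError(f"{path}: missing TPM cells")
    if (table < 0).any().any():
        bad = table[(table < 0).any(axis=1)].index[0]
        raise FormatError(f"{path}: negative TPM value at transcript {bad!r}")
    return table


def write_tpm_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6f")


def read_cohort(sige_path: str | Path, ofc_path: str | Path | None = None) -> CohortTable:
    """Read the cohort sIgE table and (optionally) OFC outcomes.

    The sIgE table is subject x analyte in kUA/L.  The OFC table is long
    format with columns ``subject``, ``fish``, ``outcome``; subjects
    present in the sIgE table but absent from the OFC table are marked
    "untested" for every challenged fish.
    """
    sige_path = Path(sige_path)
    raw = pd.read_csv(sige_path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        raise FormatError(f"{sige_path}: duplicate subject ids")
    try:
        sige = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"{sige_path}: non-numeric sIgE cell ({exc})") from None
    if (sige < 0).any().any():
        raise FormatError(f"{sige_path}: negative sIgE value")
    sige.index = sige.index.astype(str)

    if ofc_path is None:
        return CohortTable(sige=sige)

    ofc_long = pd.read_csv(ofc_path, sep="\t", dtype=str)
    required = {"subject", "fish", "outcome"}
    if not required.issubset(ofc_long.columns):
        raise FormatError(f"{ofc_path}: OFC table needs columns {sorted(required)}")
    bad_labels = set(ofc_long["outcome"]) - {"allergic", "tolerant"}
    if bad_labels:
        raise FormatError(
            f"{ofc_path}: OFC outcome labels {sorted(bad_labels)} not in "
            "{'allergic', 'tolerant'}"
        )
    unknown = set(ofc_long["subject"]) - set(sige.index)
    if unknown:
        raise FormatError(f"{ofc_path}: OFC subjects {sorted(unknown)} not in sIgE table")
    fishes = sorted(ofc_long["fish"].unique())
    ofc = pd.DataFrame("untested", index=sige.index, columns=fishes)
    for _, row in ofc_long.iterrows():
        ofc.loc[row["subject"], row["fish"]] = row["outcome"]
    return CohortTable(sige=sige, ofc=ofc)


def write_cohort(cohort: CohortTable, sige_path: str | Path, ofc_path: str | Path | None = None) -> None:
    cohort.sige.to_csv(sige_path, sep="\t", index_label="subject", float_format="%.4f")
    if ofc_path is not None and not cohort.ofc.empty:
        rows = []
        for subject in cohort.ofc.index:
            for fish in cohort.ofc.columns:
                label = cohort.ofc.loc[subject, fish]
                if label != "untested":
                    rows.append({"subject": subject, "fish": fish, "outcome": label})
        pd.DataFrame(rows, columns=["subject", "fish", "outcome"]).to_csv(
            ofc_path, sep="\t", index=False
        )
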