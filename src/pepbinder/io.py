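"""Input/output for the formats the pipeline touches.

Peptide lists travel as FASTA or TSV tables; raw phage-display selections
arrive as FASTQ (plain or gzipped, Phred+33).  Displayed peptides are
recovered from reads by locating the vector flanks around the randomized
insert and translating it with the standard genetic code.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
MAX_PEPTIDE_LENGTH = 50

LABELS = ("positive", "negative", "unknown")


class PeptideValidationError(ValueError):
    """A sequence violates the peptide contract (alphabet or length)."""


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


def validate_peptide_seq(seq: str, record: str = "") -> str:
    """Upper-case and validate a peptide sequence.

    Only the 20 standard amino-acid letters are accepted (X/B/Z and other
    ambiguity codes are rejected), and length must be between 1 and 50
    residues — the inclusion criterion used for library peptides.
    """
    s = seq.upper().strip()
    where = f" in record {record!r}" if record else ""
    if not s:
        raise PeptideValidationError(f"empty peptide sequence{where}")
    if len(s) > MAX_PEPTIDE_LENGTH:
        raise PeptideValidationError(
            f"peptide longer than {MAX_PEPTIDE_LENGTH} residues{where}: length {len(s)}"
        )
    bad = set(s) - _AA_SET
    if bad:
        raise PeptideValidationError(
            f"illegal residue(s) {sorted(bad)}{where}: only the 20 standard amino acids are allowed"
        )
    return s


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an identifier and optional label."""

    id: str
    seq: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", validate_peptide_seq(self.seq, self.id))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, DNA over {A,C,G,T,N}, per-base Phred scores."""

    id: str
    dna: str
    qual: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.dna):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qual)} != sequence length {len(self.dna)}"
            )


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read a FASTA file of peptides; order preserved, sequences upper-cased."""
    peptides = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Bio raises on gross syntax errors
        raise ParseError(f"{path}: {exc}") from exc
    for rec in records:
        peptides.append(Peptide(id=rec.id, seq=str(rec.seq)))
    return peptides


def write_fasta(path: str | Path, peptides: Iterable[Peptide]) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.seq}\n")


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a Sanger-encoded (Phred+33) FASTQ file.

    Accepts plain or gzip-compressed input.  A truncated trailing block
    raises :class:`ParseError` naming the record index reached.
    """
    idx = 0
    with _open_maybe_gz(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {idx} ({title.split()[0]}): sequence/quality length mismatch"
                    )
                yield ReadRecord(
                    id=title.split()[0],
                    dna=seq.upper(),
                    qual=tuple(ord(c) - 33 for c in qual),
                )
                idx += 1
        except ValueError as exc:
            raise ParseError(f"{path}: near record {idx}: {exc}") from exc


def extract_insert(
    read: ReadRecord, flank5: str, flank3: str, insert_nt: int
) -> str | None:
    """Extract the randomized insert between exact vector flank matches.

    Returns the ``insert_nt`` bases following the first occurrence of
    ``flank5`` provided ``flank3`` follows at exactly the expected offset,
    or ``None`` when the flanks are absent, mis-spaced, or the insert
    contains an N.  Matching is exact — reads lost to sequencing errors in
    the flanks are tolerated by the downstream enrichment statistics.
    """
    if insert_nt <= 0 or insert_nt % 3:
        raise ValueError(f"insert_nt must be positive and divisible by 3, got {insert_nt}")
    if not flank5 or not flank3:
        raise ValueError("flank sequences must be non-empty")
    dna = read.dna
    i = dna.find(flank5.upper())
    if i < 0:
        return None
    start = i + len(flank5)
    end = start + insert_nt
    if not dna.startswith(flank3.upper(), end):
        return None
    insert = dna[start:end]
    if "N" in insert:
        return None
    return insert


def translate_insert(dna: str) -> str | None:
    """Translate an insert with the standard genetic code.

    Returns ``None`` if any codon is a stop or is ambiguous; raises if the
    length is not a multiple of 3.
    """
    if len(dna) % 3:
        raise ValueError(f"insert length {len(dna)} not divisible by 3")
    dna = dna.upper()
    if set(dna) - set("ACGT"):
        return None
    pep = str(Seq(dna).translate())
    if "*" in pep:
        return None
    return pep


def extract_peptides(
    fastq_path: str | Path,
    flank5: str,
    flank3: str,
    insert_nt: int = 36,
    min_mean_phred: float = 20.0,
) -> tuple[list[str], dict]:
    """Full read → peptide extraction for one sample.

    Reads failing flank matching, insert quality (mean Phred below
    ``min_mean_phred`` over the insert), or translation (stop codons,
    ambiguous bases) are skipped and tallied in the returned summary.
    """
    peptides: list[str] = []
    summary = {"total": 0, "no_flank": 0, "low_quality": 0, "untranslatable": 0, "accepted": 0}
    for read in read_fastq(fastq_path):
        summary["total"] += 1
        insert = extract_insert(read, flank5, flank3, insert_nt)
        if insert is None:
            summary["no_flank"] += 1
            continue
        start = read.dna.find(flank5.upper()) + len(flank5)
        qual = read.qual[start : start + insert_nt]
        if qual and sum(qual) / len(qual) < min_mean_phred:
            summary["low_quality"] += 1
            continue
        pep = translate_insert(insert)
        if pep is None:
            summary["untranslatable"] += 1
            continue
        peptides.append(pep)
        summary["accepted"] += 1
    return peptides, summary


_TABLE_REQUIRED = ("id", "seq")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV peptide table with columns (id, seq[, label, score, ...]).

    Sequences are validated; a missing ``label`` column defaults to
    ``unknown``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if "label" not in df.columns:
        df["label"] = "unknown"
    df["seq"] = [validate_peptide_seq(s, r) for s, r in zip(df["seq"], df["id"])]
    return df


def write_peptide_table(path: str | Path, rows: pd.DataFrame | list[Peptide]) -> None:
    if isinstance(rows, list):
        rows = pd.DataFrame(
            {"id": [p.id for p in rows], "seq": [p.seq for p in rows], "label": [p.label for p in rows]}
        )
    rows.to_csv(path, sep="\t", index=False)


def table_to_peptides(df: pd.DataFrame) -> list[Peptide]:
    return [Peptide(id=r.id, seq=r.seq, label=getattr(r, "label", "unknown")) for r in df.itertuples()]
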