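"""Readers and writers for sequencing inputs and the collapsed-read model.

All sequences are held in a single canonical RNA alphabet: uppercase,
with T converted to U on input.  Transcriptomes supplied in the DNA
alphabet are converted on read, so downstream matching never has to
compare mixed alphabets.

Small-RNA and degradome samples are stored non-redundantly as a
:class:`ReadSet`: one entry per distinct sequence with the summed
abundance of all reads carrying it.  The collapsed-FASTA dialect
``>label_COUNT`` (the final underscore-delimited integer is the read
count) is understood on input and produced on output; a header without
a numeric suffix contributes abundance 1, so plain FASTA also parses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple
import warnings

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

__all__ = [
    "ParseError",
    "SchemaError",
    "Read",
    "ReadKind",
    "ReadSet",
    "MirnaRecord",
    "ValidatedInteraction",
    "normalize_rna",
    "reverse_complement",
    "read_sequences",
    "read_transcriptome",
    "read_mirbase",
    "read_validated",
    "write_collapsed_fasta",
]


class ParseError(ValueError):
    """A record in an input file could not be interpreted."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or violates its schema."""


def normalize_rna(sequence: str) -> str:
    """Uppercase a sequence and convert the DNA alphabet to RNA (T->U)."""
    return str(sequence).upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    """Reverse complement in the canonical RNA alphabet."""
    return normalize_rna(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """One distinct sequence with its summed abundance."""

    sequence: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("read sequence must be non-empty")
        if self.abundance < 1:
            raise ValueError(
                f"read abundance must be >= 1, got {self.abundance}"
            )


class ReadKind(str, Enum):
    SRNA = "sRNA"
    DEGRADOME = "degradome"


@dataclass
class ReadSet:
    """Non-redundant read collection: sequence -> summed abundance."""

    counts: Dict[str, int] = field(default_factory=dict)
    kind: ReadKind = ReadKind.SRNA

    @classmethod
    def from_reads(
        cls, reads: Iterable[Tuple[str, int]], kind: ReadKind = ReadKind.SRNA
    ) -> "ReadSet":
        rs = cls(kind=kind)
        for seq, abundance in reads:
            rs.add(seq, abundance)
        return rs

    def add(self, sequence: str, abundance: int = 1) -> None:
        if abundance < 1:
            raise ValueError("abundance must be >= 1")
        seq = normalize_rna(sequence)
        if not seq:
            raise ValueError("empty sequence")
        self.counts[seq] = self.counts.get(seq, 0) + abundance

    def total_abundance(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, sequence: str) -> bool:
        return normalize_rna(sequence) in self.counts

    def __iter__(self) -> Iterator[Read]:
        for seq in sorted(self.counts):
            yield Read(seq, self.counts[seq])

    def abundance(self, sequence: str) -> int:
        return self.counts.get(normalize_rna(sequence), 0)

    def subset(self, keep) -> "ReadSet":
        """New ReadSet with the reads for which ``keep(sequence)`` is true."""
        return ReadSet(
            {s: a for s, a in self.counts.items() if keep(s)}, kind=self.kind
        )


@dataclass(frozen=True)
class MirnaRecord:
    """A known mature miRNA with its annotation metadata."""

    id: str
    sequence: str
    species: str = ""
    clade: Optional[str] = None


@dataclass(frozen=True)
class ValidatedInteraction:
    """An experimentally validated miRNA-mRNA cleavage interaction."""

    mirna_id: str
    mirna_sequence: str
    transcript_id: str
    cleavage_position: int  # 1-based transcript coordinate

    def __post_init__(self) -> None:
        if self.cleavage_position < 1:
            raise ValueError(
                f"cleavage_position must be >= 1 (1-based), got "
                f"{self.cleavage_position}"
            )


def _guess_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f in {"fasta", "fa", "collapsed", "collapsed-fasta"}:
            return "fasta"
        if f in {"fastq", "fq"}:
            return "fastq"
        raise ValueError(f"unsupported format: {fmt}")
    ext = os.path.splitext(path)[1].lower()
    return "fastq" if ext in {".fastq", ".fq"} else "fasta"


def _collapsed_abundance(header_id: str) -> int:
    """Abundance encoded in a ``label_COUNT`` header; 1 when absent."""
    if "_" in header_id:
        suffix = header_id.rsplit("_", 1)[1]
        if suffix.isdigit():
            n = int(suffix)
            if n < 1:
                raise ParseError(
                    f"collapsed header {header_id!r} encodes abundance {n} < 1"
                )
            return n
    return 1


def read_sequences(
    path: str,
    format: Optional[str] = None,
    kind: ReadKind = ReadKind.SRNA,
) -> ReadSet:
    """Load reads from FASTA/FASTQ/collapsed-FASTA into a ReadSet.

    Duplicate sequences are merged with summed abundances; collapsed
    FASTA headers of the form ``>name_N`` contribute abundance N.
    FASTQ quality strings are ignored.
    """
    fmt = _guess_format(path, format)
    rs = ReadSet(kind=kind)
    try:
        with open(path) as handle:
            for i, record in enumerate(SeqIO.parse(handle, fmt), start=1):
                seq = normalize_rna(record.seq)
                if not seq:
                    raise ParseError(
                        f"{path}: record {i} ({record.id!r}) has an empty "
                        "sequence"
                    )
                abundance = (
                    _collapsed_abundance(record.id) if fmt == "fasta" else 1
                )
                rs.add(seq, abundance)
    except ValueError as err:
        if isinstance(err, ParseError):
            raise
        raise ParseError(f"{path}: malformed {fmt} record: {err}") from err
    return rs


def read_transcriptome(path: str) -> Dict[str, str]:
    """Load a transcriptome FASTA as ``transcript_id -> RNA sequence``.

    The transcript id is the first whitespace-delimited header token.
    Duplicate ids are rejected.
    """
    transcripts: Dict[str, str] = {}
    with open(path) as handle:
        for i, record in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            tid = record.id
            if tid in transcripts:
                raise SchemaError(
                    f"{path}: duplicate transcript id {tid!r}"
                )
            seq = normalize_rna(record.seq)
            if not seq:
                raise ParseError(
                    f"{path}: record {i} ({tid!r}) has an empty sequence"
                )
            transcripts[tid] = seq
    return transcripts


def read_mirbase(
    path: str, clade_map: Optional[Mapping[str, str]] = None
) -> List[MirnaRecord]:
    """Load mature miRNAs from a miRBase-style FASTA.

    Headers look like ``>ath-miR156a MIMAT0000166 Arabidopsis thaliana
    miR156a``.  The species prefix (before the first ``-``) is mapped to
    a clade through ``clade_map``; unknown prefixes get clade ``None``.
    Mature plant miRNAs are expected to be 19-25 nt; records outside
    that range are kept with a warning.
    """
    records: List[MirnaRecord] = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = normalize_rna(record.seq)
            prefix = record.id.split("-", 1)[0]
            desc_tokens = record.description.split()
            species = (
                " ".join(desc_tokens[2:4]) if len(desc_tokens) >= 4 else prefix
            )
            clade = clade_map.get(prefix) if clade_map else None
            if not 19 <= len(seq) <= 25:
                warnings.warn(
                    f"miRNA {record.id} has unusual length {len(seq)} "
                    "(expected 19-25 nt)",
                    stacklevel=2,
                )
            records.append(MirnaRecord(record.id, seq, species, clade))
    return records


_VALIDATED_COLUMNS = (
    "mirna_id",
    "mirna_sequence",
    "transcript_id",
    "cleavage_position",
)


def read_validated(path: str) -> List[ValidatedInteraction]:
    """Load a validated-interaction TSV (tab-delimited, header row).

    Required columns: mirna_id, mirna_sequence, transcript_id,
    cleavage_position (1-based).  Extra columns are ignored.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _VALIDATED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    out: List[ValidatedInteraction] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        raw = getattr(row, "cleavage_position")
        try:
            pos = int(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: row {i}: cleavage_position {raw!r} is not an "
                "integer"
            ) from None
        try:
            out.append(
                ValidatedInteraction(
                    mirna_id=str(getattr(row, "mirna_id")),
                    mirna_sequence=normalize_rna(
                        getattr(row, "mirna_sequence")
                    ),
                    transcript_id=str(getattr(row, "transcript_id")),
                    cleavage_position=pos,
                )
            )
        except ValueError as err:
            raise ParseError(f"{path}: row {i}: {err}") from None
    return out


def write_collapsed_fasta(rs: ReadSet, path: str, prefix: str = "read") -> None:
    """Write a ReadSet as collapsed FASTA (``>prefixN_COUNT`` headers).

    Records are ordered by decreasing abundance then sequence, so the
    output is deterministic and re-reading reproduces the ReadSet.
    """
    ordered = sorted(rs.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as handle:
        for i, (seq, abundance) in enumerate(ordered, start=1):
            handle.write(f">{prefix}{i}_{abundance}\n{seq}\n")


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    """Write ``id -> sequence`` mappings as FASTA in sorted id order."""
    with open(path, "w") as handle:
        for name in sorted(sequences):
            handle.write(f">{name}\n{sequences[name]}\n")
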