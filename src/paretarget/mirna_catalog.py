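"""miRNA candidate selection by homology and conservation classification.

Candidate miRNAs are the abundant small-RNA reads that match a known
mature plant miRNA on the sense strand with at most two mismatches and
no gaps.  User-supplied miRNA lists bypass the homology requirement
but must still be expressed (abundance >= 5 by default) in the sample.

A candidate is *conserved* when the known miRNAs it matches span more
than one clade, and *species-specific* when it matches nothing or only
miRNAs from a single clade.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

from .seqio import MirnaRecord, ReadSet, normalize_rna

__all__ = [
    "Conservation",
    "CandidateOrigin",
    "MirnaCandidate",
    "HomologyResult",
    "homology_match",
    "select_candidates",
    "classify_conservation",
    "load_clade_map",
    "default_clade_map",
]

MAX_HOMOLOGY_MISMATCHES = 2
MAX_LENGTH_DIFFERENCE = 2


class Conservation(str, Enum):
    CONSERVED = "conserved"
    SPECIES_SPECIFIC = "species_specific"


class CandidateOrigin(str, Enum):
    HOMOLOGY = "homology"
    USER_SUPPLIED = "user_supplied"


class HomologyResult(NamedTuple):
    is_match: bool
    n_mismatches: Optional[int]


@dataclass
class MirnaCandidate:
    """A small-RNA sequence accepted as a miRNA for target prediction."""

    sequence: str
    abundance: int
    matched_known_ids: List[str] = field(default_factory=list)
    conservation: Optional[Conservation] = None
    origin: CandidateOrigin = CandidateOrigin.HOMOLOGY
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = (
                self.matched_known_ids[0]
                if self.matched_known_ids
                else f"sRNA-{self.sequence[:8]}"
            )


def _min_hamming(short: str, long: str) -> int:
    """Minimum Hamming distance sliding the shorter along the longer."""
    best = len(short)
    for offset in range(len(long) - len(short) + 1):
        d = sum(
            1 for a, b in zip(short, long[offset : offset + len(short)]) if a != b
        )
        best = min(best, d)
        if best == 0:
            break
    return best


def homology_match(read_seq: str, known_seq: str) -> HomologyResult:
    """Ungapped sense-strand identity match with at most two mismatches.

    Sequences whose lengths differ by more than two never match.  For
    smaller length differences the shorter sequence is slid along the
    longer, unpenalized overhangs, and the minimum Hamming distance over
    offsets is the mismatch count.  G:U counts as a mismatch here: this
    is sequence identity between two miRNAs, not duplex pairing.
    """
    a = normalize_rna(read_seq)
    b = normalize_rna(known_seq)
    if abs(len(a) - len(b)) > MAX_LENGTH_DIFFERENCE:
        return HomologyResult(False, None)
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    d = _min_hamming(short, long)
    if d <= MAX_HOMOLOGY_MISMATCHES:
        return HomologyResult(True, d)
    return HomologyResult(False, None)


def select_candidates(
    rs: ReadSet,
    known: Sequence[MirnaRecord],
    min_abund: int = 5,
    user_supplied: Iterable[str] = (),
) -> List[MirnaCandidate]:
    """Select miRNA candidates from a small-RNA sample.

    Every read with abundance >= ``min_abund`` that matches at least
    one known miRNA becomes a candidate listing all matched ids.
    ``user_supplied`` sequences bypass homology but must still reach
    ``min_abund`` in the sample.  Candidates are classified as
    conserved or species-specific from the clades of their matches.
    """
    if not known:
        raise ValueError("the known-miRNA list must not be empty")
    candidates: Dict[str, MirnaCandidate] = {}
    for read in rs:
        if read.abundance < min_abund:
            continue
        matched = [
            rec.id for rec in known if homology_match(read.sequence, rec.sequence).is_match
        ]
        if matched:
            candidates[read.sequence] = MirnaCandidate(
                sequence=read.sequence,
                abundance=read.abundance,
                matched_known_ids=matched,
                origin=CandidateOrigin.HOMOLOGY,
            )
    for seq in user_supplied:
        seq = normalize_rna(seq)
        abundance = rs.abundance(seq)
        if abundance < min_abund:
            continue
        if seq not in candidates:
            matched = [
                rec.id
                for rec in known
                if homology_match(seq, rec.sequence).is_match
            ]
            candidates[seq] = MirnaCandidate(
                sequence=seq,
                abundance=abundance,
                matched_known_ids=matched,
                origin=CandidateOrigin.USER_SUPPLIED,
            )
    out = sorted(candidates.values(), key=lambda c: c.sequence)
    for cand in out:
        cand.conservation = classify_conservation(cand, known)
    return out


def classify_conservation(
    candidate: MirnaCandidate, known: Sequence[MirnaRecord]
) -> Conservation:
    """Classify a candidate as conserved or species-specific.

    All known miRNAs matching the candidate (up to two mismatches, no
    gaps) are gathered; when their clades span more than one clade the
    candidate is conserved, otherwise (one clade, or no match at all)
    it is species-specific.
    """
    matched = [
        rec
        for rec in known
        if homology_match(candidate.sequence, rec.sequence).is_match
    ]
    clades = set()
    for rec in matched:
        if rec.clade is None:
            raise ValueError(
                f"known miRNA {rec.id!r} has no clade metadata; cannot "
                "classify conservation"
            )
        clades.add(rec.clade)
    if len(clades) > 1:
        return Conservation.CONSERVED
    return Conservation.SPECIES_SPECIFIC


def load_clade_map(path: str) -> Dict[str, str]:
    """Load a species-prefix -> clade TSV (two columns, no header)."""
    clade_map: Dict[str, str] = {}
    with open(path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: malformed clade-map row: {row!r}")
            clade_map[row[0].strip()] = row[1].strip()
    return clade_map


def default_clade_map() -> Dict[str, str]:
    """The clade map shipped with the package (miRBase species prefixes)."""
    ref = resources.files("paretarget").joinpath("data/clade_map.tsv")
    with resources.as_file(ref) as path:
        return load_clade_map(str(path))
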