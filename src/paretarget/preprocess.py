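"""Optional read-filtering stages applied before any analysis.

Three independent filters, each returning a subset of its input with
abundances untouched (so they commute):

* ambiguous-base removal (any character outside A/C/G/U),
* a low-complexity filter on mono-, di- and tri-nucleotide frequencies
  with thresholds 75%, 37.5% and 25% (overlapping windows, discard on
  strictly-greater),
* exact full-length genome matching on either strand.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping, Union

from .seqio import RNA_ALPHABET, ReadSet, normalize_rna, reverse_complement

__all__ = [
    "filter_ambiguous",
    "low_complexity_pass",
    "filter_low_complexity",
    "genome_match_filter",
]

# Maximum tolerated frequency of the most common k-mer, per k.
COMPLEXITY_THRESHOLDS = {1: 0.75, 2: 0.375, 3: 0.25}


def filter_ambiguous(rs: ReadSet) -> ReadSet:
    """Drop reads containing any base outside {A, C, G, U}."""
    return rs.subset(lambda seq: set(seq) <= RNA_ALPHABET)


def _max_kmer_fraction(seq: str, k: int) -> float:
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return max(Counter(windows).values()) / len(windows)


def low_complexity_pass(seq: str) -> bool:
    """True when a sequence passes the low-complexity filter.

    A sequence is discarded (returns False) when its most frequent
    mononucleotide exceeds 75% of positions, its most frequent
    overlapping dinucleotide exceeds 37.5% of the L-1 windows, or its
    most frequent overlapping trinucleotide exceeds 25% of the L-2
    windows.  Comparison is strictly greater-than, so boundary
    sequences are kept.
    """
    seq = normalize_rna(seq)
    if len(seq) < 3:
        warnings.warn(
            f"sequence of length {len(seq)} is too short for the "
            "trinucleotide rule; discarding",
            stacklevel=2,
        )
        return False
    return all(
        _max_kmer_fraction(seq, k) <= threshold
        for k, threshold in COMPLEXITY_THRESHOLDS.items()
    )


def filter_low_complexity(rs: ReadSet) -> ReadSet:
    """Drop low-complexity reads (see :func:`low_complexity_pass`)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rs.subset(low_complexity_pass)


def genome_match_filter(
    rs: ReadSet, genome: Union[Mapping[str, str], Iterable[str]]
) -> ReadSet:
    """Keep reads with an exact full-length match on either genome strand.

    Matching is exact (no mismatches) and ungapped; a read is kept if
    it occurs as a substring of any genome sequence or of its reverse
    complement.
    """
    sequences = genome.values() if isinstance(genome, Mapping) else genome
    strands = []
    for seq in sequences:
        fwd = normalize_rna(seq)
        strands.append(fwd)
        strands.append(reverse_complement(fwd))
    if not strands:
        raise ValueError("genome must contain at least one sequence")
    return rs.subset(lambda read: any(read in s for s in strands))
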