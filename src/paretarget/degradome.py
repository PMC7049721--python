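"""Degradome read mapping, transcript 5'-end profiles and peak classes.

A degradome (PARE) read marks, by its 5' end, a position at which a
transcript was found uncapped — a candidate cleavage site.  Reads are
mapped exactly and full-length to the sense strand of the
transcriptome, and each transcript accumulates a sparse profile of
summed 5'-end abundances.  Profile positions with abundance > 1 are
then classified relative to the transcript's signal:

* category 0 — the unique maximum on the transcript;
* category 1 — a maximum attained more than once;
* category 2 — above the mean abundance of occupied positions;
* category 3 — at or below that mean.

Peaks of category 0/1 are high-confidence (HC), 2/3 low-confidence
(LC); peaks below the abundance floor (default 5) are discarded since
such weak signals cannot be told apart from random degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, List, Mapping

from .seqio import ReadSet

__all__ = [
    "TranscriptProfile",
    "Peak",
    "Confidence",
    "map_degradome",
    "categorize",
    "confident_peaks",
]


class Confidence(str, Enum):
    HC = "HC"
    LC = "LC"


@dataclass
class TranscriptProfile:
    """Per-transcript degradome 5'-end abundance vector (sparse)."""

    transcript_id: str
    length: int
    position_abundance: Dict[int, int]

    def __post_init__(self) -> None:
        for pos, abundance in self.position_abundance.items():
            if not 1 <= pos <= self.length:
                raise ValueError(
                    f"{self.transcript_id}: position {pos} outside "
                    f"[1, {self.length}]"
                )
            if abundance < 1:
                raise ValueError(
                    f"{self.transcript_id}: abundance {abundance} < 1 at "
                    f"position {pos}"
                )

    def total(self) -> int:
        return sum(self.position_abundance.values())


@dataclass(frozen=True)
class Peak:
    """A categorized degradome peak on one transcript."""

    transcript_id: str
    position: int
    abundance: int
    category: int
    confidence: Confidence | None = None


def _occurrences(needle: str, haystack: str) -> List[int]:
    """All (overlapping) 0-based occurrence offsets of needle in haystack."""
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def map_degradome(
    rs: ReadSet, transcriptome: Mapping[str, str]
) -> Dict[str, TranscriptProfile]:
    """Map degradome reads to transcripts and build 5'-end profiles.

    A read contributes its full abundance at the 1-based position of
    every exact, full-length, sense-strand occurrence in every
    transcript (multi-mapping reads are counted per occurrence, without
    apportioning).
    """
    accumulators: Dict[str, Dict[int, int]] = {}
    for read in rs:
        for tid, tseq in transcriptome.items():
            for offset in _occurrences(read.sequence, tseq):
                acc = accumulators.setdefault(tid, {})
                pos = offset + 1
                acc[pos] = acc.get(pos, 0) + read.abundance
    return {
        tid: TranscriptProfile(tid, len(transcriptome[tid]), positions)
        for tid, positions in sorted(accumulators.items())
    }


def categorize(profile: TranscriptProfile) -> List[Peak]:
    """Assign categories 0-3 to the profile positions with abundance > 1.

    The mean used for the category 2/3 split is taken over the occupied
    (nonzero) positions of the profile, and ties at the mean fall into
    category 3 so that the categories partition all eligible positions.
    """
    if not profile.position_abundance:
        raise ValueError(f"{profile.transcript_id}: empty profile")
    abundances = profile.position_abundance
    maximum = max(abundances.values())
    n_max = sum(1 for a in abundances.values() if a == maximum)
    mean = sum(abundances.values()) / len(abundances)
    peaks: List[Peak] = []
    for pos in sorted(abundances):
        abundance = abundances[pos]
        if abundance <= 1:
            continue
        if abundance == maximum:
            category = 0 if n_max == 1 else 1
        elif abundance > mean:
            category = 2
        else:
            category = 3
        peaks.append(Peak(profile.transcript_id, pos, abundance, category))
    return peaks


def peaks_to_table(profiles: Mapping[str, TranscriptProfile], min_abund: int = 5):
    """Categorized-peak table (transcript_id, position, abundance,
    category, confidence) over all profiles, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for tid in sorted(profiles):
        for peak in confident_peaks(categorize(profiles[tid]), min_abund):
            rows.append(
                {
                    "transcript_id": peak.transcript_id,
                    "position": peak.position,
                    "abundance": peak.abundance,
                    "category": peak.category,
                    "confidence": peak.confidence.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "position", "abundance", "category", "confidence"],
    )


def confident_peaks(peaks: List[Peak], min_abund: int = 5) -> List[Peak]:
    """Apply the abundance floor and attach HC/LC confidence labels.

    Peaks with abundance below ``min_abund`` are excluded; categories
    0/1 (the transcript's highest signal) become HC, categories 2/3 LC.
    """
    out = []
    for peak in peaks:
        if peak.abundance < min_abund:
            continue
        confidence = Confidence.HC if peak.category in (0, 1) else Confidence.LC
        out.append(replace(peak, confidence=confidence))
    return out
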