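"""Peak-anchored miRNA-mRNA duplex alignment, scoring and criteria tests.

Cleavage geometry
-----------------
In plants, AGO-mediated slicing cuts the target between the nucleotides
paired to miRNA positions 10 and 11, so the degradome read's 5'
nucleotide (transcript coordinate ``t``) pairs miRNA position 10.  The
duplex is antiparallel: the target nucleotide pairing miRNA position
``p`` sits at transcript coordinate ``t + 10 - p`` in an ungapped
alignment.

Alignment and scoring
---------------------
Alignments allow a small number of single-nucleotide bulges on either
strand, with miRNA position 10 fixed opposite the cleavage nucleotide.
Each miRNA position carries exactly one state: Watson-Crick ``match``,
``gu`` wobble, ``mismatch``, or ``gap`` (a bulge attached to that
position).  The alignment score is the classic position-weighted
penalty sum: mismatch 1.0, G:U 0.5, bulge 1.0, all doubled in the core
region (positions 2-13).  The aligner minimizes this score by dynamic
programming; ties prefer fewer gaps, then gaps closer to the miRNA 3'
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._thermo import NearestNeighborBackend, perfect_complement
from .degradome import Confidence, Peak, TranscriptProfile, confident_peaks, categorize
from .mirna_catalog import MirnaCandidate
from .seqio import normalize_rna

__all__ = [
    "MATCH",
    "GU",
    "MISMATCH",
    "GAP",
    "CORE_REGION",
    "pair_state",
    "SiteWindow",
    "extract_site",
    "Alignment",
    "align_duplex",
    "score_duplex",
    "mfe_ratio",
    "Duplex",
    "TargetingCriteria",
    "passes",
    "find_targets",
    "state_string",
    "duplexes_to_table",
]

MATCH = "match"
GU = "gu"
MISMATCH = "mismatch"
GAP = "gap"

#: miRNA core region (1-based, inclusive) where penalties are doubled.
CORE_REGION = (2, 13)

PENALTY = {MATCH: 0.0, GU: 0.5, MISMATCH: 1.0, GAP: 1.0}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

_STATE_CHAR = {MATCH: "=", GU: "o", MISMATCH: "x", GAP: "-"}


def position_weight(p: int) -> float:
    return 2.0 if CORE_REGION[0] <= p <= CORE_REGION[1] else 1.0


def pair_state(mirna_nt: str, target_nt: Optional[str]) -> str:
    """State of one miRNA nucleotide opposite one target nucleotide."""
    if target_nt is None:
        return MISMATCH  # off-transcript: no partner available
    key = (mirna_nt, target_nt)
    if key in _WC_PAIRS:
        return MATCH
    if key in _GU_PAIRS:
        return GU
    return MISMATCH


@dataclass(frozen=True)
class SiteWindow:
    """Transcript window anchored on a degradome cleavage position."""

    transcript_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    sequence: str
    truncated: bool


def extract_site(
    transcript_seq: str,
    cleavage_position: int,
    mirna_length: int,
    gap_budget: int = 1,
    transcript_id: str = "",
) -> SiteWindow:
    """Extract the target-site window around a cleavage position.

    The ideal window spans transcript coordinates
    ``[t - (L - 10) - g, t + 9 + g]`` so that the nucleotide pairing
    miRNA position ``p`` sits at ``t + 10 - p``, with ``g`` extra
    positions per side for bulged alignments.  Windows clipped by the
    transcript ends are flagged as truncated.
    """
    t, L, g = cleavage_position, mirna_length, gap_budget
    if not 1 <= t <= len(transcript_seq):
        raise ValueError(
            f"cleavage position {t} outside transcript of length "
            f"{len(transcript_seq)}"
        )
    ideal_start = t - (L - 10) - g
    ideal_end = t + 9 + g
    start = max(1, ideal_start)
    end = min(len(transcript_seq), ideal_end)
    return SiteWindow(
        transcript_id=transcript_id,
        start=start,
        end=end,
        sequence=transcript_seq[start - 1 : end],
        truncated=(start != ideal_start or end != ideal_end),
    )


@dataclass(frozen=True)
class Alignment:
    """Result of duplex alignment: one state per miRNA position."""

    states: Tuple[str, ...]
    score: float
    n_gaps: int
    truncated: bool


def _half_alignment(
    mirna_seq: str,
    positions: Sequence[int],
    target_at: Callable[[int], Optional[str]],
    max_gaps: int,
) -> Dict[int, Tuple[float, tuple, tuple]]:
    """Best alignment of one anchor half, per gap budget.

    ``positions`` lists miRNA positions in processing order (outward
    from the anchor); ``target_at(j)`` returns the j-th target
    nucleotide in that direction (None beyond the transcript end).
    Returns ``{gaps_budget: (cost, tie_key, states)}`` where the tie key
    prefers fewer gaps and gaps closer to the miRNA 3' end, and
    ``states`` is a tuple of (position, state).
    """
    L = len(mirna_seq)
    n = len(positions)

    @lru_cache(maxsize=None)
    def go(i: int, j: int, g: int) -> Tuple[float, tuple, tuple]:
        if i == n:
            return (0.0, (), ())
        p = positions[i]
        options = []
        # pair p with the next target nucleotide
        st = pair_state(mirna_seq[p - 1], target_at(j))
        cost, tie, states = go(i + 1, j + 1, g)
        options.append(
            (cost + PENALTY[st] * position_weight(p), tie, ((p, st),) + states)
        )
        if g > 0 and p != 10:
            gap_rank = L - p  # smaller = closer to the miRNA 3' end
            # miRNA bulge: p unpaired, target does not advance
            cost, tie, states = go(i + 1, j, g - 1)
            options.append(
                (
                    cost + position_weight(p),
                    tuple(sorted(tie + (gap_rank,))),
                    ((p, GAP),) + states,
                )
            )
            # target bulge attached at p: an extra target nucleotide is
            # skipped, p carries the gap state
            cost, tie, states = go(i + 1, j + 2, g - 1)
            options.append(
                (
                    cost + position_weight(p),
                    tuple(sorted(tie + (gap_rank,))),
                    ((p, GAP),) + states,
                )
            )
        return min(options, key=lambda o: (o[0], len(o[1]), o[1]))

    result = {g: go(0, 0, g) for g in range(max_gaps + 1)}
    go.cache_clear()
    return result


def align_duplex(
    mirna_seq: str,
    transcript_seq: str,
    cleavage_position: int,
    max_gaps: int = 1,
) -> Alignment:
    """Align a miRNA against a transcript site anchored at a cleavage peak.

    Minimizes the position-weighted penalty score over all alignments
    with at most ``max_gaps`` single-nucleotide bulges on either strand,
    keeping miRNA position 10 opposite the cleavage nucleotide.  Ties
    are broken toward fewer gaps, then gaps placed closest to the miRNA
    3' end.
    """
    mirna_seq = normalize_rna(mirna_seq)
    transcript_seq = normalize_rna(transcript_seq)
    t = cleavage_position
    L = len(mirna_seq)
    if not 1 <= t <= len(transcript_seq):
        raise ValueError(
            f"cleavage position {t} outside transcript of length "
            f"{len(transcript_seq)}"
        )

    def coord(c: int) -> Optional[str]:
        return transcript_seq[c - 1] if 1 <= c <= len(transcript_seq) else None

    # 3' half: positions 10..L pair t, t-1, ... (downstream on the miRNA,
    # upstream on the transcript)
    half_a = _half_alignment(
        mirna_seq, range(10, L + 1), lambda j: coord(t - j), max_gaps
    )
    # 5' half: positions 9..1 pair t+1, t+2, ...
    half_b = _half_alignment(
        mirna_seq, range(9, 0, -1), lambda j: coord(t + 1 + j), max_gaps
    )

    best = None
    for ga in range(max_gaps + 1):
        gb = max_gaps - ga
        cost_a, tie_a, states_a = half_a[ga]
        cost_b, tie_b, states_b = half_b[gb]
        cand = (
            cost_a + cost_b,
            tuple(sorted(tie_a + tie_b)),
            states_a + states_b,
        )
        key = (cand[0], len(cand[1]), cand[1])
        if best is None or key < best[0]:
            best = (key, cand)
    assert best is not None
    _, (score, tie, state_pairs) = best
    states: List[str] = [MISMATCH] * L
    for p, st in state_pairs:
        states[p - 1] = st
    window = extract_site(transcript_seq, t, L, max_gaps)
    return Alignment(
        states=tuple(states),
        score=round(score, 6),
        n_gaps=len(tie),
        truncated=window.truncated,
    )


def score_duplex(states: Sequence[str]) -> float:
    """Position-weighted penalty score of a complete state assignment."""
    return sum(
        PENALTY[state] * position_weight(p)
        for p, state in enumerate(states, start=1)
    )


_DEFAULT_BACKEND = NearestNeighborBackend()


def mfe_ratio(
    mirna_seq: str,
    site_seq: Optional[str],
    states: Sequence[str],
    backend=None,
) -> float:
    """Hybridization-strength ratio of a duplex in (0, 1].

    The observed duplex energy is divided by the energy of the miRNA
    bound to its perfect reverse complement, both computed by the same
    backend, so a perfect duplex scores exactly 1.0.
    """
    backend = backend or _DEFAULT_BACKEND
    return backend.ratio(normalize_rna(mirna_seq), site_seq, states)


@dataclass(frozen=True)
class Duplex:
    """One peak-anchored miRNA-mRNA duplex with its derived properties."""

    mirna: MirnaCandidate
    transcript_id: str
    cleavage_position: int
    states: Tuple[str, ...]
    score: float
    mfe_ratio: float
    peak: Optional[Peak] = None

    @property
    def mirna_sequence(self) -> str:
        return self.mirna.sequence

    def key(self) -> Tuple[str, str, int]:
        return (self.mirna.sequence, self.transcript_id, self.cleavage_position)


def state_string(states: Sequence[str]) -> str:
    """Compact per-position encoding: '=' match, 'o' G:U, 'x' MM, '-' gap."""
    return "".join(_STATE_CHAR[s] for s in states)


# --- duplex feature counting -------------------------------------------------


def _adjacent_mm(states: Sequence[str], lo: int = 1, hi: int = 10**9) -> int:
    """Adjacent-mismatch occurrences: each consecutive mismatch pair counts
    one (a run of three counts two).  Restricted to positions [lo, hi]."""
    count = 0
    for p in range(1, len(states)):
        if lo <= p and p + 1 <= hi:
            if states[p - 1] == MISMATCH and states[p] == MISMATCH:
                count += 1
    return count


def duplex_features(states: Sequence[str]) -> Dict[str, float]:
    """Counted properties of a state assignment, as used by the criteria."""
    lo, hi = CORE_REGION
    return {
        "n_mm": sum(s == MISMATCH for s in states),
        "n_gu": sum(s == GU for s in states),
        "n_gaps": sum(s == GAP for s in states),
        "n_adjacent_mm": _adjacent_mm(states),
        "n_adjacent_mm_core": _adjacent_mm(states, lo, hi),
        "n_mm_core": sum(
            s == MISMATCH for p, s in enumerate(states, 1) if lo <= p <= hi
        ),
        "nonwc_10": states[9] != MATCH if len(states) >= 10 else False,
        "nonwc_11": states[10] != MATCH if len(states) >= 11 else False,
    }


@dataclass(frozen=True)
class TargetingCriteria:
    """The rule family a duplex must satisfy to be called a target.

    Fields mirror the classic plant-targeting rule set: positional
    allowances at the cleavage-flanking positions 10/11, count caps on
    mismatches / G:U pairs / bulges / adjacent mismatches (overall and
    within the core region 2-13), a cap on the position-weighted
    alignment score, and a floor on the MFE ratio.
    """

    allow_mm_pos10: bool = True
    allow_mm_pos11: bool = True
    max_adjacent_mm_core: int = 1
    max_mm_core: int = 2
    max_score: float = 7.0
    max_mm: int = 5
    max_gu: int = 4
    max_adjacent_mm: int = 2
    mfe_ratio_cutoff: float = 0.5
    max_gaps: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name.startswith(("max_",)) and not isinstance(value, bool):
                if value < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {value}")
        if not 0.0 <= self.mfe_ratio_cutoff <= 1.0:
            raise ValueError("mfe_ratio_cutoff must be in [0, 1]")

    @classmethod
    def permissive(cls) -> "TargetingCriteria":
        """Deliberately loose defaults for the discovery pass.

        Strictly looser than any data-inferred rule set, so inference
        can only tighten them.
        """
        return cls()

    @classmethod
    def classic(cls) -> "TargetingCriteria":
        """A fixed rule set of the kind long used for plant targets.

        Approximates the widely used complementarity rules: no
        mismatch at positions 10/11, at most one core mismatch and no
        adjacent core mismatches, score at most 4.0.
        """
        return cls(
            allow_mm_pos10=False,
            allow_mm_pos11=False,
            max_adjacent_mm_core=0,
            max_mm_core=1,
            max_score=4.0,
            max_mm=3,
            max_gu=2,
            max_adjacent_mm=1,
            mfe_ratio_cutoff=0.70,
            max_gaps=1,
        )

    def to_file(self, path: str) -> None:
        with open(path, "w") as handle:
            for f in fields(self):
                value = getattr(self, f.name)
                if isinstance(value, bool):
                    value = "yes" if value else "no"
                handle.write(f"{f.name}={value}\n")

    @classmethod
    def from_file(cls, path: str) -> "TargetingCriteria":
        kwargs: Dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, raw = line.partition("=")
                name = name.strip()
                raw = raw.strip()
                if name not in types:
                    raise ValueError(f"{path}: unknown criteria field {name!r}")
                if name.startswith("allow_"):
                    kwargs[name] = raw.lower() in {"yes", "true", "1"}
                elif name in {"max_score", "mfe_ratio_cutoff"}:
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = int(raw)
        return cls(**kwargs)


def passes(duplex: Duplex, criteria: TargetingCriteria) -> bool:
    """Whether a duplex satisfies every rule of a criteria set."""
    feats = duplex_features(duplex.states)
    if not criteria.allow_mm_pos10 and feats["nonwc_10"]:
        return False
    if not criteria.allow_mm_pos11 and feats["nonwc_11"]:
        return False
    return (
        feats["n_mm"] <= criteria.max_mm
        and feats["n_gu"] <= criteria.max_gu
        and feats["n_gaps"] <= criteria.max_gaps
        and feats["n_adjacent_mm"] <= criteria.max_adjacent_mm
        and feats["n_adjacent_mm_core"] <= criteria.max_adjacent_mm_core
        and feats["n_mm_core"] <= criteria.max_mm_core
        and duplex.score <= criteria.max_score + 1e-9
        and duplex.mfe_ratio >= criteria.mfe_ratio_cutoff - 1e-9
    )


def find_targets(
    candidates: Sequence[MirnaCandidate],
    transcriptome: Mapping[str, str],
    profiles: Mapping[str, TranscriptProfile],
    permissive: Optional[TargetingCriteria] = None,
    min_peak_abund: int = 5,
    confidences: Iterable[Confidence] = (Confidence.HC, Confidence.LC),
    mfe_backend=None,
) -> List[Duplex]:
    """Predict duplexes for every (candidate, confident peak) pair.

    For each peak with abundance >= ``min_peak_abund`` and an accepted
    confidence class, every candidate miRNA is aligned against the
    peak-anchored site, scored, and kept when it satisfies the
    permissive criteria.  Output order is deterministic.
    """
    criteria = permissive or TargetingCriteria.permissive()
    wanted = set(confidences)
    out: List[Duplex] = []
    for tid in sorted(profiles):
        profile = profiles[tid]
        tseq = transcriptome[tid]
        peaks = [
            pk
            for pk in confident_peaks(categorize(profile), min_peak_abund)
            if pk.confidence in wanted
        ]
        for peak in peaks:
            for cand in candidates:
                alignment = align_duplex(
                    cand.sequence, tseq, peak.position, criteria.max_gaps
                )
                if alignment.truncated:
                    continue
                window = extract_site(
                    tseq, peak.position, len(cand.sequence), criteria.max_gaps, tid
                )
                ratio = mfe_ratio(
                    cand.sequence, window.sequence, alignment.states, mfe_backend
                )
                duplex = Duplex(
                    mirna=cand,
                    transcript_id=tid,
                    cleavage_position=peak.position,
                    states=alignment.states,
                    score=alignment.score,
                    mfe_ratio=ratio,
                    peak=peak,
                )
                if passes(duplex, criteria):
                    out.append(duplex)
    return out


def duplexes_to_table(duplexes: Sequence[Duplex]):
    """Interactions table (one row per duplex) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for d in duplexes:
        rows.append(
            {
                "mirna_id": d.mirna.name,
                "mirna_seq": d.mirna.sequence,
                "transcript_id": d.transcript_id,
                "cleavage_position": d.cleavage_position,
                "category": d.peak.category if d.peak else None,
                "confidence": d.peak.confidence.value
                if d.peak and d.peak.confidence
                else None,
                "score": d.score,
                "mfe_ratio": round(d.mfe_ratio, 4),
                "states": state_string(d.states),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "mirna_seq",
            "transcript_id",
            "cleavage_position",
            "category",
            "confidence",
            "score",
            "mfe_ratio",
            "states",
        ],
    )


_CHAR_STATE = {v: k for k, v in _STATE_CHAR.items()}


def duplexes_from_table(table) -> List[Duplex]:
    """Rebuild Duplex records from an interactions table (inverse of
    :func:`duplexes_to_table`; peak metadata is restored when present)."""
    out: List[Duplex] = []
    for row in table.itertuples(index=False):
        states = tuple(_CHAR_STATE[c] for c in str(row.states))
        peak = None
        category = getattr(row, "category", None)
        if category is not None and not (
            isinstance(category, float) and category != category
        ):
            confidence = getattr(row, "confidence", None)
            peak = Peak(
                transcript_id=str(row.transcript_id),
                position=int(row.cleavage_position),
                abundance=int(getattr(row, "peak_abundance", 0) or 0),
                category=int(category),
                confidence=Confidence(confidence) if confidence else None,
            )
        out.append(
            Duplex(
                mirna=MirnaCandidate(
                    sequence=normalize_rna(row.mirna_seq),
                    abundance=1,
                    name=str(row.mirna_id),
                ),
                transcript_id=str(row.transcript_id),
                cleavage_position=int(row.cleavage_position),
                states=states,
                score=float(row.score),
                mfe_ratio=float(row.mfe_ratio),
                peak=peak,
            )
        )
    return out
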