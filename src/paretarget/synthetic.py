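"""Seeded synthetic fixtures with planted miRNA-cleavage signals.

The generator emulates the full input bundle of a paired small-RNA /
degradome experiment at desk scale: a toy transcriptome, a set of
miRNAs, an sRNA sample expressing them, a degradome sample whose reads
start exactly at planted cleavage coordinates, and a ground-truth
manifest.  Each planted interaction embeds, at its cleavage coordinate,
the target site realizing a planned per-position pairing state against
its miRNA (reverse complement with planned edits, using the same
cleavage geometry as the aligner: miRNA position 10 opposite the
degradome 5' nucleotide).

Background degradation is modelled as reads at uniform random
coordinates with abundance 1 + Geometric(p) (support 1, 2, ...; the
bulk of random degradation signal is at the lowest abundances).

Same seed and config give byte-identical fixture files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .duplex import GAP, GU, MATCH, MISMATCH, score_duplex, state_string
from .seqio import ReadKind, ReadSet, write_collapsed_fasta

__all__ = [
    "PlannedEdit",
    "PlannedInteraction",
    "FixtureConfig",
    "Fixture",
    "generate_fixture",
    "two_subset_config",
]

_NTS = np.array(list("ACGU"))
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_GU_PARTNER = {"G": "U", "U": "G"}
# nucleotides that neither Watson-Crick pair nor wobble with the key
_MISMATCH_CHOICES = {
    "A": "ACG",
    "C": "ACU",
    "G": "AG",
    "U": "CU",
}


@dataclass(frozen=True)
class PlannedEdit:
    """One departure from perfect complementarity at a miRNA position."""

    position: int  # 1-based miRNA position
    kind: str  # "mismatch" | "gu" | "bulge" (unpaired miRNA nucleotide)


@dataclass
class PlannedInteraction:
    """One miRNA-transcript interaction to plant."""

    mirna: int  # miRNA index
    transcript: int  # transcript index
    peak_abundance: int = 50
    edits: Tuple[PlannedEdit, ...] = ()
    cleavage_position: Optional[int] = None  # chosen by the generator if None
    subset: str = ""


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic fixture.

    Defaults emulate a small but realistic experiment: ~21-nt miRNAs,
    transcripts of a few hundred nt, strong planted cleavage peaks
    (abundance 50) well above the detection floor of 5, miRNA sRNA
    abundance 30, and Geometric(0.5) background abundances.
    """

    n_transcripts: int = 25
    transcript_length: Tuple[int, int] = (250, 400)
    n_mirnas: int = 20
    mirna_length: int = 21
    interactions: Optional[List[PlannedInteraction]] = None
    background_per_transcript: float = 0.0  # expected background reads
    background_geometric_p: float = 0.5
    mirna_srna_abundance: int = 30
    n_background_srna: int = 50
    degradome_read_length: int = 20
    conserved: Optional[Sequence[bool]] = None  # per miRNA; default all True
    species_prefix: str = "ath"
    second_prefix: str = "osa"  # clade-distinct duplicates for conserved miRNAs


@dataclass
class Fixture:
    """Generated bundle: in-memory objects plus (optionally) file paths."""

    transcripts: Dict[str, str]
    mirnas: Dict[str, str]  # known-miRNA id -> sequence
    srna: ReadSet
    degradome: ReadSet
    manifest: "object"  # pandas DataFrame
    background_positions: Dict[str, Dict[int, int]]
    paths: Dict[str, str] = dc_field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NTS, size=length))


def _planned_states(length: int, edits: Sequence[PlannedEdit]) -> List[str]:
    states = [MATCH] * length
    for edit in edits:
        if not 1 <= edit.position <= length:
            raise ValueError(
                f"planned edit at position {edit.position} outside miRNA of "
                f"length {length}"
            )
        states[edit.position - 1] = {
            "mismatch": MISMATCH,
            "gu": GU,
            "bulge": GAP,
        }[edit.kind]
    return states


def _site_for(
    rng: np.random.Generator, mirna: str, states: Sequence[str]
) -> Tuple[str, int]:
    """Target site (transcript 5'->3') realizing the planned states.

    Returns the site string and the offset, within it, of the
    nucleotide pairing miRNA position 10.
    """
    nts: List[str] = []
    anchor_offset = None
    for p in range(len(mirna), 0, -1):  # transcript 5'->3' order
        state = states[p - 1]
        if state == GAP:
            continue  # unpaired miRNA nucleotide: no target base
        m = mirna[p - 1]
        if state == MATCH:
            nts.append(_WC[m])
        elif state == GU:
            nts.append(_GU_PARTNER[m])
        else:
            nts.append(str(rng.choice(list(_MISMATCH_CHOICES[m]))))
        if p == 10:
            anchor_offset = len(nts) - 1
    if anchor_offset is None:
        raise ValueError("a planted site must pair miRNA position 10")
    return "".join(nts), anchor_offset


def _check_plan(config: FixtureConfig) -> List[PlannedInteraction]:
    if config.interactions is not None:
        plan = config.interactions
    else:
        # default plan: one interaction per miRNA with the edit diversity
        # typical of real plant duplexes (perfect, 3' wobble, position-1
        # mismatch plus wobble, 3' bulge, in rotation)
        k = min(config.n_mirnas, config.n_transcripts)
        rotation = (
            (),
            (PlannedEdit(16, "gu"),),
            (PlannedEdit(1, "mismatch"), PlannedEdit(20, "gu")),
            (PlannedEdit(15, "bulge"),),
        )
        plan = [
            PlannedInteraction(mirna=i, transcript=i,
                               edits=rotation[i % len(rotation)])
            for i in range(k)
        ]
    for inter in plan:
        if not 0 <= inter.mirna < config.n_mirnas:
            raise ValueError(f"miRNA index {inter.mirna} out of range")
        if not 0 <= inter.transcript < config.n_transcripts:
            raise ValueError(f"transcript index {inter.transcript} out of range")
        for edit in inter.edits:
            if edit.kind == "bulge" and edit.position == 10:
                raise ValueError("cannot plant a bulge at the anchor position 10")
            if edit.kind not in {"mismatch", "gu", "bulge"}:
                raise ValueError(f"unknown edit kind {edit.kind!r}")
    by_transcript: Dict[int, int] = {}
    for inter in plan:
        by_transcript[inter.transcript] = by_transcript.get(inter.transcript, 0) + 1
    return plan


def generate_fixture(
    config: FixtureConfig, seed: int, out_dir: Optional[str] = None
) -> Fixture:
    """Generate a fixture bundle; optionally write its files to ``out_dir``.

    Files written: transcriptome.fasta (DNA alphabet), mirnas.fasta
    (known miRNAs, miRBase-style headers), srna.fasta and
    degradome.fasta (collapsed FASTA), clade_map.tsv, manifest.tsv.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    plan = _check_plan(config)
    L = config.mirna_length

    # miRNAs, forcing G/U at positions planned as wobbles
    gu_positions: Dict[int, set] = {}
    for inter in plan:
        for edit in inter.edits:
            if edit.kind == "gu":
                gu_positions.setdefault(inter.mirna, set()).add(edit.position)
    mirna_seqs: List[str] = []
    seen = set()
    for i in range(config.n_mirnas):
        while True:
            seq = list(_random_seq(rng, L))
            for p in gu_positions.get(i, ()):
                seq[p - 1] = str(rng.choice(["G", "U"]))
            seq = "".join(seq)
            if seq not in seen:
                seen.add(seq)
                mirna_seqs.append(seq)
                break

    lo, hi = config.transcript_length
    transcripts: Dict[str, str] = {}
    t_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_transcripts)]
    raw = [_random_seq(rng, n) for n in t_lengths]

    manifest_rows = []
    used: Dict[int, List[Tuple[int, int]]] = {}
    for inter in plan:
        mirna = mirna_seqs[inter.mirna]
        states = _planned_states(L, inter.edits)
        site, anchor_offset = _site_for(rng, mirna, states)
        tlen = t_lengths[inter.transcript]
        read_len = config.degradome_read_length
        t_min = len(site) + 2
        t_max = tlen - max(read_len, 12) - 2
        if t_max < t_min:
            raise ValueError(
                f"transcript {inter.transcript} too short for a planted site"
            )
        if inter.cleavage_position is None:
            t = int(rng.integers(t_min, t_max + 1))
        else:
            t = inter.cleavage_position
            if not t_min <= t <= t_max:
                raise ValueError(
                    f"cleavage position {t} incompatible with transcript "
                    f"length {tlen}"
                )
        start = t - anchor_offset  # 1-based site start
        end = start + len(site) - 1
        if start < 1 or end > tlen:
            raise ValueError("planted site falls off the transcript")
        for s, e in used.get(inter.transcript, []):
            if not (end < s or start > e):
                raise ValueError(
                    f"planted sites overlap on transcript {inter.transcript}"
                )
        used.setdefault(inter.transcript, []).append((start, end))
        seq = raw[inter.transcript]
        raw[inter.transcript] = seq[: start - 1] + site + seq[end:]
        manifest_rows.append(
            {
                "mirna_index": inter.mirna,
                "transcript_index": inter.transcript,
                "cleavage_position": t,
                "peak_abundance": inter.peak_abundance,
                "states": state_string(states),
                "score": score_duplex(states),
                "subset": inter.subset,
            }
        )

    for i, seq in enumerate(raw):
        transcripts[f"TX{i + 1:04d}"] = seq

    # known-miRNA catalogue: one record per miRNA under the primary
    # species prefix; conserved miRNAs get a clade-distinct duplicate
    conserved = (
        list(config.conserved)
        if config.conserved is not None
        else [True] * config.n_mirnas
    )
    mirnas: Dict[str, str] = {}
    for i, seq in enumerate(mirna_seqs):
        mirnas[f"{config.species_prefix}-miR{i + 1:04d}"] = seq
        if conserved[i]:
            mirnas[f"{config.second_prefix}-miR{i + 1:04d}"] = seq

    # degradome: planted cleavage products plus geometric background
    degradome = ReadSet(kind=ReadKind.DEGRADOME)
    background_positions: Dict[str, Dict[int, int]] = {
        tid: {} for tid in transcripts
    }
    for row in manifest_rows:
        tid = f"TX{row['transcript_index'] + 1:04d}"
        t = row["cleavage_position"]
        read = transcripts[tid][t - 1 : t - 1 + config.degradome_read_length]
        degradome.add(read, row["peak_abundance"])
        row["transcript_id"] = tid
        row["mirna_id"] = f"{config.species_prefix}-miR{row['mirna_index'] + 1:04d}"
        row["mirna_seq"] = mirna_seqs[row["mirna_index"]]
    if config.background_per_transcript > 0:
        for tid in sorted(transcripts):
            tseq = transcripts[tid]
            n_bg = int(rng.poisson(config.background_per_transcript))
            max_start = len(tseq) - config.degradome_read_length + 1
            for _ in range(n_bg):
                pos = int(rng.integers(1, max_start + 1))
                abundance = int(rng.geometric(config.background_geometric_p))
                read = tseq[pos - 1 : pos - 1 + config.degradome_read_length]
                degradome.add(read, abundance)
                bg = background_positions[tid]
                bg[pos] = bg.get(pos, 0) + abundance

    # sRNA sample: every miRNA at its planned abundance, plus noise
    srna = ReadSet(kind=ReadKind.SRNA)
    for seq in mirna_seqs:
        srna.add(seq, config.mirna_srna_abundance)
    for _ in range(config.n_background_srna):
        length = int(rng.integers(19, 25))
        srna.add(_random_seq(rng, length), int(rng.geometric(0.5)))

    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "mirna_id",
            "mirna_seq",
            "transcript_id",
            "cleavage_position",
            "peak_abundance",
            "states",
            "score",
            "subset",
            "mirna_index",
            "transcript_index",
        ],
    )

    fixture = Fixture(
        transcripts=transcripts,
        mirnas=mirnas,
        srna=srna,
        degradome=degradome,
        manifest=manifest,
        background_positions=background_positions,
    )
    if out_dir is not None:
        fixture.paths = _write_fixture(fixture, config, out_dir)
    return fixture


def _to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def _write_fixture(fixture: Fixture, config: FixtureConfig, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "transcriptome": os.path.join(out_dir, "transcriptome.fasta"),
        "mirnas": os.path.join(out_dir, "mirnas.fasta"),
        "srna": os.path.join(out_dir, "srna.fasta"),
        "degradome": os.path.join(out_dir, "degradome.fasta"),
        "clade_map": os.path.join(out_dir, "clade_map.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "validated": os.path.join(out_dir, "validated.tsv"),
    }
    with open(paths["transcriptome"], "w") as handle:
        for tid in sorted(fixture.transcripts):
            handle.write(f">{tid}\n{_to_dna(fixture.transcripts[tid])}\n")
    with open(paths["mirnas"], "w") as handle:
        for mid in sorted(fixture.mirnas):
            handle.write(f">{mid} synthetic\n{fixture.mirnas[mid]}\n")
    write_collapsed_fasta(fixture.srna, paths["srna"], prefix="s")
    write_collapsed_fasta(fixture.degradome, paths["degradome"], prefix="d")
    with open(paths["clade_map"], "w") as handle:
        handle.write(f"{config.species_prefix}\tCladePrimary\n")
        handle.write(f"{config.second_prefix}\tCladeSecondary\n")
    fixture.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    # planted ground truth in the validated-interaction table schema
    fixture.manifest[
        ["mirna_id", "mirna_seq", "transcript_id", "cleavage_position"]
    ].rename(columns={"mirna_seq": "mirna_sequence"}).to_csv(
        paths["validated"], sep="\t", index=False
    )
    return paths


def two_subset_config(
    n_per_subset: int = 12,
    seed: int = 0,
    peak_abundance: int = 50,
    background_per_transcript: float = 0.0,
) -> FixtureConfig:
    """Config with two interaction subsets of distinct planted properties.

    Subset "tight" emulates conserved-miRNA-like interactions: no
    mismatches at all, but one or (mostly) two G:U wobbles in the miRNA
    3' region.  Subset "loose" emulates species-specific-like
    interactions: a mismatch tolerated in the 5' core (positions 5, 8,
    9 or 10), at most one wobble, sometimes an extra 3' mismatch.
    Neither subset's property envelope contains the other's, so criteria
    inferred on one transfer poorly to the other in both directions.
    The tight subset's miRNAs are marked conserved (present in two
    clades of the known catalogue), the loose subset's are not.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_subset
    interactions: List[PlannedInteraction] = []
    for i in range(n_per_subset):
        positions = rng.choice(np.arange(14, 22), size=2, replace=False)
        n_gu = 2 if rng.random() < 0.6 else 1
        edits = [PlannedEdit(int(p), "gu") for p in positions[:n_gu]]
        interactions.append(
            PlannedInteraction(
                mirna=i,
                transcript=i,
                peak_abundance=peak_abundance,
                edits=tuple(edits),
                subset="tight",
            )
        )
    for i in range(n_per_subset):
        edits = [PlannedEdit(int(rng.choice([5, 8, 9, 10])), "mismatch")]
        if rng.random() < 0.5:
            p = int(rng.integers(14, 22))
            edits.append(PlannedEdit(p, "gu"))
        if rng.random() < 0.5:
            p = int(rng.integers(15, 22))
            if all(e.position != p for e in edits):
                edits.append(PlannedEdit(p, "mismatch"))
        interactions.append(
            PlannedInteraction(
                mirna=n_per_subset + i,
                transcript=n_per_subset + i,
                peak_abundance=peak_abundance,
                edits=tuple(edits),
                subset="loose",
            )
        )
    return FixtureConfig(
        n_transcripts=n,
        n_mirnas=n,
        interactions=interactions,
        background_per_transcript=background_per_transcript,
        conserved=[True] * n_per_subset + [False] * n_per_subset,
    )
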