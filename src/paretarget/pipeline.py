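"""End-to-end orchestration of the inference pipeline.

Stages: read filtering -> miRNA candidate selection -> degradome
profiling -> permissive target prediction -> property profiling and
criteria inference -> (optionally) evaluation, retain-rate sweep and
subset statistics when a validated-interaction table is supplied.

Outputs are plain TSV/flat-text files under one output directory, plus
a run log recording every effective parameter, so every number in every
table is recomputable from the log and the inputs.  Re-running with
identical inputs and configuration is bit-identical apart from the
log's timestamp line.

Multiple sRNA/degradome replicate pairs are processed independently
(results in ``rep1/``, ``rep2/`` ...) and a cross-replicate consistency
table is emitted; genuine cleavage sites tend to recur across
biological replicates, so consistency is evidence of signal.
"""

from __future__ import annotations

import datetime
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .degradome import (
    Confidence,
    categorize,
    confident_peaks,
    map_degradome,
    peaks_to_table,
)
from .duplex import (
    Duplex,
    TargetingCriteria,
    duplexes_to_table,
    find_targets,
    passes,
)
from .evaluation import evaluate
from .inference import (
    infer_criteria,
    position_profile,
    retain_sweep,
    select_retain,
    sweep_to_table,
)
from .mirna_catalog import (
    Conservation,
    default_clade_map,
    load_clade_map,
    select_candidates,
)
from .preprocess import filter_ambiguous, filter_low_complexity, genome_match_filter
from .seqio import (
    ReadKind,
    ValidatedInteraction,
    read_mirbase,
    read_sequences,
    read_transcriptome,
    read_validated,
)
from .stats import ks_mfe, stats_report

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "observable_positives"]


@dataclass
class PipelineConfig:
    """All inputs, toggles and thresholds for one run."""

    srna: Sequence[str] = ()
    degradome: Sequence[str] = ()
    transcriptome: str = ""
    mirbase: str = ""
    out: str = "paretarget_out"
    genome: Optional[str] = None
    validated: Optional[str] = None
    clade_map: Optional[str] = None
    user_mirnas: Sequence[str] = ()
    retain_rate: float = 0.85
    min_peak_abund: int = 5
    min_mirna_abund: int = 5
    confidence: str = "HC"  # HC | LC | both
    position_tolerance: int = 1
    filter_ambiguous: bool = True
    filter_complexity: bool = True
    filter_genome: bool = True  # only effective when a genome is given
    run_sweep: bool = True
    seed: int = 0
    permissive: TargetingCriteria = field(
        default_factory=TargetingCriteria.permissive
    )

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        permissive_raw = raw.pop("permissive", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        config = cls(**raw)
        if permissive_raw:
            config.permissive = TargetingCriteria(**permissive_raw)
        return config

    def confidences(self) -> Tuple[Confidence, ...]:
        return {
            "HC": (Confidence.HC,),
            "LC": (Confidence.LC,),
            "both": (Confidence.HC, Confidence.LC),
        }[self.confidence]


@dataclass
class PipelineResult:
    out_dir: str
    duplexes_by_replicate: List[List[Duplex]]
    criteria_by_replicate: List[Optional[TargetingCriteria]]


def observable_positives(
    validated: Sequence[ValidatedInteraction],
    profiles,
    srna,
    min_peak_abund: int = 5,
    min_mirna_abund: int = 5,
    position_tolerance: int = 1,
) -> List[ValidatedInteraction]:
    """Validated interactions observable in this dataset.

    Keeps interactions whose miRNA is expressed (sample abundance >=
    ``min_mirna_abund``) and whose cleavage coordinate carries a
    high-confidence degradome peak (category 0/1, abundance >=
    ``min_peak_abund``) within the position tolerance.
    """
    out = []
    for v in validated:
        if srna.abundance(v.mirna_sequence) < min_mirna_abund:
            continue
        profile = profiles.get(v.transcript_id)
        if profile is None:
            continue
        peaks = confident_peaks(categorize(profile), min_peak_abund)
        if any(
            p.confidence is Confidence.HC
            and abs(p.position - v.cleavage_position) <= position_tolerance
            for p in peaks
        ):
            out.append(v)
    return out


def _preprocess(rs, config: PipelineConfig, genome):
    if config.filter_ambiguous:
        rs = filter_ambiguous(rs)
    if config.filter_complexity:
        rs = filter_low_complexity(rs)
    if genome is not None and config.filter_genome:
        rs = genome_match_filter(rs, genome)
    return rs


def _run_replicate(
    rep_dir: str,
    srna_path: str,
    degradome_path: str,
    transcriptome,
    known,
    genome,
    validated,
    config: PipelineConfig,
    log: List[str],
) -> Tuple[List[Duplex], Optional[TargetingCriteria]]:
    os.makedirs(rep_dir, exist_ok=True)
    srna = _preprocess(
        read_sequences(srna_path, kind=ReadKind.SRNA), config, genome
    )
    degradome = _preprocess(
        read_sequences(degradome_path, kind=ReadKind.DEGRADOME), config, genome
    )
    log.append(
        f"{rep_dir}: sRNA {len(srna)} distinct / {srna.total_abundance()} total; "
        f"degradome {len(degradome)} distinct / {degradome.total_abundance()} total"
    )
    candidates = select_candidates(
        srna, known, config.min_mirna_abund, config.user_mirnas
    )
    log.append(f"{rep_dir}: {len(candidates)} miRNA candidates")
    profiles = map_degradome(degradome, transcriptome)
    peaks_to_table(profiles, config.min_peak_abund).to_csv(
        os.path.join(rep_dir, "degradome_peaks.tsv"), sep="\t", index=False
    )
    duplexes = find_targets(
        candidates,
        transcriptome,
        profiles,
        config.permissive,
        config.min_peak_abund,
        config.confidences(),
    )
    log.append(f"{rep_dir}: {len(duplexes)} duplexes pass the permissive criteria")
    duplexes_to_table(duplexes).to_csv(
        os.path.join(rep_dir, "interactions.tsv"), sep="\t", index=False
    )

    criteria: Optional[TargetingCriteria] = None
    if not duplexes:
        log.append(
            f"{rep_dir}: WARNING empty duplex set; criteria output skipped"
        )
        return duplexes, None
    position_profile(duplexes).to_table().to_csv(
        os.path.join(rep_dir, "position_profile.tsv"), sep="\t", index=False
    )
    criteria = infer_criteria(duplexes, config.retain_rate)
    criteria.to_file(os.path.join(rep_dir, "criteria.txt"))

    if validated is not None:
        positives = observable_positives(
            validated,
            profiles,
            srna,
            config.min_peak_abund,
            config.min_mirna_abund,
            config.position_tolerance,
        )
        kept = [d for d in duplexes if passes(d, criteria)]
        result = evaluate(kept, validated, positives, config.position_tolerance)
        with open(os.path.join(rep_dir, "evaluation.tsv"), "w") as handle:
            handle.write("TP\tFP\tP\tSe\tPPV\n")
            handle.write(
                f"{result.TP}\t{result.FP}\t{result.P}\t"
                f"{result.fmt(result.sensitivity)}\t"
                f"{result.fmt(result.precision)}\n"
            )
        if config.run_sweep:
            sweep = retain_sweep(
                duplexes,
                validated,
                positives,
                position_tolerance=config.position_tolerance,
            )
            sweep_to_table(sweep).to_csv(
                os.path.join(rep_dir, "sweep.tsv"), sep="\t", index=False
            )
            log.append(
                f"{rep_dir}: sweep-selected retain rate "
                f"{select_retain(sweep)}"
            )

    # conserved vs species-specific comparison when both classes occur
    by_class: Dict[Conservation, List[Duplex]] = {}
    for d in duplexes:
        if d.mirna.conservation is not None:
            by_class.setdefault(d.mirna.conservation, []).append(d)
    if len(by_class) == 2 and all(len(v) >= 2 for v in by_class.values()):
        conserved_d = by_class[Conservation.CONSERVED]
        specific_d = by_class[Conservation.SPECIES_SPECIFIC]
        report = stats_report(
            position_profile(specific_d), position_profile(conserved_d)
        )
        report.to_csv(os.path.join(rep_dir, "stats.tsv"), sep="\t", index=False)
        ks_p = ks_mfe(
            [d.mfe_ratio for d in specific_d],
            [d.mfe_ratio for d in conserved_d],
            seed=config.seed,
        )
        with open(os.path.join(rep_dir, "stats_mfe.txt"), "w") as handle:
            handle.write(f"ks_mfe_p={ks_p}\n")
    return duplexes, criteria


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline; returns per-replicate duplexes and criteria."""
    if not config.srna or not config.degradome:
        raise ValueError("configuration must name sRNA and degradome inputs")
    if len(config.srna) != len(config.degradome):
        raise ValueError("sRNA and degradome replicate lists differ in length")
    for path in [
        *config.srna,
        *config.degradome,
        config.transcriptome,
        config.mirbase,
        *( [config.genome] if config.genome else [] ),
        *( [config.validated] if config.validated else [] ),
    ]:
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"required input missing: {path!r}")

    os.makedirs(config.out, exist_ok=True)
    log: List[str] = []
    transcriptome = read_transcriptome(config.transcriptome)
    clade_map = (
        load_clade_map(config.clade_map)
        if config.clade_map
        else default_clade_map()
    )
    known = read_mirbase(config.mirbase, clade_map)
    genome = read_transcriptome(config.genome) if config.genome else None
    validated = read_validated(config.validated) if config.validated else None

    n_reps = len(config.srna)
    duplexes_by_rep: List[List[Duplex]] = []
    criteria_by_rep: List[Optional[TargetingCriteria]] = []
    for i in range(n_reps):
        rep_dir = (
            config.out if n_reps == 1 else os.path.join(config.out, f"rep{i + 1}")
        )
        duplexes, criteria = _run_replicate(
            rep_dir,
            config.srna[i],
            config.degradome[i],
            transcriptome,
            known,
            genome,
            validated,
            config,
            log,
        )
        duplexes_by_rep.append(duplexes)
        criteria_by_rep.append(criteria)

    if n_reps > 1:
        _consistency_report(config.out, duplexes_by_rep)

    with open(os.path.join(config.out, "run_log.txt"), "w") as handle:
        handle.write(f"# paretarget {__version__}\n")
        handle.write(f"# finished {datetime.datetime.now().isoformat()}\n")
        params = asdict(config)
        for key in sorted(params):
            handle.write(f"{key}={params[key]}\n")
        for line in log:
            handle.write(f"{line}\n")
    return PipelineResult(config.out, duplexes_by_rep, criteria_by_rep)


def _consistency_report(out_dir: str, duplexes_by_rep: List[List[Duplex]]) -> None:
    import pandas as pd

    keys = sorted({d.key() for dupes in duplexes_by_rep for d in dupes})
    rows = []
    for key in keys:
        row = {
            "mirna_seq": key[0],
            "transcript_id": key[1],
            "cleavage_position": key[2],
        }
        present = 0
        for i, dupes in enumerate(duplexes_by_rep, start=1):
            hit = key in {d.key() for d in dupes}
            row[f"rep{i}"] = int(hit)
            present += hit
        row["n_replicates"] = present
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "consistency.tsv"), sep="\t", index=False
    )
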