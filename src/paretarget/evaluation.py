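"""Sensitivity/precision evaluation against validated interactions.

Following common practice for degradome-supported target prediction,
the validation classes are used in a loose sense: TP are predictions
with experimental validation, FP predictions currently lacking it (they
may simply be unvalidated true targets), and P the experimentally
validated interactions observable in the data (HC peak, expressed
miRNA).  Sensitivity is ``100 * TP / P`` and precision (PPV)
``100 * TP / (TP + FP)``.  Specificity is deliberately not computed: a
comprehensive set of true negatives cannot be assembled from
validation-driven data.

Predicted and validated interactions are matched on (miRNA sequence,
transcript id, cleavage position) with a +/-1 nt position tolerance by
default, since published validation tables mix conventions for which
side of the cleaved bond is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .seqio import ValidatedInteraction

__all__ = [
    "EvaluationResult",
    "evaluate",
    "intersect",
    "comparison_table",
    "OverlapSummary",
]

Key = Tuple[str, str, int]


def _key_of(obj) -> Key:
    """(miRNA sequence, transcript id, cleavage position) of any record."""
    if isinstance(obj, ValidatedInteraction):
        return (obj.mirna_sequence, obj.transcript_id, obj.cleavage_position)
    return (obj.mirna.sequence, obj.transcript_id, obj.cleavage_position)


def _dedup(keys: Sequence[Key]) -> List[Key]:
    return sorted(set(keys))


def _index(keys: Sequence[Key]) -> Dict[Tuple[str, str], Set[int]]:
    index: Dict[Tuple[str, str], Set[int]] = {}
    for seq, tid, pos in keys:
        index.setdefault((seq, tid), set()).add(pos)
    return index


def _matches(key: Key, index: Dict[Tuple[str, str], Set[int]], tol: int) -> bool:
    seq, tid, pos = key
    positions = index.get((seq, tid))
    if not positions:
        return False
    return any(abs(pos - p) <= tol for p in positions)


@dataclass(frozen=True)
class EvaluationResult:
    """TP/FP/P counts with percent sensitivity and precision.

    ``sensitivity``/``precision`` are None (undefined) when their
    denominator is zero; they are never raised as exceptions.
    """

    TP: int
    FP: int
    P: int

    @property
    def sensitivity(self) -> Optional[float]:
        return 100.0 * self.TP / self.P if self.P else None

    @property
    def precision(self) -> Optional[float]:
        total = self.TP + self.FP
        return 100.0 * self.TP / total if total else None

    @staticmethod
    def fmt(value: Optional[float]) -> str:
        """One-decimal display form (half-up), or 'NA' when undefined."""
        if value is None:
            return "NA"
        import decimal

        return str(
            decimal.Decimal(repr(value)).quantize(
                decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
            )
        )


def evaluate(
    predicted: Sequence,
    validated: Sequence[ValidatedInteraction],
    positives: Optional[Sequence[ValidatedInteraction]] = None,
    position_tolerance: int = 1,
) -> EvaluationResult:
    """Evaluate predictions against validated interactions.

    ``positives`` is the subset of validated interactions observable in
    the dataset (HC peaks, expressed miRNAs); it defaults to the whole
    validated set.  Predictions are deduplicated by key before
    counting, and sensitivity is counted against ``positives`` so that
    TP never exceeds P.
    """
    if positives is None:
        positives = validated
    pred_keys = _dedup([_key_of(p) for p in predicted])
    validated_index = _index([_key_of(v) for v in validated])
    positive_keys = _dedup([_key_of(v) for v in positives])
    positive_index = _index(positive_keys)

    tp = sum(_matches(k, validated_index, position_tolerance) for k in pred_keys)
    fp = len(pred_keys) - tp
    tp_se = sum(
        _matches(k, positive_index, position_tolerance) for k in pred_keys
    )
    return EvaluationResult(TP=min(tp_se, len(positive_keys)), FP=fp, P=len(positive_keys))


def comparison_table(results: Dict[str, EvaluationResult]):
    """Side-by-side evaluation of criteria sets as a pandas DataFrame.

    One row per named criteria set with V (positives), captured V, NV,
    Se and PPV; when exactly two sets are compared, the second row also
    carries the Se gain and PPV difference of the second over the first.
    """
    import pandas as pd

    rows = []
    baseline: Optional[EvaluationResult] = None
    for name, result in results.items():
        row = {
            "criteria": name,
            "V": result.P,
            "captured_V": result.TP,
            "NV": result.FP,
            "Se": EvaluationResult.fmt(result.sensitivity),
            "PPV": EvaluationResult.fmt(result.precision),
            "Se_gain": None,
            "PPV_difference": None,
        }
        if baseline is not None and len(results) == 2:
            if None not in (result.sensitivity, baseline.sensitivity):
                row["Se_gain"] = EvaluationResult.fmt(
                    result.sensitivity - baseline.sensitivity
                )
            if None not in (result.precision, baseline.precision):
                row["PPV_difference"] = EvaluationResult.fmt(
                    result.precision - baseline.precision
                )
        if baseline is None:
            baseline = result
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapSummary:
    """Intersection summary of two prediction sets."""

    n_mirnas_a: int
    n_mirnas_b: int
    n_interactions_a: int
    n_interactions_b: int
    shared_a: int  # interactions of A matched in B
    shared_b: int  # interactions of B matched in A
    specific_a: int
    specific_b: int
    mirnas_specific_a: int
    mirnas_specific_b: int


def intersect(
    predictions_a: Sequence,
    predictions_b: Sequence,
    position_tolerance: int = 1,
) -> OverlapSummary:
    """Overlap of two prediction sets, keyed as in :func:`evaluate`.

    Reports per set the distinct miRNAs with at least one target, the
    total (deduplicated) interactions, and the counts specific to each
    set; ``n_interactions_a == shared_a + specific_a`` by construction.
    """
    keys_a = _dedup([_key_of(p) for p in predictions_a])
    keys_b = _dedup([_key_of(p) for p in predictions_b])
    index_a = _index(keys_a)
    index_b = _index(keys_b)
    shared_a = sum(_matches(k, index_b, position_tolerance) for k in keys_a)
    shared_b = sum(_matches(k, index_a, position_tolerance) for k in keys_b)
    mirnas_a = {k[0] for k in keys_a}
    mirnas_b = {k[0] for k in keys_b}
    return OverlapSummary(
        n_mirnas_a=len(mirnas_a),
        n_mirnas_b=len(mirnas_b),
        n_interactions_a=len(keys_a),
        n_interactions_b=len(keys_b),
        shared_a=shared_a,
        shared_b=shared_b,
        specific_a=len(keys_a) - shared_a,
        specific_b=len(keys_b) - shared_b,
        mirnas_specific_a=len(mirnas_a - mirnas_b),
        mirnas_specific_b=len(mirnas_b - mirnas_a),
    )
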