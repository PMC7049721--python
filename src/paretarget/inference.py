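"""Duplex property profiling and data-driven targeting-criteria inference.

The central contract is the *retain rate* r: criteria inferred from a
population of observed high-confidence duplexes must jointly pass at
least a fraction r of that population (default 0.85).  Thresholds are
first set marginally — each count cap at the smallest value covering a
fraction r of duplexes, the score cap at the r-quantile rounded up to
the scoring atom (0.5), the MFE-ratio floor at the (1-r)-quantile
rounded down to 0.01, positional allowances opened only if a duplex in
the retained quantile needs them.  Marginal thresholds alone can
under-retain jointly (their failures need not overlap), so each
threshold is then widened to the fieldwise envelope of the retained
quantile subpopulation (the ceil(r*n) duplexes ranked by score, then
hybridization strength).  Every retained duplex then passes every rule,
so joint retention is guaranteed in one deterministic, order-invariant
step, and criteria inferred at a higher retain rate always pass a
superset of the duplexes passed at a lower one.

The default retain rate is chosen by sweeping r over a grid and taking
the lower endpoint of the first increment where the sensitivity gained
no longer outweighs the precision lost (|dSe|/|dPPV| < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .duplex import (
    GAP,
    GU,
    MATCH,
    MISMATCH,
    Duplex,
    TargetingCriteria,
    duplex_features,
    passes,
)
from .evaluation import EvaluationResult, evaluate
from .seqio import ValidatedInteraction

__all__ = [
    "PositionProfile",
    "position_profile",
    "infer_criteria",
    "SweepRow",
    "retain_sweep",
    "se_ppv_ratio",
    "select_retain",
    "sweep_to_table",
]

_PROPERTIES = (MISMATCH, GU, GAP)

_FEATURE_OF_CAP = {
    "max_mm": "n_mm",
    "max_gu": "n_gu",
    "max_gaps": "n_gaps",
    "max_adjacent_mm": "n_adjacent_mm",
    "max_adjacent_mm_core": "n_adjacent_mm_core",
    "max_mm_core": "n_mm_core",
}


@dataclass
class PositionProfile:
    """Per-position property counts over a duplex population.

    ``counts[property][p-1]`` is the number of duplexes with that
    property at miRNA position p; ``totals[p-1]`` the number of
    duplexes covering position p (the proportion denominator).
    """

    counts: Dict[str, np.ndarray]
    totals: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.totals)

    def proportion(self, prop: str, position: int) -> float:
        total = self.totals[position - 1]
        return float(self.count(prop, position) / total) if total else 0.0

    def count(self, prop: str, position: int) -> int:
        if prop == MATCH:
            others = sum(int(self.counts[q][position - 1]) for q in _PROPERTIES)
            return int(self.totals[position - 1]) - others
        return int(self.counts[prop][position - 1])

    def to_table(self):
        import pandas as pd

        rows = []
        for p in range(1, self.n_positions + 1):
            row = {"position": p, "n": int(self.totals[p - 1])}
            for prop in _PROPERTIES:
                row[f"{prop}_count"] = self.count(prop, p)
                row[f"{prop}_proportion"] = round(self.proportion(prop, p), 6)
            rows.append(row)
        return pd.DataFrame(rows)


def position_profile(duplexes: Sequence[Duplex]) -> PositionProfile:
    """Tabulate mismatch/G:U/gap occurrences per miRNA position."""
    if not duplexes:
        raise ValueError("cannot profile an empty duplex set")
    n_pos = max(len(d.states) for d in duplexes)
    counts = {prop: np.zeros(n_pos, dtype=int) for prop in _PROPERTIES}
    totals = np.zeros(n_pos, dtype=int)
    for d in duplexes:
        for p, state in enumerate(d.states, start=1):
            totals[p - 1] += 1
            if state in counts:
                counts[state][p - 1] += 1
    return PositionProfile(counts=counts, totals=totals)


def _required(n: int, retain_rate: float) -> int:
    return max(1, math.ceil(retain_rate * n - 1e-9))


def _lower_quantile(sorted_values: Sequence[float], q: float, n: int) -> float:
    """Type-1 (no interpolation) lower empirical quantile."""
    idx = max(math.ceil(q * n - 1e-9), 1) - 1
    return sorted_values[min(idx, n - 1)]


def _ceil_half(x: float) -> float:
    return math.ceil(x * 2 - 1e-9) / 2


def _floor_cent(x: float) -> float:
    return math.floor(x * 100 + 1e-9) / 100


def infer_criteria(
    duplexes: Sequence[Duplex], retain_rate: float = 0.85
) -> TargetingCriteria:
    """Infer targeting criteria retaining at least ``retain_rate`` of input.

    See the module docstring for the algorithm.  The result is
    deterministic and invariant to the order of ``duplexes``.
    """
    if not duplexes:
        raise ValueError("cannot infer criteria from an empty duplex set")
    if not 0.0 < retain_rate <= 1.0:
        raise ValueError(f"retain_rate must be in (0, 1], got {retain_rate}")
    n = len(duplexes)
    k = _required(n, retain_rate)
    feats = [duplex_features(d.states) for d in duplexes]

    # retained-quantile subpopulation for the positional allowances:
    # the k duplexes with the tightest duplexes (lowest score, then
    # strongest hybridization), under a total, order-invariant key
    order = sorted(
        range(n),
        key=lambda i: (
            duplexes[i].score,
            -duplexes[i].mfe_ratio,
            duplexes[i].states,
            duplexes[i].mirna.sequence,
            duplexes[i].transcript_id,
            duplexes[i].cleavage_position,
        ),
    )
    retained = order[:k]
    allow10 = any(feats[i]["nonwc_10"] for i in retained)
    allow11 = any(feats[i]["nonwc_11"] for i in retained)

    caps: Dict[str, int] = {}
    for cap_name, feat_name in _FEATURE_OF_CAP.items():
        values = sorted(f[feat_name] for f in feats)
        caps[cap_name] = int(values[k - 1])

    scores = sorted(d.score for d in duplexes)
    max_score = _ceil_half(_lower_quantile(scores, retain_rate, n))
    ratios = sorted(d.mfe_ratio for d in duplexes)
    cutoff = max(0.0, _floor_cent(_lower_quantile(ratios, 1.0 - retain_rate, n)))

    # joint retention: marginal quantiles alone can under-retain (their
    # failures need not overlap), so each threshold is widened to the
    # fieldwise envelope of the retained quantile subpopulation.  Every
    # retained duplex then passes every rule jointly, the result is
    # order-invariant, and because the retained set only grows with the
    # retain rate, criteria inferred at a higher rate pass a superset of
    # the duplexes passed at a lower rate.
    for cap_name, feat_name in _FEATURE_OF_CAP.items():
        caps[cap_name] = max(
            caps[cap_name], max(int(feats[i][feat_name]) for i in retained)
        )
    max_score = max(
        max_score, _ceil_half(max(duplexes[i].score for i in retained))
    )
    cutoff = min(
        cutoff,
        max(0.0, _floor_cent(min(duplexes[i].mfe_ratio for i in retained))),
    )
    return TargetingCriteria(
        allow_mm_pos10=allow10,
        allow_mm_pos11=allow11,
        max_score=max_score,
        mfe_ratio_cutoff=cutoff,
        **caps,
    )


@dataclass(frozen=True)
class SweepRow:
    """One grid point of the retain-rate sweep."""

    retain_rate: float
    n_captured: int
    n_validated: int
    n_nonvalidated: int
    sensitivity: Optional[float]  # percent
    precision: Optional[float]  # percent
    criteria: Optional[TargetingCriteria] = None


def retain_sweep(
    duplexes: Sequence[Duplex],
    validated: Sequence[ValidatedInteraction],
    positives: Optional[Sequence[ValidatedInteraction]] = None,
    start: float = 0.50,
    step: float = 0.05,
    end: float = 1.00,
    position_tolerance: int = 1,
) -> List[SweepRow]:
    """Sweep the retain rate over a grid, re-inferring criteria each time.

    At each grid value, criteria are inferred from the full duplex set,
    the duplexes passing them are evaluated against the validated
    interactions, and the captured/validated/non-validated counts with
    Se and PPV are recorded.
    """
    rows: List[SweepRow] = []
    n_steps = int(round((end - start) / step))
    for i in range(n_steps + 1):
        r = round(start + i * step, 10)
        criteria = infer_criteria(duplexes, r)
        kept = [d for d in duplexes if passes(d, criteria)]
        result = evaluate(kept, validated, positives, position_tolerance)
        rows.append(
            SweepRow(
                retain_rate=r,
                n_captured=result.TP + result.FP,
                n_validated=result.TP,
                n_nonvalidated=result.FP,
                sensitivity=result.sensitivity,
                precision=result.precision,
                criteria=criteria,
            )
        )
    return rows


def se_ppv_ratio(row_lo: SweepRow, row_hi: SweepRow) -> float:
    """|dSe| / |dPPV| across one sweep increment; +inf when PPV does not drop."""
    if row_lo.sensitivity is None or row_hi.sensitivity is None:
        return math.inf
    if row_lo.precision is None or row_hi.precision is None:
        return math.inf
    d_se = row_hi.sensitivity - row_lo.sensitivity
    d_ppv = row_hi.precision - row_lo.precision
    if d_ppv >= 0:
        return math.inf
    return abs(d_se) / abs(d_ppv)


def select_retain(sweep: Sequence[SweepRow]) -> float:
    """Pick the retain rate from a sweep.

    Returns the lower endpoint of the first increment whose
    sensitivity-gain/precision-loss ratio drops below 1; if none does,
    the final grid value.
    """
    if len(sweep) < 2:
        raise ValueError("the sweep needs at least two rows")
    for lo, hi in zip(sweep, sweep[1:]):
        if se_ppv_ratio(lo, hi) < 1.0:
            return lo.retain_rate
    return sweep[-1].retain_rate


def sweep_to_table(sweep: Sequence[SweepRow]):
    """Sweep rows as a DataFrame, with the per-increment Se/PPV ratio."""
    import pandas as pd

    rows = []
    for i, row in enumerate(sweep):
        ratio = se_ppv_ratio(sweep[i - 1], row) if i else None
        rows.append(
            {
                "retain_rate": row.retain_rate,
                "captured": row.n_captured,
                "V": row.n_validated,
                "NV": row.n_nonvalidated,
                "Se": None
                if row.sensitivity is None
                else round(row.sensitivity, 1),
                "PPV": None
                if row.precision is None
                else round(row.precision, 1),
                "se_ppv_ratio": None
                if ratio is None
                else (math.inf if math.isinf(ratio) else round(ratio, 2)),
            }
        )
    return pd.DataFrame(rows)
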