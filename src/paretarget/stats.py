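"""Statistical comparisons of duplex-property profiles and MFE ratios.

Three tests compare interaction subsets (e.g. conserved vs
species-specific miRNAs, with the former as the reference):

* an offset chi-square goodness-of-fit test per miRNA position, with
  the reference subset's category proportions as the expected
  distribution (zero expected cells are stabilized with +0.5 — the
  "offset");
* a two-sided Fisher exact test per position and property, each
  position against the pooled counts of all remaining positions;
* a two-sample Kolmogorov-Smirnov test on MFE-ratio distributions,
  after subsampling the larger set without replacement (seeded) to the
  size of the smaller.

P-values are reported raw; the conventional significance threshold
(0.05) belongs to the reporting layer.  An optional Benjamini-Hochberg
correction across positions is available but off by default.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .duplex import GAP, GU, MATCH, MISMATCH
from .inference import PositionProfile

__all__ = [
    "chi2_offset_position",
    "chi2_offset_profile",
    "fisher_position",
    "fisher_exact_2x2",
    "ks_mfe",
    "stats_report",
]

_CATEGORIES = (MISMATCH, GU, GAP, MATCH)
ZERO_OFFSET = 0.5


def _offset_chi2(observed: np.ndarray, expected: np.ndarray) -> Optional[float]:
    """Goodness-of-fit p-value with +0.5 stabilization of zero expecteds."""
    total = observed.sum()
    if total == 0:
        return None
    expected = expected.astype(float).copy()
    expected[expected == 0] = ZERO_OFFSET
    expected *= total / expected.sum()
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    return float(sps.chi2.sf(stat, df))


def chi2_offset_position(
    profile_obs: PositionProfile, profile_ref: PositionProfile, position: int
) -> Optional[float]:
    """Offset chi-square at one position: observed vs reference categories.

    Builds the observed {mismatch, gu, gap, match} counts at the
    position; expected counts are the reference set's category
    proportions there scaled to the observed total.  Returns None when
    the observed set does not cover the position.
    """
    obs = np.array(
        [profile_obs.count(c, position) for c in _CATEGORIES], dtype=float
    )
    ref = np.array(
        [profile_ref.count(c, position) for c in _CATEGORIES], dtype=float
    )
    if ref.sum() == 0:
        return None
    expected = ref / ref.sum() * obs.sum()
    return _offset_chi2(obs, expected)


def chi2_offset_profile(
    profile_obs: PositionProfile,
    profile_ref: PositionProfile,
    prop: str = MISMATCH,
) -> Optional[float]:
    """Global offset chi-square of one property across all positions.

    Pools the property's per-position counts into a single contingency
    vector (degrees of freedom = positions - 1), assessing the overall
    difference in localization between the two sets.
    """
    n = min(profile_obs.n_positions, profile_ref.n_positions)
    obs = np.array([profile_obs.count(prop, p) for p in range(1, n + 1)], float)
    ref = np.array([profile_ref.count(prop, p) for p in range(1, n + 1)], float)
    if obs.sum() == 0 or ref.sum() == 0:
        return None
    expected = ref / ref.sum() * obs.sum()
    return _offset_chi2(obs, expected)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for [[a, b], [c, d]]."""
    if a + b + c + d == 0:
        return 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def fisher_position(
    profile_a: PositionProfile,
    profile_b: PositionProfile,
    prop: str,
    position: int,
) -> float:
    """Fisher exact test of one property at one position between two sets.

    The 2x2 table opposes the property's count at the position to the
    summed counts over all remaining positions, per set.
    """
    n = min(profile_a.n_positions, profile_b.n_positions)
    a_at = profile_a.count(prop, position)
    b_at = profile_b.count(prop, position)
    a_rest = sum(profile_a.count(prop, p) for p in range(1, n + 1)) - a_at
    b_rest = sum(profile_b.count(prop, p) for p in range(1, n + 1)) - b_at
    return fisher_exact_2x2(a_at, a_rest, b_at, b_rest)


def ks_mfe(
    ratios_a: Sequence[float], ratios_b: Sequence[float], seed: int = 0
) -> float:
    """Two-sample KS p-value on MFE ratios after size-matched subsampling.

    The larger sample is subsampled without replacement (seeded) to the
    size of the smaller before the two-sided test, so sample-size
    imbalance does not drive the comparison.  Same seed, same result.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both MFE-ratio samples must be non-empty")
    rng = np.random.default_rng(seed)
    if a.size > b.size:
        a = rng.choice(a, size=b.size, replace=False)
    elif b.size > a.size:
        b = rng.choice(b, size=a.size, replace=False)
    result = sps.ks_2samp(a, b, alternative="two-sided")
    return float(result.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adjusted[i] = running
    return adjusted


def stats_report(
    profile_obs: PositionProfile,
    profile_ref: PositionProfile,
    bh_correct: bool = False,
):
    """Per-position test table: chi2_p, fisher_mm_p, fisher_gu_p, fisher_gap_p."""
    import pandas as pd

    n = min(profile_obs.n_positions, profile_ref.n_positions)
    rows = []
    for p in range(1, n + 1):
        rows.append(
            {
                "position": p,
                "chi2_p": chi2_offset_position(profile_obs, profile_ref, p),
                "fisher_mm_p": fisher_position(
                    profile_obs, profile_ref, MISMATCH, p
                ),
                "fisher_gu_p": fisher_position(profile_obs, profile_ref, GU, p),
                "fisher_gap_p": fisher_position(
                    profile_obs, profile_ref, GAP, p
                ),
            }
        )
    table = pd.DataFrame(rows)
    if bh_correct:
        for col in ("chi2_p", "fisher_mm_p", "fisher_gu_p", "fisher_gap_p"):
            mask = table[col].notna()
            table.loc[mask, col] = benjamini_hochberg(
                table.loc[mask, col].to_numpy()
            )
    return table
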