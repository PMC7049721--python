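"""Duplex geometry, alignment (vs. exhaustive oracle), scoring, criteria."""

import numpy as np
import pytest

from paretarget._thermo import NearestNeighborBackend, perfect_complement
from paretarget.duplex import (
    GAP,
    GU,
    MATCH,
    MISMATCH,
    TargetingCriteria,
    align_duplex,
    duplex_features,
    extract_site,
    mfe_ratio,
    pair_state,
    passes,
    score_duplex,
    state_string,
)
from paretarget.seqio import normalize_rna

from conftest import make_duplex

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
GUP = {"G": "U", "U": "G"}


def plant(rng, mirna, t, tx_len=300, edits=()):
    """Embed the perfect site for ``mirna`` at cleavage position t, then
    apply (position, new_target_nt) edits in miRNA coordinates."""
    tx = list(rng.choice(list("ACGU"), tx_len))
    L = len(mirna)
    for p in range(1, L + 1):
        tx[t + 10 - p - 1] = WC[mirna[p - 1]]
    for p, nt in edits:
        tx[t + 10 - p - 1] = nt
    return "".join(tx)


class TestExtractSite:
    def test_window_coordinates_follow_anchor_formula(self):
        site = extract_site("A" * 300, 100, 21, 0)
        assert (site.start, site.end) == (89, 109)
        # miRNA position 1 pairs coordinate t + 10 - 1 = 109
        assert site.end == 100 + 10 - 1

    def test_gap_budget_widens_window(self):
        site = extract_site("A" * 300, 100, 20, 1)
        assert (site.start, site.end) == (89, 110)

    def test_truncation_flag_near_transcript_start(self):
        assert extract_site("A" * 300, 5, 21, 0).truncated is True

    def test_out_of_range_position_is_error(self):
        with pytest.raises(ValueError):
            extract_site("A" * 50, 60, 21, 0)


class TestAlignDuplex:
    def test_perfect_complement_all_match(self, rng):
        m = "UGACAGAAGAGAGUGAGCACA"
        tx = plant(rng, m, 100)
        al = align_duplex(m, tx, 100)
        assert set(al.states) == {MATCH}
        assert al.score == 0.0

    def test_single_wobble_at_position_16(self, rng):
        m = "UGACAGAAGAGAGUGGGCACA"  # position 16 is G
        assert m[15] == "G"
        tx = plant(rng, m, 100, edits=[(16, "U")])  # G:U wobble
        al = align_duplex(m, tx, 100)
        assert al.states[15] == GU
        assert al.score == 0.5

    def test_mismatch_at_anchor_cannot_be_bulged_away(self, rng):
        m = "UGACAGAAGAGAGUGAGCACA"
        bad = [nt for nt in "ACGU" if nt not in (WC[m[9]], GUP.get(m[9]))][0]
        tx = plant(rng, m, 100, edits=[(10, bad)])
        al = align_duplex(m, tx, 100)
        assert al.states[9] == MISMATCH


def oracle_alignments(mirna, tx, t, max_gaps=1):
    """Exhaustive enumeration over bulge placements (independent oracle).

    Yields (score, n_gaps, tie_rank, type_rank, states) for the no-gap
    alignment and for every single-bulge placement.
    """
    L = len(mirna)

    def at(c):
        return tx[c - 1] if 1 <= c <= len(tx) else None

    def states_for(gap_pos, gap_type):
        states = []
        for p in range(1, L + 1):
            partner = t + 10 - p
            if gap_pos is not None:
                if gap_type == "mirna":
                    if gap_pos >= 11 and p > gap_pos:
                        partner = t + 11 - p
                    elif gap_pos <= 9 and p < gap_pos:
                        partner = t + 9 - p
                else:  # target bulge attached at gap_pos
                    if gap_pos >= 11 and p >= gap_pos:
                        partner = t + 9 - p
                    elif gap_pos <= 9 and p <= gap_pos:
                        partner = t + 11 - p
            if gap_pos == p:
                states.append(GAP)
            else:
                states.append(pair_state(mirna[p - 1], at(partner)))
        return tuple(states)

    yield (score_duplex(states_for(None, None)), 0, -1, -1,
           states_for(None, None))
    if max_gaps >= 1:
        for p in list(range(1, 10)) + list(range(11, L + 1)):
            for rank, kind in enumerate(("mirna", "target")):
                states = states_for(p, kind)
                yield (score_duplex(states), 1, L - p, rank, states)


class TestAlignmentOracle:
    def test_dp_equals_exhaustive_enumeration(self, rng):
        """DP alignment matches brute-force minimal-score enumeration on
        random sites with planted edits and at most one bulge."""
        for trial in range(120):
            L = int(rng.integers(20, 23))
            m = "".join(rng.choice(list("ACGU"), L))
            t = int(rng.integers(L + 5, 280))
            n_edits = int(rng.integers(0, 4))
            edit_positions = rng.choice(
                np.arange(1, L + 1), size=n_edits, replace=False
            )
            edits = [
                (int(p), str(rng.choice(list("ACGU")))) for p in edit_positions
            ]
            tx = plant(rng, m, t, tx_len=300, edits=edits)
            # occasionally delete one target nucleotide to force a bulge
            if rng.random() < 0.4:
                cut = int(rng.integers(t - L + 10, t + 8))
                if cut != t:
                    tx = tx[: cut - 1] + tx[cut:]
                    t = t - 1 if cut < t else t
            al = align_duplex(m, tx, t, max_gaps=1)
            best = min(oracle_alignments(m, tx, t, 1))
            assert al.score == best[0], f"trial {trial}"
            assert al.states == best[4], f"trial {trial}"

    def test_planted_single_bulge_recovered(self, rng):
        m = "UGACAGAAGAGAGUGAGCACA"
        t = 100
        tx = plant(rng, m, t)
        # remove the target nucleotide pairing position 16: the 3' tail
        # realigns with one bulge instead of five mismatches
        cut = t + 10 - 16
        tx = tx[: cut - 1] + tx[cut:]
        al = align_duplex(m, tx, t - 1, max_gaps=1)
        assert al.n_gaps == 1
        assert al.score <= 1.0


class TestScore:
    def test_all_match_scores_zero(self):
        assert score_duplex([MATCH] * 21 ) == 0.0

    def test_core_mismatch_counts_double(self):
        states = [MATCH] * 21
        states[4] = MISMATCH  # position 5 is in the core region 2-13
        assert score_duplex(states) == 2.0

    def test_mixed_penalties_add(self):
        states = [MATCH] * 21
        states[15] = GU  # position 16: 0.5 x 1
        states[0] = MISMATCH  # position 1: 1.0 x 1
        assert score_duplex(states) == 1.5

    def test_moving_mismatch_into_core_adds_its_penalty_again(self, rng):
        for _ in range(30):
            states = list(random_base := [MATCH] * 21)
            outside = int(rng.choice([1, *range(14, 22)]))
            inside = int(rng.integers(2, 14))
            states[outside - 1] = MISMATCH
            s_out = score_duplex(states)
            states[outside - 1] = MATCH
            states[inside - 1] = MISMATCH
            assert score_duplex(states) == s_out + 1.0


class TestMfeRatio:
    def test_perfect_duplex_ratio_is_one(self):
        assert mfe_ratio("UGACAGAAGAGAGUGAGCACA", None, [MATCH] * 21) == 1.0

    def test_any_mismatch_strictly_below_one(self, rng):
        for _ in range(40):
            m = "".join(rng.choice(list("ACGU"), 21))
            states = [MATCH] * 21
            states[int(rng.integers(0, 21))] = MISMATCH
            assert mfe_ratio(m, None, states) < 1.0

    def test_adding_mismatch_never_raises_ratio_or_lowers_score(self, rng):
        for _ in range(60):
            m = "".join(rng.choice(list("ACGU"), 21))
            states = list(random_base := [MATCH] * 21)
            for p in rng.choice(np.arange(21), size=int(rng.integers(0, 4)),
                                replace=False):
                states[p] = MISMATCH
            r0, s0 = mfe_ratio(m, None, states), score_duplex(states)
            p = int(rng.integers(0, 21))
            if states[p] == MISMATCH:
                continue
            states[p] = MISMATCH
            assert mfe_ratio(m, None, states) <= r0 + 1e-12
            assert score_duplex(states) >= s0

    def test_default_backend_tracks_external_folding_engine(self, rng):
        """Cross-backend harness: the self-contained energy model agrees
        with ViennaRNA's RNAduplex on the MFE ratio of 100 random
        near-complementary duplexes (mean within 0.05; see docs)."""
        RNA = pytest.importorskip("RNA")
        from paretarget._thermo import ViennaBackend

        nn, vienna = NearestNeighborBackend(), ViennaBackend()
        diffs = []
        for _ in range(100):
            L = int(rng.integers(20, 23))
            m = "".join(rng.choice(list("ACGU"), L))
            states = [MATCH] * L
            for p in rng.choice(np.arange(1, L + 1),
                                size=int(rng.integers(0, 4)), replace=False):
                nt = m[p - 1]
                states[p - 1] = (
                    str(rng.choice([MISMATCH, GU])) if nt in "GU" else MISMATCH
                )
            site = []
            for p in range(L, 0, -1):
                nt = m[p - 1]
                if states[p - 1] == MATCH:
                    site.append(WC[nt])
                elif states[p - 1] == GU:
                    site.append(GUP[nt])
                else:
                    site.append(
                        str(rng.choice([c for c in "ACGU"
                                        if c != WC[nt] and c != GUP.get(nt)]))
                    )
            site = "".join(site)
            diffs.append(
                abs(nn.ratio(m, None, states) - vienna.ratio(m, site, states))
            )
        diffs = np.array(diffs)
        assert diffs.mean() <= 0.05
        assert (diffs <= 0.05).mean() >= 0.80
        assert diffs.max() <= 0.15


class TestCriteria:
    def test_perfect_duplex_passes_any_criteria(self):
        d = make_duplex([MATCH] * 21, mfe=1.0)
        assert passes(d, TargetingCriteria.permissive())
        assert passes(d, TargetingCriteria.classic())

    def test_mismatch_at_10_fails_without_allowance(self):
        states = [MATCH] * 21
        states[9] = MISMATCH
        d = make_duplex(states, mfe=0.9)
        assert not passes(d, TargetingCriteria(allow_mm_pos10=False))
        assert passes(d, TargetingCriteria(allow_mm_pos10=True))

    def test_gu_at_10_is_governed_by_the_allowance(self):
        states = [MATCH] * 21
        states[9] = GU
        d = make_duplex(states, mfe=0.9)
        assert not passes(d, TargetingCriteria(allow_mm_pos10=False))

    def test_run_of_three_mismatches_counts_two_adjacent(self):
        states = [MATCH] * 21
        for p in (14, 15, 16):
            states[p - 1] = MISMATCH
        feats = duplex_features(states)
        assert feats["n_adjacent_mm"] == 2
        d = make_duplex(states, mfe=0.9)
        assert not passes(d, TargetingCriteria(max_adjacent_mm=1))
        assert passes(d, TargetingCriteria(max_adjacent_mm=2))

    def test_core_caps_apply_to_positions_2_to_13(self):
        states = [MATCH] * 21
        states[4] = states[7] = MISMATCH  # two core mismatches
        d = make_duplex(states, mfe=0.9)
        assert not passes(d, TargetingCriteria(max_mm_core=1, max_score=10.0))
        assert passes(d, TargetingCriteria(max_mm_core=2, max_score=10.0))

    def test_mfe_cutoff_is_a_floor(self):
        d = make_duplex([MATCH] * 21, mfe=0.64)
        assert not passes(d, TargetingCriteria(mfe_ratio_cutoff=0.65))
        assert passes(d, TargetingCriteria(mfe_ratio_cutoff=0.64))

    def test_criteria_file_round_trip(self, tmp_path):
        criteria = TargetingCriteria(
            allow_mm_pos10=False,
            max_score=4.5,
            mfe_ratio_cutoff=0.72,
            max_mm=3,
        )
        path = tmp_path / "criteria.txt"
        criteria.to_file(str(path))
        assert TargetingCriteria.from_file(str(path)) == criteria

    def test_state_string_round_trip_alphabet(self):
        states = (MATCH, GU, MISMATCH, GAP)
        assert state_string(states) == "=ox-"
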