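"""Shared fixtures and synthetic-population helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from paretarget.duplex import Duplex, score_duplex
from paretarget.mirna_catalog import MirnaCandidate

STATE_NAMES = ("match", "gu", "mismatch", "gap")
NTS = list("ACGU")


def random_states(rng, length=21, p=(0.78, 0.10, 0.09, 0.03)):
    return tuple(rng.choice(STATE_NAMES, size=length, p=list(p)))


def make_duplex(states, mfe=0.8, seq=None, transcript="TX", position=100, rng=None):
    """Duplex stub with a consistent score for inference/evaluation tests."""
    if seq is None:
        seq = "".join((rng or np.random.default_rng(0)).choice(NTS, len(states)))
    return Duplex(
        mirna=MirnaCandidate(sequence=seq, abundance=10),
        transcript_id=transcript,
        cleavage_position=position,
        states=tuple(states),
        score=score_duplex(states),
        mfe_ratio=float(mfe),
    )


def random_population(rng, n, length=21):
    """Random duplex stubs with varied states and MFE ratios."""
    out = []
    for i in range(n):
        states = random_states(rng, length)
        out.append(
            make_duplex(
                states,
                mfe=float(np.clip(rng.normal(0.8, 0.12), 0.01, 1.0)),
                seq="".join(rng.choice(NTS, length)),
                transcript=f"T{i}",
                position=int(rng.integers(30, 200)),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
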