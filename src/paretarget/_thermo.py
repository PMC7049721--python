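"""Nearest-neighbour hybridization energies for miRNA-target duplexes.

The default backend evaluates the fixed duplex alignment produced by
the aligner: contiguous runs of paired positions (Watson-Crick or G:U)
contribute Turner-style 37C stacking energies; unpaired runs
(mismatches, bulges) interrupt stacking and add a destabilizing loop
term; helix initiation and terminal AU/GU penalties follow the usual
duplex conventions.  Only the MFE *ratio* (observed energy over the
energy of the miRNA with its perfect complement) is consumed
downstream, so small systematic offsets cancel.

An external folding engine (ViennaRNA's RNAduplex, through its Python
bindings) is pluggable behind the same interface and serves as an
independent cross-check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

__all__ = ["NearestNeighborBackend", "ViennaBackend", "perfect_complement"]

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# Turner 2004 37C stacking free energies (kcal/mol).  Key: two
# consecutive pairs read 5'->3' on the guide strand; a pair is written
# guide-nt + target-nt.  Entries not listed are resolved through the
# strand-exchange symmetry (p1, p2) == (swap(p2), swap(p1)).
_STACK: Dict[Tuple[str, str], float] = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # G:U wobble-containing stacks
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27,
    ("GU", "GU"): -0.50,
    ("UG", "UG"): -0.50,
    ("GU", "UG"): +0.47,
    ("UG", "GU"): -0.57,
}


def _swap(pair: str) -> str:
    return pair[1] + pair[0]


def _stack_energy(p1: str, p2: str) -> float:
    if (p1, p2) in _STACK:
        return _STACK[(p1, p2)]
    key = (_swap(p2), _swap(p1))
    if key in _STACK:
        return _STACK[key]
    raise KeyError(f"no stacking entry for step {p1}/{p2}")


def perfect_complement(mirna_seq: str) -> str:
    """The target site perfectly Watson-Crick paired to a miRNA (5'->3')."""
    return "".join(_WC[nt] for nt in reversed(mirna_seq))


class NearestNeighborBackend:
    """Self-contained duplex energy model over a fixed alignment.

    Parameters
    ----------
    init : duplex initiation penalty (kcal/mol).
    terminal_au : penalty per AU/GU pair closing either duplex end.
    loop_open, loop_per_nt : destabilization of an internal unpaired
        run (mismatch/bulge) of length k, ``loop_open + k * loop_per_nt``;
        the defaults are calibrated once against RNAduplex energies on
        random near-complementary duplexes.

    Isolated pairs at the duplex ends (no stacked neighbour) contribute
    nothing: an optimal fold would leave them open.
    """

    def __init__(
        self,
        init: float = 4.09,
        terminal_au: float = 0.45,
        loop_open: float = 0.0,
        loop_per_nt: float = 0.5,
    ) -> None:
        self.init = init
        self.terminal_au = terminal_au
        self.loop_open = loop_open
        self.loop_per_nt = loop_per_nt

    def _pairs(self, mirna_seq: str, states: Sequence[str]) -> List[Optional[str]]:
        """Per position: the guide+target pair string, or None if unpaired."""
        pairs: List[Optional[str]] = []
        for nt, state in zip(mirna_seq, states):
            if state == "match":
                pairs.append(nt + _WC[nt])
            elif state == "gu":
                if nt == "G":
                    pairs.append("GU")
                elif nt == "U":
                    pairs.append("UG")
                else:  # cannot wobble: treat as unpaired
                    pairs.append(None)
            else:
                pairs.append(None)
        return pairs

    def duplex_energy(self, mirna_seq: str, states: Sequence[str]) -> float:
        """Free energy (kcal/mol) of the aligned duplex; negative = stable."""
        pairs = self._pairs(mirna_seq, states)
        # trim isolated end pairs: a terminal pair with no stacked
        # neighbour is left unpaired by any optimal fold
        paired_idx = [i for i, p in enumerate(pairs) if p is not None]

        def _stacked(i: int) -> bool:
            return (i - 1 >= 0 and pairs[i - 1] is not None) or (
                i + 1 < len(pairs) and pairs[i + 1] is not None
            )

        while paired_idx and not _stacked(paired_idx[0]):
            pairs[paired_idx[0]] = None
            paired_idx.pop(0)
        while paired_idx and not _stacked(paired_idx[-1]):
            pairs[paired_idx[-1]] = None
            paired_idx.pop()
        energy = self.init
        # stacking over consecutive paired positions; the rare
        # destabilizing wobble-wobble steps are treated as unstacked,
        # which keeps energy monotone in the number of broken pairs
        for p1, p2 in zip(pairs, pairs[1:]):
            if p1 is not None and p2 is not None:
                energy += min(_stack_energy(p1, p2), 0.0)
        # every unpaired position is charged, terminal runs included;
        # together with the per-position charge exceeding the terminal
        # AU/GU penalty this keeps the energy monotone under any
        # match -> mismatch conversion
        n_unpaired = sum(1 for p in pairs if p is None)
        energy += n_unpaired * self.loop_per_nt
        if paired_idx:
            run_count = 0
            previous_paired = True
            for p in pairs:
                if p is None and previous_paired:
                    run_count += 1
                previous_paired = p is not None
            energy += run_count * self.loop_open
            # terminal AU/GU penalties at the outermost paired positions
            for i in (paired_idx[0], paired_idx[-1]):
                if pairs[i] in ("AU", "UA", "GU", "UG"):
                    energy += self.terminal_au
        return energy

    def ratio(
        self,
        mirna_seq: str,
        site_seq: Optional[str],
        states: Sequence[str],
    ) -> float:
        """MFE ratio: observed duplex energy over the perfect-duplex energy.

        Both energies come from this model, so a perfect duplex yields
        exactly 1.0 and any weakened duplex a smaller ratio.  Duplexes
        with non-negative (unstable) energy are reported as 0.0.
        """
        perfect = self.duplex_energy(mirna_seq, ["match"] * len(mirna_seq))
        observed = self.duplex_energy(mirna_seq, states)
        if perfect >= 0:
            raise ValueError(
                f"perfect duplex for {mirna_seq} is not stable under the "
                "energy model"
            )
        if observed >= 0:
            return 0.0
        return min(observed / perfect, 1.0)


class ViennaBackend:
    """MFE ratio from ViennaRNA's RNAduplex (optional external engine)."""

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as err:  # pragma: no cover
            raise ImportError(
                "the ViennaRNA Python bindings are required for this backend"
            ) from err
        self._RNA = RNA

    def _energy(self, seq_a: str, seq_b: str) -> float:
        return self._RNA.duplexfold(seq_a, seq_b).energy

    def ratio(
        self,
        mirna_seq: str,
        site_seq: Optional[str],
        states: Sequence[str],
    ) -> float:
        if site_seq is None:
            raise ValueError("the ViennaRNA backend requires the target site")
        perfect = self._energy(mirna_seq, perfect_complement(mirna_seq))
        if perfect >= 0:
            raise ValueError(f"perfect duplex for {mirna_seq} is not stable")
        observed = self._energy(mirna_seq, site_seq)
        if observed >= 0:
            return 0.0
        return min(observed / perfect, 1.0)
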