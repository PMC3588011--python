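"""RNA secondary-structure prediction by weighted maximum base pairing.

Candidate pre-miRNA hairpins are judged purely on pairing geometry (arm
placement of the mature/star duplex, mismatch and bulge counts), so the
folder implements a Nussinov-style dynamic programme that maximises a
weighted pair count (GC=3, AU=2, GU=1) over all nested structures, rather
than a full thermodynamic model.  An external thermodynamic folder can be
swapped in for cross-checks, but nothing downstream requires free energies.

Coordinates are 0-based throughout; structures are nested (no pseudoknots)
and every hairpin loop spans at least ``min_loop`` unpaired bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

#: pair weights for Watson-Crick and G:U wobble pairs (DNA alphabet, T==U)
PAIR_WEIGHTS: dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AT"): 2,
    frozenset("GT"): 1,
}

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def pair_weight(a: str, b: str) -> int:
    """Weight of pairing base ``a`` with ``b`` (0 = not pairable)."""
    return PAIR_WEIGHTS.get(frozenset((a.upper().replace("U", "T"),
                                       b.upper().replace("U", "T"))), 0)


@dataclass
class SecondaryStructure:
    """A nested secondary structure over one sequence.

    Attributes
    ----------
    sequence : str
        The folded sequence (as given, U/T preserved).
    dotbracket : str
        Vienna dot-bracket rendering.
    pair_table : list[int]
        ``pair_table[i]`` is the partner of position ``i`` or -1 if unpaired.
    score : int
        The optimised weighted pair count.
    min_loop : int
        Minimum hairpin-loop size enforced during folding.
    """

    sequence: str
    dotbracket: str
    pair_table: list[int]
    score: int
    min_loop: int = 3

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.pair_table) if j > i]

    def to_vienna(self, name: str = "structure") -> str:
        return f">{name} score={self.score}\n{self.sequence}\n{self.dotbracket}\n"


def _weight_matrix(seq: str) -> np.ndarray:
    codes = np.array([_ENC[c] for c in seq.upper()], dtype=np.int8)
    table = np.zeros((4, 4), dtype=np.int64)
    table[_ENC["G"], _ENC["C"]] = table[_ENC["C"], _ENC["G"]] = 3
    table[_ENC["A"], _ENC["T"]] = table[_ENC["T"], _ENC["A"]] = 2
    table[_ENC["G"], _ENC["T"]] = table[_ENC["T"], _ENC["G"]] = 1
    return table[codes[:, None], codes[None, :]]


@njit(cache=True)
def _fill(w: np.ndarray, n: int, min_loop: int) -> np.ndarray:  # pragma: no cover
    W = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            best = W[i, j - 1]
            for k in range(i, j - min_loop):
                if w[k, j] == 0:
                    continue
                left = W[i, k - 1] if k > i else 0
                cand = left + w[k, j] + W[k + 1, j - 1]
                if cand > best:
                    best = cand
            W[i, j] = best
    return W


def fold(sequence: str, min_loop: int = 3) -> SecondaryStructure:
    """Fold ``sequence`` into its maximum-weight nested structure.

    The DP recursion over interval ``[i, j]`` considers ``j`` unpaired or
    ``j`` paired with some ``k`` (``j - k > min_loop``); ties are broken
    deterministically during traceback by preferring a paired ``j`` with the
    smallest partner ``k`` over leaving ``j`` unpaired.

    Raises
    ------
    ValueError
        If the sequence contains characters outside A/C/G/T/U or is shorter
        than ``min_loop + 2``.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTU")
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence length {n} < min_loop + 2 = {min_loop + 2}")

    w = _weight_matrix(seq)
    W = _fill(w, n, min_loop)

    pair_table = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = W[i, j]
        chosen = None
        for k in range(i, j - min_loop):
            if w[k, j] == 0:
                continue
            left = W[i, k - 1] if k > i else 0
            inner = W[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if left + w[k, j] + inner == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i, j - 1))
        else:
            pair_table[chosen] = j
            pair_table[j] = chosen
            if chosen > i:
                stack.append((i, chosen - 1))
            stack.append((chosen + 1, j - 1))

    db = "".join("(" if (p := pair_table[i]) > i else ")" if p != -1 else "."
                 for i in range(n))
    return SecondaryStructure(sequence=sequence, dotbracket=db,
                              pair_table=pair_table, score=int(W[0, n - 1]),
                              min_loop=min_loop)


# ---------------------------------------------------------------------------
# hairpin geometry


@dataclass
class Hairpin:
    """The stem-loop around one terminal loop of a structure."""

    loop_start: int      # first base of the terminal loop (inclusive)
    loop_end: int        # past-the-end of the terminal loop
    stem_start: int      # outermost 5' base of the enclosing helix chain
    stem_end: int        # past-the-end (outermost 3' base + 1)
    n_stem_pairs: int = 0


def hairpins(structure: SecondaryStructure) -> list[Hairpin]:
    """All stem-loops of a structure, one per terminal loop.

    A terminal loop is a pair (i, j) with no paired base strictly inside;
    the enclosing helix chain follows nested pairs outward until a
    bifurcation or unpaired flank intervenes (interior loops and bulges do
    not break the chain).
    """
    pt = structure.pair_table
    n = len(pt)
    out: list[Hairpin] = []
    for i, j in ((a, b) for a, b in enumerate(pt) if b > a):
        if any(pt[k] != -1 for k in range(i + 1, j)):
            continue
        # follow the chain of enclosing pairs outward
        oi, oj = i, j
        pairs = 1
        while True:
            # nearest paired base 5' of oi whose partner is 3' of oj
            k = oi - 1
            while k >= 0 and pt[k] == -1:
                k -= 1
            if k < 0 or pt[k] < oj:
                break
            # ensure (k, pt[k]) directly encloses with no bifurcation between
            between_5 = range(k + 1, oi)
            between_3 = range(oj + 1, pt[k])
            if any(pt[x] != -1 for x in between_5) or any(pt[x] != -1 for x in between_3):
                break
            oi, oj = k, pt[k]
            pairs += 1
        out.append(Hairpin(loop_start=i + 1, loop_end=j,
                           stem_start=oi, stem_end=oj + 1, n_stem_pairs=pairs))
    return out


def major_hairpin(structure: SecondaryStructure) -> Hairpin | None:
    """The stem-loop with the most pairs in its helix chain (ties: leftmost)."""
    hps = hairpins(structure)
    if not hps:
        return None
    return max(hps, key=lambda h: (h.n_stem_pairs, -h.loop_start))


def arm_of(structure: SecondaryStructure, interval: tuple[int, int]) -> str:
    """Place ``interval`` (0-based half-open) relative to the major stem-loop.

    Returns one of ``five_prime_arm``, ``three_prime_arm``, ``loop``,
    ``spanning`` or ``outside``.  An interval entirely between the stem's
    outermost 5' base and the terminal loop is ``five_prime_arm`` (mirrored
    for 3'); overlap with the terminal loop is ``loop`` (contained) or
    ``spanning`` (partial); anything else, or a structure without a hairpin,
    is ``outside``.
    """
    s, e = interval
    if not (0 <= s < e <= len(structure.sequence)):
        raise ValueError(f"interval {interval} outside sequence")
    hp = major_hairpin(structure)
    if hp is None:
        return "outside"
    if s >= hp.loop_start and e <= hp.loop_end:
        return "loop"
    if s < hp.loop_end and e > hp.loop_start:
        return "spanning"
    if e <= hp.loop_start and s >= hp.stem_start:
        return "five_prime_arm"
    if s >= hp.loop_end and e <= hp.stem_end:
        return "three_prime_arm"
    return "outside"
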