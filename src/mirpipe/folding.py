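"""RNA hairpin folding and duplex energetics.

The folding search space is deliberately restricted to *single-stem*
(multibranch-free) nested structures: one ladder of base pairs with
bulges and internal loops, closing a terminal hairpin loop of >= 3
unpaired nucleotides.  Every precursor candidate the pipeline evaluates is
a single hairpin, so excluding multibranch loops keeps the dynamic
programme quadratic-ish in sequence length and exhaustively testable by
enumeration at small scale.

The energy model is a compact nearest-neighbour one: stacking energies for
adjacent base pairs (Watson-Crick + G:U wobble, symmetric under strand
reversal), size-dependent hairpin/bulge/internal-loop penalties with
logarithmic extrapolation, and an optional flat per-pair bonus (used by the
unit test model).  Interior loops are capped at 30 nt total, the standard
cap in secondary-structure prediction; since loop penalties are
non-negative and pairs only gain energy by stacking on *adjacent* pairs,
larger loops can never improve a single-stem optimum within one helix run.

The inner dynamic-programming kernel is JIT-compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "default_model",
    "unit_model",
    "fold_hairpin",
    "nussinov_maxpairs",
    "duplex_mfe",
    "perfect_complement_mfe",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
]

BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(BASES)}
# Pair identifiers: AU UA CG GC GU UG
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_ID = -np.ones((4, 4), dtype=np.int64)
for _k, _p in enumerate(PAIR_NAMES):
    _PAIR_ID[_CODE[_p[0]], _CODE[_p[1]]] = _k

MIN_HAIRPIN_LOOP = 3
MAX_INTERIOR_LOOP = 30
_LOG_EXTRAP = 1.08  # kcal/mol multiplier for log-size loop extrapolation
_INF = 1e9


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r} in sequence") from exc


def _extrapolate(table: dict[int, float], up_to: int) -> np.ndarray:
    sizes = sorted(table)
    base = sizes[-1]
    out = np.full(up_to + 1, _INF)
    for s, e in table.items():
        out[s] = e
    for s in range(base + 1, up_to + 1):
        out[s] = table[base] + _LOG_EXTRAP * math.log(s / base)
    return out


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbour energy parameters for hairpins and duplexes.

    ``stack[p1, p2]`` is the stacking energy (kcal/mol) of inner pair p2 on
    outer pair p1 (pair ids in :data:`PAIR_NAMES` order).  Loop arrays are
    indexed by loop size.  ``pair_bonus`` is added once per formed pair
    (0 in the thermodynamic model; -1 in the unit test model).
    ``duplex_mismatch_penalty`` is the per-position interior penalty used
    for miRNA/target duplex scoring.
    """

    stack: np.ndarray
    hairpin: np.ndarray
    bulge: np.ndarray
    internal: np.ndarray
    pair_bonus: float = 0.0
    duplex_mismatch_penalty: float = 0.5

    def pair_id(self, a: str, b: str) -> int:
        ca, cb = _CODE.get(a, -1), _CODE.get(b, -1)
        if ca < 0 or cb < 0:
            return -1
        return int(_PAIR_ID[ca, cb])

    def can_pair(self, a: str, b: str) -> bool:
        return self.pair_id(a, b) >= 0


def _load_tables() -> tuple[np.ndarray, dict[str, dict[int, float]]]:
    data = resources.files("mirpipe.data")
    stack = np.zeros((6, 6))
    lines = (data / "stack_energies.tsv").read_text().strip().splitlines()
    header = lines[0].split("\t")[1:]
    for line in lines[1:]:
        cells = line.split("\t")
        outer = PAIR_NAMES.index(cells[0])
        for name, val in zip(header, cells[1:]):
            stack[outer, PAIR_NAMES.index(name)] = float(val)
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    for line in (data / "loop_penalties.tsv").read_text().strip().splitlines()[1:]:
        kind, size, energy = line.split("\t")
        loops[kind][int(size)] = float(energy)
    return stack, loops


_DEFAULT: EnergyModel | None = None


def default_model() -> EnergyModel:
    """The shipped thermodynamic model (loaded once from the data files)."""
    global _DEFAULT
    if _DEFAULT is None:
        stack, loops = _load_tables()
        _DEFAULT = EnergyModel(
            stack=stack,
            hairpin=_extrapolate(loops["hairpin"], 600),
            bulge=_extrapolate(loops["bulge"], MAX_INTERIOR_LOOP),
            internal=_extrapolate(loops["internal"], MAX_INTERIOR_LOOP),
        )
    return _DEFAULT


def unit_model() -> EnergyModel:
    """-1 per pair, zero stacking and loop penalties (testing model)."""
    return EnergyModel(
        stack=np.zeros((6, 6)),
        hairpin=np.zeros(601),
        bulge=np.zeros(MAX_INTERIOR_LOOP + 1),
        internal=np.zeros(MAX_INTERIOR_LOOP + 1),
        pair_bonus=-1.0,
        duplex_mismatch_penalty=0.0,
    )


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested, multibranch-free secondary structure.

    Pairs are 0-based ``(i, j)`` with ``i < j``; the dot-bracket rendering
    is kept consistent with the pair set by construction and checked on
    init, along with non-crossing nesting and the minimum hairpin loop.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValueError("an index participates in more than one pair")
            seen.update((i, j))
        for (i, j) in self.pairs:
            if j - i - 1 < MIN_HAIRPIN_LOOP and not any(
                i < k < l < j for k, l in self.pairs
            ):
                raise ValueError(f"hairpin loop of pair ({i},{j}) shorter than 3")
            for (k, l) in self.pairs:
                if i < k < j < l:
                    raise ValueError("crossing pairs")
        if pairs_to_dotbracket(len(self.sequence), self.pairs) != self.dotbracket:
            raise ValueError("dot-bracket inconsistent with pair set")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def pairs_to_dotbracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dotbracket_to_pairs(dotbracket: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return tuple(sorted(pairs))


@njit(cache=True)
def _fold_kernel(codes, pair_id, stack, hairpin, bulge, internal, pair_bonus):
    n = codes.shape[0]
    INF = 1e9
    E = np.full((n, n), INF)
    P = np.zeros((n, n), dtype=np.int64)  # pair count of optimum closed by (i,j)
    K = -np.ones((n, n), dtype=np.int64)
    L = -np.ones((n, n), dtype=np.int64)
    for span in range(4, n):  # j - i
        for i in range(0, n - span):
            j = i + span
            pid_ij = pair_id[codes[i], codes[j]]
            if pid_ij < 0:
                continue
            best = INF
            best_p = 0
            best_k = -1
            best_l = -1
            loop = j - i - 1
            if loop >= 3 and loop < hairpin.shape[0]:
                best = hairpin[loop]
                best_p = 1
            for k in range(i + 1, j - 1):
                left = k - i - 1
                if left > 30:
                    break
                for l in range(j - 1, k, -1):
                    right = j - 1 - l
                    if left + right > 30:
                        break
                    if E[k, l] >= INF:
                        continue
                    pid_kl = pair_id[codes[k], codes[l]]
                    if pid_kl < 0:
                        continue
                    if left == 0 and right == 0:
                        e = E[k, l] + stack[pid_ij, pid_kl]
                    elif left == 0 or right == 0:
                        e = E[k, l] + bulge[left + right]
                    else:
                        e = E[k, l] + internal[left + right]
                    p = P[k, l] + 1
                    if e < best - 1e-9 or (e < best + 1e-9 and p < best_p):
                        best = e
                        best_p = p
                        best_k = k
                        best_l = l
            if best < INF:
                E[i, j] = best + pair_bonus
                P[i, j] = best_p
                K[i, j] = best_k
                L[i, j] = best_l
    # Global optimum: the empty structure (0.0) or the best closed stem.
    gi = -1
    gj = -1
    gbest = 0.0
    gp = 0
    for i in range(n):
        for j in range(i + 1, n):
            if E[i, j] < INF:
                if E[i, j] < gbest - 1e-9 or (
                    E[i, j] < gbest + 1e-9 and P[i, j] < gp and gi >= 0
                ):
                    gbest = E[i, j]
                    gp = P[i, j]
                    gi = i
                    gj = j
    return gbest, gi, gj, K, L


def fold_hairpin(sequence: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-energy single-stem structure of ``sequence`` under ``model``.

    Deterministic; ties broken toward fewer pairs, then the first optimal
    transition in a fixed scan order.  A sequence admitting no stabilising
    stem folds to the unpaired structure with mfe 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    model = model or default_model()
    seq = sequence.upper().replace("T", "U")
    codes = encode(seq)
    n = len(seq)
    if n < 2:
        return SecondaryStructure(seq, (), "." * n, 0.0)
    mfe, gi, gj, K, L = _fold_kernel(
        codes,
        _PAIR_ID,
        model.stack,
        model.hairpin,
        model.bulge,
        model.internal,
        model.pair_bonus,
    )
    pairs: list[tuple[int, int]] = []
    if gi >= 0:
        i, j = gi, gj
        while i >= 0:
            pairs.append((i, j))
            i, j = int(K[i, j]), int(L[i, j])
        mfe = float(mfe)
    else:
        mfe = 0.0
    pairs_t = tuple(sorted(pairs))
    return SecondaryStructure(seq, pairs_t, pairs_to_dotbracket(n, pairs_t), mfe)


def nussinov_maxpairs(sequence: str) -> int:
    """Maximum number of nested pairs (hairpin loop >= 3) in a single stem.

    Nussinov-style recursion without the bifurcation case, i.e. over the
    same multibranch-free structure space as :func:`fold_hairpin`; used as
    a structural cross-check of the energy DP under the unit model.
    """
    seq = sequence.upper().replace("T", "U")
    codes = encode(seq)
    n = len(seq)
    if n < 5:
        return 0
    N = [[0] * n for _ in range(n)]
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            best = max(N[i + 1][j], N[i][j - 1])
            if _PAIR_ID[codes[i], codes[j]] >= 0:
                inner = N[i + 1][j - 1] if j - i - 1 > MIN_HAIRPIN_LOOP else 0
                cand = inner + 1
                if cand > best:
                    best = cand
            N[i][j] = best
    return N[0][n - 1]


# ---------------------------------------------------------------------------
# miRNA/target duplex energetics


def duplex_pair_states(mirna: str, site: str) -> list[str]:
    """Per-miRNA-position pair state against an antiparallel site.

    Position p of the miRNA (0-based from its 5' end) faces position
    ``len(site)-1-p`` of the site.  States: ``match`` (Watson-Crick),
    ``GU`` (wobble), ``mismatch``.
    """
    if len(mirna) != len(site):
        raise ValueError("duplex site must have the same length as the miRNA")
    wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    states = []
    L = len(mirna)
    for p in range(L):
        a, b = mirna[p], site[L - 1 - p]
        if (a, b) in wc:
            states.append("match")
        elif (a, b) in {("G", "U"), ("U", "G")}:
            states.append("GU")
        else:
            states.append("mismatch")
    return states


def duplex_mfe(
    mirna: str,
    site: str,
    pairing: Sequence[str] | None = None,
    model: EnergyModel | None = None,
) -> float:
    """Hybridisation energy of an ungapped, full-length miRNA/site duplex.

    Energy = sum of stacking terms over consecutive paired positions plus a
    non-negative penalty per interior mismatch.  The perfect complement of
    a miRNA minimises this over all sites of equal length.
    """
    model = model or default_model()
    mirna = mirna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")
    if pairing is None:
        pairing = duplex_pair_states(mirna, site)
    if len(pairing) != len(mirna):
        raise ValueError("pairing must cover every miRNA position")
    L = len(mirna)
    energy = 0.0
    for p in range(L):
        if pairing[p] == "mismatch":
            energy += model.duplex_mismatch_penalty
            continue
        if p + 1 < L and pairing[p + 1] != "mismatch":
            pid1 = model.pair_id(mirna[p], site[L - 1 - p])
            pid2 = model.pair_id(mirna[p + 1], site[L - 2 - p])
            if pid1 >= 0 and pid2 >= 0:
                energy += model.stack[pid1, pid2]
    return energy


def perfect_complement_mfe(mirna: str, model: EnergyModel | None = None) -> float:
    """Energy of the miRNA bound to its exact reverse complement."""
    mirna = mirna.upper().replace("T", "U")
    rc = mirna.translate(str.maketrans("ACGU", "UGCA"))[::-1]
    return duplex_mfe(mirna, rc, model=model)
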