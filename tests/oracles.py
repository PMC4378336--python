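"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, separate
from the package implementation paths it cross-checks: plain-Python
recursion/enumeration, no shared helpers, no loop-size caps.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import product

# --------------------------------------------------------------------------
# Edit distance (global, unit costs) by straightforward DP


def edit_distance(a: str, b: str) -> int:
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


# --------------------------------------------------------------------------
# Single-stem folding by exhaustive recursion (no interior-loop cap)

_PAIRS = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}
_PAIR_INDEX = {
    ("A", "U"): 0, ("U", "A"): 1, ("C", "G"): 2,
    ("G", "C"): 3, ("G", "U"): 4, ("U", "G"): 5,
}


def ladder_energy(seq: str, pairs: list[tuple[int, int]], model) -> float:
    """Energy of a single-stem structure given outer-to-inner pair list."""
    if not pairs:
        return 0.0
    e = model.pair_bonus * len(pairs)
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        left, right = k - i - 1, j - 1 - l
        if left == 0 and right == 0:
            p1 = _PAIR_INDEX[(seq[i], seq[j])]
            p2 = _PAIR_INDEX[(seq[k], seq[l])]
            e += float(model.stack[p1, p2])
        elif left == 0 or right == 0:
            e += float(model.bulge[left + right])
        else:
            e += float(model.internal[left + right])
    ii, jj = pairs[-1]
    e += float(model.hairpin[jj - ii - 1])
    return e


def brute_force_mfe(seq: str, model) -> tuple[float, int]:
    """Minimum energy over all single-stem structures, by recursion with
    memoisation and no loop-size restrictions.  Returns (mfe, pairs)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def closed(i: int, j: int) -> tuple[float, int]:
        # best (energy, npairs) of a stem whose outermost pair is (i, j)
        if (seq[i], seq[j]) not in _PAIRS:
            return (math.inf, 0)
        best = (math.inf, 0)
        if j - i - 1 >= 3:
            best = (float(model.hairpin[j - i - 1]), 1)
        for k in range(i + 1, j - 1):
            for l in range(k + 4, j):
                e_in, p_in = closed(k, l)
                if not math.isfinite(e_in):
                    continue
                left, right = k - i - 1, j - 1 - l
                if left == 0 and right == 0:
                    p1 = _PAIR_INDEX[(seq[i], seq[j])]
                    p2 = _PAIR_INDEX[(seq[k], seq[l])]
                    step = float(model.stack[p1, p2])
                elif left == 0 or right == 0:
                    step = float(model.bulge[left + right]) if left + right < len(model.bulge) else math.inf
                else:
                    step = float(model.internal[left + right]) if left + right < len(model.internal) else math.inf
                cand = (e_in + step, p_in + 1)
                if cand < best:
                    best = cand
        return (best[0] + model.pair_bonus, best[1])

    best = (0.0, 0)
    for i in range(n):
        for j in range(i + 4, n):
            e, p = closed(i, j)
            if e < best[0] - 1e-12:
                best = (e, p)
    return best


def enumerate_all_ladders(seq: str):
    """Literally yield every single-stem structure (outer-to-inner pair
    lists) of a short sequence."""
    n = len(seq)

    def extend(prefix: list[tuple[int, int]], i: int, j: int):
        yield list(prefix)
        for k in range(i, j - 3):
            for l in range(k + 4, j):
                if (seq[k], seq[l]) in _PAIRS:
                    prefix.append((k, l))
                    yield from extend(prefix, k + 1, l)
                    prefix.pop()

    for ladder in extend([], 0, n):
        if ladder:
            yield ladder


# --------------------------------------------------------------------------
# Target-rule checker, re-coded from the rule statements

GU = {("G", "U"), ("U", "G")}
WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def pair_state(mi: str, tb: str) -> str:
    if (mi, tb) in WC:
        return "match"
    if (mi, tb) in GU:
        return "GU"
    return "mismatch"


def rule_check(states: list[str], energy_ratio: float) -> set[str]:
    """All violated target rules for a duplex given its per-position states
    (miRNA 5'->3') and energy ratio percentage."""
    bad: set[str] = set()
    score = sum({"match": 0.0, "GU": 0.5, "mismatch": 1.0}[s] for s in states)
    if score > 4.0:
        bad.add("i")
    runs, cur = [], 0
    for s in states:
        cur = cur + 1 if s == "mismatch" else 0
        runs.append(cur)
    if max(runs, default=0) > 2:
        bad.add("ii")
    if any(s == "mismatch" for s in states[1:12]):
        bad.add("iii")
    if len(states) >= 11 and (states[9] != "match" or states[10] != "match"):
        bad.add("iv")
    head = states[:12]
    if sum({"match": 0.0, "GU": 0.5, "mismatch": 1.0}[s] for s in head) > 2.5:
        bad.add("v")
    if energy_ratio < 74.0:
        bad.add("vi")
    return bad


# --------------------------------------------------------------------------
# Nearest-neighbour Tm recomputation (SantaLucia unified parameters)

_NN = {  # dH (kcal/mol), dS (cal/mol/K)
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def tm_oracle(primer: str, na_eq_mm: float, dnac1_nm: float) -> float:
    dh, ds = 0.0, 0.0
    for a, b in zip(primer, primer[1:]):
        h, s = _NN[a + b]
        dh += h
        ds += s
    for terminal in (primer[0], primer[-1]):
        if terminal in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    ds += 0.368 * (len(primer) - 1) * math.log(na_eq_mm / 1000.0)
    k = dnac1_nm * 1e-9  # primer excess over template
    R = 1.987
    return 1000.0 * dh / (ds + R * math.log(k)) - 273.15
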