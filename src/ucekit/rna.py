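"""RNA secondary structure scoring for candidate structured elements.

The built-in folder is a Nussinov-style dynamic program over nested
structures with nearest-neighbor stacking bonuses: Watson-Crick and GU
wobble pairs, hairpin loops of at least three unpaired bases, lonely pairs
permitted, no pseudoknots. It is deliberately not a Turner-parameter
thermodynamic model; energies are in arbitrary model units (lower = more
stable). An external Vienna-compatible backend can be plugged in through
the ``folder`` callable for absolute free energies.

Structural significance is assessed by comparing the observed minimum
energy against the distribution over exact dinucleotide-preserving
randomizations (Altschul-Erickson algorithm), expressed as a z-score.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FoldResult",
    "ZscoreResult",
    "fold_mfe",
    "dinucleotide_shuffle",
    "dinucleotide_counts",
    "mfe_zscore",
    "length_zscore_correlation",
    "structure_energy",
    "ViennaFolder",
    "PAIR_ENERGY",
    "STACK_BONUS",
    "MIN_HAIRPIN",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop

# pair formation energies (model units); +inf marks a forbidden pair
_INF = math.inf
PAIR_ENERGY = np.full((4, 4), _INF)
for (a, b), e in {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}.items():
    PAIR_ENERGY[_CODE[a], _CODE[b]] = e
STACK_BONUS = -1.0  # extra stability when (i+1, j-1) pairs directly inside (i, j)


@dataclass
class FoldResult:
    """A dot-bracket structure and its folding score (lower = more stable)."""

    structure: str
    energy: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        stack, out = [], []
        for k, c in enumerate(self.structure):
            if c == "(":
                stack.append(k)
            elif c == ")":
                out.append((stack.pop(), k))
        return sorted(out)


def _encode(seq: str) -> np.ndarray:
    s = seq.upper()
    bad = set(s) - set(_CODE)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return np.array([_CODE[c] for c in s], dtype=np.int8)


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of an explicit pair set under the built-in scoring model.

    Sum of pair energies plus a stacking bonus for every pair (i, j) whose
    immediate interior (i+1, j-1) is also paired.
    """
    codes = _encode(seq)
    pair_set = set(map(tuple, pairs))
    e = 0.0
    for i, j in pair_set:
        pe = PAIR_ENERGY[codes[i], codes[j]]
        if not np.isfinite(pe):
            raise ValueError(f"bases at {i},{j} cannot pair")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError(f"hairpin below minimum size at pair ({i},{j})")
        e += pe
        if (i + 1, j - 1) in pair_set:
            e += STACK_BONUS
    return e


def _fold_dp(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill the DP tables over inclusive spans.

    ``W[i, j]`` is the best (lowest) energy of any nested structure on
    s[i..j]; ``V[i, j]`` the best given that (i, j) is paired. Empty or
    sub-hairpin spans score 0.
    """
    n = len(codes)
    W = np.zeros((n, n))
    V = np.full((n, n), np.inf)
    pe = PAIR_ENERGY[codes[:, None], codes[None, :]]
    for j in range(n):
        for i in range(j - MIN_HAIRPIN - 1, -1, -1):
            if np.isfinite(pe[i, j]):
                interior = W[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                stacked = V[i + 1, j - 1] + STACK_BONUS
                V[i, j] = pe[i, j] + min(interior, stacked)
            best = W[i, j - 1] if j - 1 >= i else 0.0  # j unpaired
            ks = np.arange(i, j - MIN_HAIRPIN)
            if len(ks):
                prefix = np.empty(len(ks))
                prefix[0] = 0.0
                if len(ks) > 1:
                    prefix[1:] = W[i, ks[1:] - 1]
                m = (prefix + V[ks, j]).min()
                if m < best:
                    best = m
            W[i, j] = best
    return W, V


def _trace_W(codes, W, V, i, j, pairs):
    """Recover one optimal pair set for span [i, j] inclusive."""
    if j - i <= MIN_HAIRPIN:
        return
    unpaired = W[i, j - 1] if j - 1 >= i else 0.0
    if np.isclose(W[i, j], unpaired):
        _trace_W(codes, W, V, i, j - 1, pairs)
        return
    for k in range(i, j - MIN_HAIRPIN):
        prefix = W[i, k - 1] if k - 1 >= i else 0.0
        if np.isfinite(V[k, j]) and np.isclose(W[i, j], prefix + V[k, j]):
            _trace_W(codes, W, V, i, k - 1, pairs)
            _trace_V(codes, W, V, k, j, pairs)
            return
    _trace_W(codes, W, V, i, j - 1, pairs)  # numerical fallback


def _trace_V(codes, W, V, i, j, pairs):
    pairs.append((i, j))
    pe = PAIR_ENERGY[codes[i], codes[j]]
    stacked = V[i + 1, j - 1] + STACK_BONUS
    if np.isfinite(stacked) and np.isclose(V[i, j], pe + stacked):
        _trace_V(codes, W, V, i + 1, j - 1, pairs)
    else:
        _trace_W(codes, W, V, i + 1, j - 1, pairs)


def _builtin_fold(seq: str) -> FoldResult:
    codes = _encode(seq)
    n = len(codes)
    if n < MIN_HAIRPIN + 2:
        return FoldResult("." * n, 0.0)
    W, V = _fold_dp(codes)
    energy = float(W[0, n - 1])
    if energy >= 0:
        return FoldResult("." * n, 0.0)
    pairs: list[tuple[int, int]] = []
    _trace_W(codes, W, V, 0, n - 1, pairs)
    structure = ["."] * n
    for a, b in pairs:
        structure[a] = "("
        structure[b] = ")"
    return FoldResult("".join(structure), energy)


class ViennaFolder:
    """External folding backend calling the RNAfold executable."""

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise FileNotFoundError(f"{executable} not found on PATH")
        self.executable = executable

    def __call__(self, seq: str) -> FoldResult:
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=seq.upper().replace("T", "U") + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = proc.stdout.strip().splitlines()
        struct, _, rest = lines[-1].partition(" ")
        energy = float(rest.strip().strip("()"))
        return FoldResult(struct, energy)


def fold_mfe(seq: str, folder: Callable[[str], FoldResult] | None = None) -> FoldResult:
    """Minimum-energy nested structure of a DNA/RNA sequence.

    T and U are equivalent on input. With no ``folder``, the built-in
    stacking-aware Nussinov dynamic program is used; any callable mapping a
    sequence to a :class:`FoldResult` (e.g. :class:`ViennaFolder`) may be
    substituted.
    """
    if folder is None:
        return _builtin_fold(seq)
    return folder(seq)


# ---------------------------------------------------------------------------
# Dinucleotide shuffling (Altschul-Erickson)


def dinucleotide_counts(seq: str) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the input's dinucleotide count matrix.

    Altschul-Erickson construction: sample a random arborescence of
    last-exit edges directed toward the terminal vertex, shuffle the
    remaining edge multiset per vertex, and read off the Eulerian walk from
    the first character. Preserves mononucleotide counts and both endpoints;
    deterministic under a fixed generator state.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # sample last-exit edges forming a tree into `last`
    for _ in range(10_000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample a valid arborescence")
    pools = {}
    for v, succ in edges.items():
        pool = list(succ)
        if v in last_edge:
            pool.remove(last_edge[v])
        perm = rng.permutation(len(pool))
        pool = [pool[k] for k in perm]
        if v in last_edge:
            pool.append(last_edge[v])
        pools[v] = pool
    out = [seq[0]]
    cursor = {v: 0 for v in edges}
    cur = seq[0]
    total = len(seq) - 1
    for _ in range(total):
        nxt = pools[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# Z-scores


@dataclass
class ZscoreResult:
    """Observed energy vs the dinucleotide-shuffle null distribution."""

    observed_mfe: float
    shuffle_mean: float
    shuffle_sd: float
    z: float | None
    n_shuffles: int

    @property
    def flagged(self) -> bool:
        return self.z is None


def mfe_zscore(
    seq: str,
    n_shuffles: int = 100,
    folder: Callable[[str], FoldResult] | None = None,
    rng: np.random.Generator | None = None,
) -> ZscoreResult:
    """Standardized folding energy against the dinucleotide-shuffle null.

    z = (observed - null mean) / null sd with the sample (n-1) standard
    deviation; negative z means more stable than the null. A degenerate
    null (sd = 0, e.g. a homopolymer) yields a flagged result with z
    undefined rather than zero.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    observed = fold_mfe(seq, folder).energy
    null = np.array(
        [fold_mfe(dinucleotide_shuffle(seq, rng), folder).energy for _ in range(n_shuffles)]
    )
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else None
    return ZscoreResult(observed, mean, sd, z, n_shuffles)


def length_zscore_correlation(records: Sequence[Mapping[str, float]]) -> dict:
    """Pearson correlation between element length and structure z-score.

    Records with undefined z are excluded (their count is reported); fewer
    than three finite records, or zero variance in either variable, is an
    error. The p-value is the two-sided t transform with n - 2 df.
    """
    usable = [
        (r["length"], r["z"])
        for r in records
        if r.get("z") is not None and np.isfinite(r["z"])
    ]
    n_excluded = len(records) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 records with finite z-scores")
    lengths, zs = map(np.asarray, zip(*usable))
    if np.ptp(lengths) == 0 or np.ptp(zs) == 0:
        raise ValueError("degenerate input: constant length or z")
    r, p = stats.pearsonr(lengths, zs)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "n_used": len(usable),
        "n_excluded": n_excluded,
    }
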