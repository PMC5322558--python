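"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written the slow, obvious way, sharing no
code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- scan oracle -----------------------------------------------------------


def scan_oracle(blocks, min_len, required_species=None):
    """Per-column brute force: mark each conserved column, extract maximal
    runs of length >= min_len. Returns a sorted list of (chrom, start, end)."""
    found = []
    for block in blocks:
        rows = {sp: r.text.upper() for sp, r in block.rows.items()}
        if required_species and not set(required_species) <= set(rows):
            continue
        texts = list(rows.values())
        width = len(texts[0])
        ref = block.ref_row.text.upper()
        conserved = []
        for c in range(width):
            chars = {t[c] for t in texts}
            conserved.append(len(chars) == 1 and chars.pop() in "ACGT")
        # reference coordinate per column
        pos, coords = block.ref_start, []
        for c in range(width):
            coords.append(pos)
            if ref[c] != "-":
                pos += 1
        c = 0
        while c < width:
            if conserved[c]:
                run_start = c
                while c < width and conserved[c]:
                    c += 1
                if c - run_start >= min_len:
                    found.append(
                        (block.ref_chrom, coords[run_start], coords[run_start] + (c - run_start))
                    )
            else:
                c += 1
    return sorted(found)


# --- pruning oracle --------------------------------------------------------


def pruning_oracle(tree, model, leaf_bases):
    """Likelihood of one column by explicit summation over all internal-node
    state assignments (feasible for <= 5 leaves)."""
    P = model.transition_matrices()
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leafpos = {l: k for k, l in enumerate(tree.leaves)}
    total = 0.0
    for states in itertools.product(range(4), repeat=len(internal)):
        assign = dict(zip(internal, states))
        for l in tree.leaves:
            assign[l] = leaf_bases[leafpos[l]]
        p = model.pi[assign[tree.root]]
        for i in range(tree.n_nodes):
            if i != tree.root:
                p *= P[i][assign[tree.parent[i]], assign[i]]
        total += p
    return float(np.log(total))


# --- RNA folding oracle ----------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIR_E = {
    (2, 1): -3.0, (1, 2): -3.0,
    (0, 3): -2.0, (3, 0): -2.0,
    (2, 3): -1.0, (3, 2): -1.0,
}


def _enumerate_pairings(codes, i, j):
    """All nested pair sets on codes[i..j] with hairpins >= 3."""
    if j - i <= 3:
        yield frozenset()
        return
    for s in _enumerate_pairings(codes, i, j - 1):
        yield s
    for k in range(i, j - 3):
        if (codes[k], codes[j]) in _PAIR_E:
            for left in _enumerate_pairings(codes, i, k - 1):
                for inner in _enumerate_pairings(codes, k + 1, j - 1):
                    yield left | inner | frozenset([(k, j)])


def fold_oracle(seq):
    """Minimum energy over exhaustive enumeration of nested structures."""
    codes = [_CODE[c] for c in seq.upper()]
    best = 0.0
    for pairs in set(_enumerate_pairings(codes, 0, len(codes) - 1)):
        e = 0.0
        for i, j in pairs:
            e += _PAIR_E[(codes[i], codes[j])]
            if (i + 1, j - 1) in pairs:
                e += -1.0
        best = min(best, e)
    return best


# --- annotation overlap oracle ---------------------------------------------

_PRECEDENCE = ["cds", "utr", "intron", "rna_gene"]


def overlap_oracle(elements, intervals):
    """Per-base classification by linear scan over every annotation."""
    counts = {c: 0 for c in _PRECEDENCE + ["none"]}
    for e in elements:
        for pos in range(e.start, e.end):
            hit = [
                cat
                for chrom, s, t, cat in intervals
                if chrom == e.chrom and s <= pos < t
            ]
            if hit:
                best = min(hit, key=_PRECEDENCE.index)
                counts[best] += 1
            else:
                counts["none"] += 1
    total = sum(counts.values())
    return {c: (v / total if total else 0.0) for c, v in counts.items()}


# --- Wilcoxon permutation oracle -------------------------------------------


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def ustat(sample):
        rank_sum = sum(ranks[v] for v in sample)
        return rank_sum - n * (n + 1) / 2

    u_obs = ustat(x)
    total_u = len(x) * len(y)
    dev_obs = abs(u_obs - total_u / 2)
    count = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        sample = [pooled[i] for i in combo]
        count += 1
        if abs(ustat(sample) - total_u / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / count
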