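"""Ultraconserved-element scan over MAF alignment blocks.

An ultraconserved element (UCE) here is a maximal run of alignment columns,
at least ``min_len`` long, in which every species shows the identical
unambiguous base with no gaps — zero substitutions and zero indels across the
whole species set. Runs are evaluated within blocks only; reference
coordinates are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from fnmatch import fnmatch
from typing import Iterable, Sequence

import numpy as np

from .maf import MafBlock

__all__ = [
    "ConservedElement",
    "scan_ultraconserved",
    "filter_unmapped",
    "name_elements",
    "length_summary",
    "elements_to_bed",
    "elements_to_fasta",
    "elements_to_table",
]



@dataclass(frozen=True)
class ConservedElement:
    """A perfectly conserved, reference-anchored interval.

    ``start``/``end`` are 0-based half-open reference coordinates, so
    ``end - start == len(sequence)``. ``name`` follows the ``<chrom>.<k>``
    ordinal convention and is assigned by :func:`name_elements`.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    n_species: int
    name: str | None = None

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"interval width {self.end - self.start} != sequence length "
                f"{len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("element sequence must contain only A,C,G,T")

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_ultraconserved(
    blocks: Iterable[MafBlock],
    min_len: int = 80,
    required_species: Sequence[str] | None = None,
) -> list[ConservedElement]:
    """Extract maximal perfectly conserved runs of length >= ``min_len``.

    A column qualifies iff (a) the block contains every required species,
    (b) no row carries a gap, and (c) every row shows the same unambiguous
    base (case-insensitive; any N or ambiguity code disqualifies). Runs never
    stitch across block boundaries.

    Parameters
    ----------
    blocks : iterable of MafBlock
    min_len : int
        Minimum element length in columns (80 bp is the conventional cutoff).
    required_species : sequence of str, optional
        Species that must be present in a block for its columns to count.
        Defaults to requiring only the reference species' presence.

    Returns
    -------
    list of ConservedElement, sorted by (chrom, start).

    Raises
    ------
    ValueError
        If ``min_len < 1``, or a required species never appears in any block.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    required = set(required_species) if required_species else None
    if required is not None and not required:
        raise ValueError("required_species must be non-empty when given")
    seen_species: set[str] = set()
    out: list[ConservedElement] = []
    n_blocks = 0
    for block in blocks:
        n_blocks += 1
        seen_species.update(block.rows)
        if required is not None and not required <= set(block.rows):
            continue
        out.extend(_scan_block(block, min_len))
    if n_blocks and required is not None:
        missing = required - seen_species
        if missing:
            raise ValueError(f"species never observed in any block: {sorted(missing)}")
    out.sort(key=lambda e: (e.chrom, e.start, e.end))
    return out


def _scan_block(block: MafBlock, min_len: int) -> list[ConservedElement]:
    rows = [r.text.upper().encode("ascii") for r in block.rows.values()]
    arr = np.frombuffer(b"".join(rows), dtype=np.uint8).reshape(len(rows), -1)
    ref = block.ref_row.text.upper().encode("ascii")
    ref_arr = np.frombuffer(ref, dtype=np.uint8)
    # identical in every row, and that base is unambiguous; equality plus an
    # unambiguous reference base also rules out gaps and Ns in all rows
    all_equal = (arr == arr[0]).all(axis=0)
    unambiguous = np.isin(arr[0], np.frombuffer(b"ACGT", dtype=np.uint8))
    conserved = all_equal & unambiguous
    if not conserved.any():
        return []
    # reference coordinate of each column (valid wherever ref is ungapped)
    ref_gapless = ref_arr != ord("-")
    ref_pos = block.ref_start + np.cumsum(ref_gapless) - 1
    # maximal runs of conserved columns
    padded = np.concatenate(([False], conserved, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    elements = []
    n_sp = len(block.rows)
    for c0, c1 in zip(starts.tolist(), ends.tolist()):
        if c1 - c0 < min_len:
            continue
        seq = ref[c0:c1].decode("ascii")
        g_start = int(ref_pos[c0])
        elements.append(
            ConservedElement(
                chrom=block.ref_chrom,
                start=g_start,
                end=g_start + (c1 - c0),
                sequence=seq,
                n_species=n_sp,
            )
        )
    return elements


def filter_unmapped(
    elements: Sequence[ConservedElement], excluded_patterns: Sequence[str]
) -> tuple[list[ConservedElement], int]:
    """Drop elements on chromosomes matching any glob pattern.

    Returns ``(kept, n_removed)``; relative order is preserved. Typical use
    drops elements on unmapped contigs with patterns like ``chrU*``.
    """
    kept = [
        e
        for e in elements
        if not any(fnmatch(e.chrom, pat) for pat in excluded_patterns)
    ]
    return kept, len(elements) - len(kept)


def name_elements(elements: Sequence[ConservedElement]) -> list[ConservedElement]:
    """Assign ``<chrom>.<k>`` names, numbering 1..k by ascending start.

    Input is sorted by (chrom, start, end) first, so shuffled input yields
    the same names as sorted input. Duplicate (chrom, start) pairs are an
    error.
    """
    ordered = sorted(elements, key=lambda e: (e.chrom, e.start, e.end))
    seen: set[tuple[str, int]] = set()
    counters: Counter[str] = Counter()
    named = []
    for e in ordered:
        key = (e.chrom, e.start)
        if key in seen:
            raise ValueError(f"duplicate element position {key}")
        seen.add(key)
        counters[e.chrom] += 1
        named.append(replace(e, name=f"{e.chrom}.{counters[e.chrom]}"))
    return named


def length_summary(
    elements: Sequence[ConservedElement], bin_width: int = 1
) -> dict:
    """Length histogram plus count/min/max (min/max are None when empty)."""
    lengths = [e.length for e in elements]
    hist: Counter[int] = Counter((l // bin_width) * bin_width for l in lengths)
    return {
        "count": len(lengths),
        "min": min(lengths) if lengths else None,
        "max": max(lengths) if lengths else None,
        "histogram": dict(sorted(hist.items())),
        "bin_width": bin_width,
    }


def elements_to_bed(elements: Sequence[ConservedElement]) -> str:
    """BED6 text: score = element length, strand '+'."""
    lines = [
        f"{e.chrom}\t{e.start}\t{e.end}\t{e.name or '.'}\t{e.length}\t+"
        for e in elements
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def elements_to_fasta(elements: Sequence[ConservedElement]) -> str:
    chunks = []
    for e in elements:
        header = e.name or f"{e.chrom}:{e.start}-{e.end}"
        chunks.append(f">{header}\n{e.sequence}\n")
    return "".join(chunks)


def elements_to_table(elements: Sequence[ConservedElement]) -> str:
    """Tab-delimited element table with a header row."""
    lines = ["chrom\tstart\tend\tname\tlength\tn_species"]
    for e in elements:
        lines.append(
            f"{e.chrom}\t{e.start}\t{e.end}\t{e.name or '.'}\t{e.length}\t{e.n_species}"
        )
    return "\n".join(lines) + "\n"
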