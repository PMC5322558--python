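"""Base composition and annotation overlap analysis of conserved elements.

Covers the core-vs-flank A+T contrast (central 60 bp of an element against
60 bp of immediately flanking sequence on each side, pooled), the Wilcoxon
rank-sum test used to compare those samples, per-base-pair classification
of elements against genome annotation (CDS > UTR > intron > RNA gene > none
precedence), and the genic report of CDS-overlapping elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_scan import ConservedElement

__all__ = [
    "CompositionRecord",
    "AnnotationSet",
    "CATEGORIES",
    "at_profile",
    "wilcoxon_rank_sum",
    "classify_overlap",
    "genic_table",
    "load_genic_uce_table",
    "genic_table_summary",
]

# classification precedence, highest first; a base gets exactly one label
CATEGORIES = ("cds", "utr", "intron", "rna_gene")
_PRECEDENCE = {c: k for k, c in enumerate(CATEGORIES)}

_GFF_TYPE_MAP = {
    "CDS": "cds",
    "five_prime_UTR": "utr",
    "three_prime_UTR": "utr",
    "UTR": "utr",
    "intron": "intron",
    "ncRNA": "rna_gene",
    "snRNA": "rna_gene",
    "snoRNA": "rna_gene",
    "rRNA": "rna_gene",
    "tRNA": "rna_gene",
    "miRNA": "rna_gene",
}


@dataclass(frozen=True)
class CompositionRecord:
    """A+T frequencies of an element's central window vs pooled flanks."""

    name: str
    core_at: float
    flank_at: float
    core_width: int
    flank_width: int


@dataclass
class AnnotationSet:
    """Half-open annotation intervals with categories from CATEGORIES."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self):
        for chrom, start, end, cat in self.intervals:
            if start >= end:
                raise ValueError(f"negative or zero width interval {chrom}:{start}-{end}")
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}; expected one of {CATEGORIES}")

    @classmethod
    def from_gff3(cls, path) -> "AnnotationSet":
        """Read CDS/UTR/intron/RNA-gene features from a GFF3 file.

        GFF3 coordinates are 1-based closed and are converted to 0-based
        half-open; feature types outside the classification vocabulary are
        ignored.
        """
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8:
                    continue
                ftype = parts[2]
                if ftype in _GFF_TYPE_MAP:
                    intervals.append(
                        (parts[0], int(parts[3]) - 1, int(parts[4]), _GFF_TYPE_MAP[ftype])
                    )
        return cls(intervals)

    def by_chrom(self) -> dict[str, list[tuple[int, int, str]]]:
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, cat in self.intervals:
            out.setdefault(chrom, []).append((start, end, cat))
        return out


def _at_fraction(seq: str) -> float:
    s = seq.upper()
    counted = [c for c in s if c != "N"]
    if not counted:
        raise ValueError("window contains only N bases")
    at = sum(c in "AT" for c in counted)
    return at / len(counted)


def at_profile(
    element_seq: str,
    left_flank: str,
    right_flank: str,
    core_width: int = 60,
    flank_width: int = 60,
    name: str = "",
) -> CompositionRecord:
    """A+T frequency of the element's central window vs its pooled flanks.

    The core window of ``core_width`` bases is centered in the element
    (offset floor((L - core)/2)); the flank sample pools the ``flank_width``
    bases immediately adjacent on each side. A and T are counted
    case-insensitively; N bases are excluded from both numerator and
    denominator. Strand-symmetric by construction (A+T content is invariant
    under reverse complement).
    """
    L = len(element_seq)
    if L < core_width:
        raise ValueError(f"element length {L} < core width {core_width}")
    if len(left_flank) < flank_width or len(right_flank) < flank_width:
        raise ValueError(f"flanks must provide at least {flank_width} bases each side")
    off = (L - core_width) // 2
    core = element_seq[off : off + core_width]
    flank = left_flank[-flank_width:] + right_flank[:flank_width]
    return CompositionRecord(
        name=name,
        core_at=_at_fraction(core),
        flank_at=_at_fraction(flank),
        core_width=core_width,
        flank_width=flank_width,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    W is the rank-sum-based U statistic of ``x`` (the value R's
    ``wilcox.test`` prints as W). The p-value is exact by enumeration when
    min(n, m) <= 8 and there are no ties, otherwise the normal
    approximation with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"W": float(res.statistic), "p_two_sided": float(res.pvalue), "method": method}


def _element_base_categories(
    element, chrom_annotations: Mapping[str, list[tuple[int, int, str]]]
) -> np.ndarray:
    """Category index per element base (len(CATEGORIES) = unannotated)."""
    none_code = len(CATEGORIES)
    codes = np.full(element.end - element.start, none_code, dtype=np.int8)
    for start, end, cat in chrom_annotations.get(element.chrom, []):
        lo = max(start, element.start) - element.start
        hi = min(end, element.end) - element.start
        if lo < hi:
            code = _PRECEDENCE[cat]
            codes[lo:hi] = np.minimum(codes[lo:hi], code)
    return codes


def classify_overlap(
    elements: Sequence[ConservedElement], annotations: AnnotationSet
) -> dict:
    """Per-base-pair annotation composition of an element set.

    Each element base is assigned exactly one category by the precedence
    CDS > UTR > intron > RNA gene > none; the returned ``fractions`` (over
    all element bases) sum to 1. Per-element records carry the same
    fractions plus an ``overlaps_cds`` flag.
    """
    by_chrom = annotations.by_chrom()
    labels = list(CATEGORIES) + ["none"]
    totals = np.zeros(len(labels))
    per_element = []
    total_bases = 0
    for e in elements:
        codes = _element_base_categories(e, by_chrom)
        counts = np.bincount(codes, minlength=len(labels)).astype(float)
        totals += counts
        total_bases += len(codes)
        per_element.append(
            {
                "name": e.name or f"{e.chrom}:{e.start}-{e.end}",
                "fractions": dict(zip(labels, counts / len(codes))),
                "overlaps_cds": bool(counts[_PRECEDENCE["cds"]] > 0),
            }
        )
    fractions = (
        dict(zip(labels, totals / total_bases))
        if total_bases
        else dict(zip(labels, np.zeros(len(labels))))
    )
    return {
        "fractions": fractions,
        "total_bases": total_bases,
        "per_element": per_element,
    }


def genic_table(
    elements: Sequence[ConservedElement],
    gene_cds: pd.DataFrame,
) -> pd.DataFrame:
    """Report of elements overlapping coding sequence, one row per
    element x gene.

    ``gene_cds`` needs columns chromosome/start/end/symbol/fbid (half-open
    CDS intervals). Each row reports the CDS-intersected sub-interval
    spanned within the element; output is sorted by (chromosome, start).
    """
    required = {"chromosome", "start", "end", "symbol", "fbid"}
    if not required <= set(gene_cds.columns):
        raise ValueError(f"gene_cds must have columns {sorted(required)}")
    rows = []
    for e in elements:
        on_chrom = gene_cds[gene_cds["chromosome"] == e.chrom]
        for (symbol, fbid), group in on_chrom.groupby(["symbol", "fbid"], sort=False):
            lo = np.maximum(group["start"].to_numpy(), e.start)
            hi = np.minimum(group["end"].to_numpy(), e.end)
            hit = lo < hi
            if hit.any():
                rows.append(
                    {
                        "chromosome": e.chrom,
                        "start": int(lo[hit].min()),
                        "end": int(hi[hit].max()),
                        "name": e.name or f"{e.chrom}:{e.start}-{e.end}",
                        "symbol": symbol,
                        "fbid": fbid,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "name", "symbol", "fbid"]
    )
    return out.sort_values(["chromosome", "start"], ignore_index=True)


def load_genic_uce_table(path=None) -> pd.DataFrame:
    """Load the packaged genic-element report (or one in the same format)."""
    if path is None:
        ref = resources.files("ucekit.data").joinpath("genic_uce_table.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def genic_table_summary(table: pd.DataFrame) -> dict:
    """Row count, maximum interval length, and per-locus multiplicities."""
    lengths = table["end"] - table["start"]
    multiplicity = table["symbol"].value_counts().to_dict()
    return {
        "n_rows": int(len(table)),
        "max_length": int(lengths.max()) if len(table) else None,
        "n_distinct_loci": int(table["symbol"].nunique()),
        "locus_multiplicity": multiplicity,
    }
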