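"""Reading and writing MAF (Multiple Alignment Format) blocks.

Parsing is delegated to Biopython's MAF support; this module wraps the result
in a light :class:`MafBlock` container that keeps per-row source coordinates,
strand, and source size, and identifies the reference row by species name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import AlignIO

__all__ = ["MafRow", "MafBlock", "MafParseError", "read_maf", "write_maf"]


class MafParseError(ValueError):
    """Raised when a MAF file is malformed."""


@dataclass
class MafRow:
    """One 's' line of a MAF block."""

    species: str
    chrom: str
    start: int  # 0-based start on the source sequence (strand-relative)
    size: int  # ungapped length of this row
    strand: str  # '+' or '-'
    src_size: int
    text: str  # aligned sequence including gaps

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}" if self.chrom else self.species


@dataclass
class MafBlock:
    """A MAF alignment block: equal-length aligned rows keyed by species.

    The reference row anchors the block to genome coordinates. Invariants:
    all rows have equal aligned length; the reference row's non-gap character
    count equals its declared source span.
    """

    ref_species: str
    rows: dict[str, MafRow] = field(default_factory=dict)
    score: float | None = None

    @property
    def ref_row(self) -> MafRow:
        try:
            return self.rows[self.ref_species]
        except KeyError:
            raise MafParseError(
                f"reference species {self.ref_species!r} missing from block"
            ) from None

    @property
    def ref_chrom(self) -> str:
        return self.ref_row.chrom

    @property
    def ref_start(self) -> int:
        return self.ref_row.start

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text)

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def validate(self, block_index: int | None = None) -> None:
        where = f" (block {block_index})" if block_index is not None else ""
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) > 1:
            raise MafParseError(f"rows differ in aligned length{where}: {sorted(widths)}")
        for r in self.rows.values():
            ungapped = len(r.text) - r.text.count("-")
            if ungapped != r.size:
                raise MafParseError(
                    f"row {r.src} declares size {r.size} but has {ungapped} bases{where}"
                )
        if self.ref_species not in self.rows:
            raise MafParseError(
                f"reference species {self.ref_species!r} missing from block{where} "
                f"(rows: {sorted(self.rows)})"
            )


def _split_src(src: str) -> tuple[str, str]:
    """'dm3.chr2L' -> ('dm3', 'chr2L'); a bare name has an empty chrom."""
    sp, _, chrom = src.partition(".")
    return sp, chrom


def read_maf(path, ref_species: str) -> Iterator[MafBlock]:
    """Yield :class:`MafBlock` objects from a MAF file in file order.

    Parameters
    ----------
    path : str or Path
        MAF file starting with a ``##maf`` header line.
    ref_species : str
        Species name (the part of the ``s`` source field before the first
        dot) whose row anchors each block to reference coordinates.

    Raises
    ------
    MafParseError
        On a missing header, rows of unequal length, or a block that lacks
        the reference row. Errors name the offending block's ordinal.
    """
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith("##maf"):
            raise MafParseError(f"{path}: missing '##maf' header line")
        handle.seek(0)
        try:
            alignments = list(AlignIO.parse(handle, "maf"))
        except ValueError as exc:
            raise MafParseError(f"{path}: {exc}") from exc
    for k, aln in enumerate(alignments):
        block = MafBlock(ref_species=ref_species)
        for rec in aln:
            sp, chrom = _split_src(rec.id)
            strand = "-" if rec.annotations.get("strand", 1) in (-1, "-") else "+"
            block.rows[sp] = MafRow(
                species=sp,
                chrom=chrom,
                start=int(rec.annotations.get("start", 0)),
                size=int(rec.annotations.get("size", len(rec.seq) - str(rec.seq).count("-"))),
                strand=strand,
                src_size=int(rec.annotations.get("srcSize", 0)),
                text=str(rec.seq),
            )
        block.validate(block_index=k)
        yield block


def write_maf(blocks: Iterable[MafBlock], path) -> None:
    """Write blocks as a minimal MAF file (##maf header plus a/s lines)."""
    with open(path, "w") as out:
        out.write("##maf version=1 scoring=none\n")
        for block in blocks:
            out.write("\na score=%s\n" % (block.score if block.score is not None else "0.0"))
            width = max(len(r.src) for r in block.rows.values())
            for r in block.rows.values():
                out.write(
                    "s %-*s %10d %6d %s %10d %s\n"
                    % (width, r.src, r.start, r.size, r.strand, r.src_size, r.text)
                )


def blocks_from_text(text: str, ref_species: str) -> list[MafBlock]:
    """Parse MAF text in memory (convenience for tests and simulators)."""
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".maf", delete=False) as tmp:
        tmp.write(text)
        name = tmp.name
    try:
        return list(read_maf(name, ref_species))
    finally:
        os.unlink(name)
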