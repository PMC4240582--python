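"""Coordinate conventions, annotation types, readers/writers and an interval index.

All in-memory coordinates are 0-based half-open ``[start, end)``.  Formats that
use 1-based fully-closed coordinates (RepeatMasker ``.out``, optionally gene
tables exported from genome browsers) are converted at the parser boundary via
a ``dialect`` switch, so the same physical feature always yields the same
:class:`GenomicInterval` regardless of the source dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: Closed repeat-class vocabulary (Repbase top-level classes) plus a fallback.
REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA",
    "Satellite",
    "Simple",
    "Low_complexity",
    "RNA",
)
OTHER_CLASS = "Other"

_RNA_ALIASES = {"RNA", "rRNA", "snRNA", "tRNA", "scRNA", "srpRNA", "ncRNA"}
_CLASS_ALIASES = {
    "Simple_repeat": "Simple",
    "Low_complexity": "Low_complexity",
}


class ParseError(ValueError):
    """A file line could not be interpreted under the declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval; the universal coordinate carrier."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GenomeAssembly:
    """A named set of chromosomes with their lengths."""

    name: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"non-positive length for {chrom}: {size}")

    def length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValidationError(f"unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_sizes[iv.chrom]}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript with exon structure; TSS/TES are strand-oriented."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside bounds"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start: first transcribed base (strand-oriented)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end: last transcribed base (strand-oriented)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def introns(self) -> list[GenomicInterval]:
        """Gaps between exons, in genomic order."""
        gaps = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                gaps.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return gaps

    def intron_number(self, pos: int) -> int | None:
        """1-based intron index in transcription order containing ``pos``.

        Intron 1 is adjacent to the TSS-proximal exon on both strands.
        """
        gaps = self.introns()
        if self.strand == "-":
            gaps = gaps[::-1]
        for i, gap in enumerate(gaps, start=1):
            if gap.contains(pos):
                return i
        return None

    def in_exon(self, pos: int) -> bool:
        return any(ex.contains(pos) for ex in self.exons)


@dataclass(frozen=True)
class CpgIsland:
    interval: GenomicInterval


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES + (OTHER_CLASS,):
            raise ValidationError(f"unknown repeat class {self.repeat_class!r}")


def split_repeat_class(class_string: str) -> tuple[str, str]:
    """Map a RepeatMasker class/family string to (class, family).

    ``"LINE/L1"`` -> ``("LINE", "L1")``; a class outside the closed vocabulary
    maps to ``Other`` with a logged warning.
    """
    if "/" in class_string:
        cls, family = class_string.split("/", 1)
    else:
        cls, family = class_string, ""
    cls = _CLASS_ALIASES.get(cls, cls)
    if cls in _RNA_ALIASES:
        cls = "RNA"
    if cls not in REPEAT_CLASSES:
        log.warning("unrecognized repeat class %r -> Other", class_string)
        cls = OTHER_CLASS
    return cls, family


def _interval_of(feature) -> GenomicInterval:
    return feature if isinstance(feature, GenomicInterval) else feature.interval


class FeatureIndex:
    """Per-chromosome containment index over one annotation kind.

    Intervals are extended by ``slop`` on both sides at build time; a point
    query returns exactly the features whose extended interval contains the
    point, ordered by (start, input order) — equivalent to a linear scan.
    """

    def __init__(self, features: Iterable, slop: int = 0):
        if slop < 0:
            raise ValidationError("slop must be >= 0")
        self.slop = slop
        self._trees: dict[str, IntervalTree] = {}
        self._features = list(features)
        for order, feat in enumerate(self._features):
            iv = _interval_of(feat)
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start - slop, iv.end + slop, (iv.start, order))

    def query(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(hit.data for hit in tree.at(pos))
        return [self._features[order] for _, order in hits]

    def __len__(self) -> int:
        return len(self._features)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a two-column (chrom, length) TSV into a :class:`GenomeAssembly`."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            chrom, size_s = parts
            try:
                size = int(size_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {size_s!r}")
            if size <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive length {size}")
            if chrom in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            sizes[chrom] = size
    return GenomeAssembly(name or path.stem, sizes)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in assembly.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_gene_table(
    path: str | Path, dialect: str = "zero_based"
) -> list[GeneModel]:
    """Read a refFlat-like gene TSV: name, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma lists).

    ``dialect`` is ``zero_based`` (half-open, the native convention) or
    ``one_based`` (fully-closed browser coordinates, converted on read).
    """
    if dialect not in ("zero_based", "one_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    off = 1 if dialect == "one_based" else 0
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            name, chrom, strand, tx_s, tx_e, ex_s, ex_e = parts
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            start, end = int(tx_s) - off, int(tx_e)
            starts = [s - off for s in _parse_int_list(ex_s)]
            ends = _parse_int_list(ex_e)
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{lineno}: exon list length mismatch")
            exons = tuple(
                GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
            )
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end, strand), strand, exons)
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes in the native 0-based half-open dialect."""
    with open(path, "w") as fh:
        for g in genes:
            ex_s = ",".join(str(e.start) for e in g.exons) + ","
            ex_e = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t{ex_s}\t{ex_e}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, as BED is defined)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_cpg_islands(path: str | Path) -> list[CpgIsland]:
    return [CpgIsland(iv) for iv in read_bed(path)]


def read_repeat_table(
    path: str | Path,
    dialect: str = "bed",
    assembly: GenomeAssembly | None = None,
) -> list[RepeatElement]:
    """Read repeat elements.

    ``bed`` dialect: chrom, start, end, repeat_name, class_string (e.g.
    ``LINE/L1``).  ``rmsk_out`` dialect: RepeatMasker ``.out`` whitespace
    table with a 3-line header and 1-based fully-closed begin/end.
    """
    repeats = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 5:
                    raise ParseError(f"{path}:{lineno}: expected >=5 columns")
                chrom, start, end, name, class_string = parts[:5]
                cls, family = split_repeat_class(class_string)
                repeats.append(
                    RepeatElement(
                        GenomicInterval(chrom, int(start), int(end)),
                        name,
                        cls,
                        family,
                    )
                )
    elif dialect == "rmsk_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if lineno <= 3 or not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 11:
                    raise ParseError(f"{path}:{lineno}: short RepeatMasker row")
                chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
                name, class_string = parts[9], parts[10]
                cls, family = split_repeat_class(class_string)
                repeats.append(
                    RepeatElement(
                        GenomicInterval(chrom, begin - 1, end), name, cls, family
                    )
                )
    else:
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    if assembly is not None:
        for rep in repeats:
            assembly.validate_interval(rep.interval)
    return repeats


def write_repeat_table(repeats: Sequence[RepeatElement], path: str | Path) -> None:
    """Write repeats in the BED+class dialect."""
    with open(path, "w") as fh:
        for r in repeats:
            cls = r.repeat_class + (f"/{r.family}" if r.family else "")
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.repeat_name}\t{cls}\n"
            )
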