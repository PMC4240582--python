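"""Scoring and scanning of p53 response elements around peak maxima.

A p53 response element is two RRRCWWGYYY decamer half-sites separated by a
0–13 bp spacer (R=A/G, W=A/T, Y=C/T).  A base matching its degenerate
consensus class scores that position's weight, otherwise 0; a site's score is
reported as percent of the maximal two-half-site score, and sites at or above
a cutoff (default 75%) are called.  The default weight table emphasises the
invariant core C (position 4) and G (position 7) and the central WW; it is
pluggable, so an externally published matrix can be loaded from TSV.

The consensus is its own reverse complement class-wise and the weight table is
palindromic, so scores are strand-symmetric: scanning the forward strand finds
every site, and calls are reported unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomicInterval, ValidationError

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "W": "AT",
    "S": "CG",
    "K": "GT",
    "M": "AC",
    "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_SPACERS = tuple(range(14))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)  # unknown -> N (matches nothing)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    return lut[arr]


@dataclass(frozen=True)
class HalfSiteModel:
    """Weighted degenerate consensus for one RRRCWWGYYY half-site."""

    consensus: str = "RRRCWWGYYY"
    weights: tuple[int, ...] = (1, 1, 1, 3, 2, 2, 3, 1, 1, 1)

    def __post_init__(self) -> None:
        if len(self.consensus) != 10 or len(self.weights) != 10:
            raise ValidationError("half-site model must have 10 positions")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be positive")

    @property
    def max_half_score(self) -> int:
        return sum(self.weights)

    @property
    def max_site_score(self) -> int:
        return 2 * self.max_half_score

    def weight_table(self) -> np.ndarray:
        """(10, 5) array: weight if the base (A,C,G,T,N) matches the class."""
        table = np.zeros((10, 5), dtype=np.float64)
        for j, (sym, w) in enumerate(zip(self.consensus, self.weights)):
            for base in IUPAC[sym]:
                table[j, _BASE_INDEX[base]] = w
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HalfSiteModel":
        """Load a 10-row (symbol, weight) TSV."""
        syms, weights = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sym, w = line.split("\t")
                syms.append(sym)
                weights.append(int(w))
        return cls("".join(syms), tuple(weights))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sym, w in zip(self.consensus, self.weights):
                fh.write(f"{sym}\t{w}\n")


DEFAULT_MODEL = HalfSiteModel()


@dataclass(frozen=True)
class SiteCall:
    """A response-element call; coordinates are offsets in the scanned
    sequence unless lifted to the genome by :func:`sites_near_maxima`."""

    start: int
    spacer: int
    score_percent: float
    sequence: str
    strand: str = "."
    chrom: str | None = None

    @property
    def end(self) -> int:
        return self.start + 20 + self.spacer

    @property
    def midpoint(self) -> int:
        return self.start + (20 + self.spacer) // 2

    def interval(self) -> GenomicInterval:
        if self.chrom is None:
            raise ValidationError("call has no chromosome")
        return GenomicInterval(self.chrom, self.start, self.end)


def _half_scores(enc: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Score of the decamer starting at every position (length L-9)."""
    n = len(enc) - 9
    if n <= 0:
        return np.zeros(0)
    out = np.zeros(n)
    for j in range(10):
        out += table[j][enc[j : j + n]]
    return out


def score_site(seq: str, model: HalfSiteModel = DEFAULT_MODEL, spacer: int = 0) -> float:
    """Score a full site (two decamers around a ``spacer``-bp gap) as percent
    of the maximal score.  Spacer bases are unscored; N matches nothing."""
    if len(seq) != 20 + spacer:
        raise ValidationError(
            f"expected {20 + spacer} bases for spacer {spacer}, got {len(seq)}"
        )
    table = model.weight_table()
    enc = _encode(seq)
    left = float(sum(table[j, enc[j]] for j in range(10)))
    right = float(sum(table[j, enc[10 + spacer + j]] for j in range(10)))
    return 100.0 * (left + right) / model.max_site_score


def scan_window(
    seq: str,
    model: HalfSiteModel = DEFAULT_MODEL,
    min_percent: float = 75.0,
    spacers: Sequence[int] = DEFAULT_SPACERS,
) -> list[SiteCall]:
    """All sites scoring >= ``min_percent`` over every position and spacer.

    Overlapping calls are all reported, sorted by (position, spacer).  A
    sequence shorter than 20 bp yields an empty list.
    """
    if len(seq) < 20:
        return []
    enc = _encode(seq)
    table = model.weight_table()
    halves = _half_scores(enc, table)
    calls = []
    for spacer in spacers:
        site_len = 20 + spacer
        n = len(seq) - site_len + 1
        if n <= 0:
            continue
        total = halves[:n] + halves[10 + spacer : 10 + spacer + n]
        pct = 100.0 * total / model.max_site_score
        for pos in np.flatnonzero(pct >= min_percent):
            calls.append(
                SiteCall(
                    int(pos), spacer, float(pct[pos]), seq[pos : pos + site_len]
                )
            )
    calls.sort(key=lambda c: (c.start, c.spacer))
    return calls


def _fetch(fasta, chrom: str, start: int, end: int) -> str:
    """Fetch a subsequence from a dict of strings or a pyfaidx.Fasta."""
    if isinstance(fasta, Mapping):
        return fasta[chrom][start:end]
    return str(fasta[chrom][start:end])


def _chrom_length(fasta, chrom: str) -> int:
    return len(fasta[chrom])


def sites_near_maxima(
    peaks,
    fasta,
    model: HalfSiteModel = DEFAULT_MODEL,
    window: int = 2000,
    report_radius: int = 100,
    min_percent: float = 75.0,
) -> dict:
    """Scan ``window``-bp intervals centered on each peak maximum; return, per
    peak, the calls whose site midpoint lies within ±``report_radius`` of the
    maximum.  Windows are truncated at chromosome edges."""
    out = {}
    for peak in peaks:
        chrom = peak.region.chrom
        length = _chrom_length(fasta, chrom)
        ws = max(0, peak.maximum - window // 2)
        we = min(length, peak.maximum + window // 2)
        seq = _fetch(fasta, chrom, ws, we)
        kept = []
        for call in scan_window(seq, model, min_percent):
            genomic_mid = ws + call.midpoint
            if abs(genomic_mid - peak.maximum) <= report_radius:
                kept.append(
                    SiteCall(
                        ws + call.start,
                        call.spacer,
                        call.score_percent,
                        call.sequence,
                        chrom=chrom,
                    )
                )
        out[peak] = kept
    return out


def site_distance_table(
    peaks,
    fasta,
    model: HalfSiteModel = DEFAULT_MODEL,
    window: int = 2000,
    min_percent: float = 75.0,
) -> list[int]:
    """Signed distances (site midpoint − peak maximum) of every in-window call,
    pooled over peaks — the input for a site-enrichment histogram."""
    distances = []
    for peak in peaks:
        chrom = peak.region.chrom
        length = _chrom_length(fasta, chrom)
        ws = max(0, peak.maximum - window // 2)
        we = min(length, peak.maximum + window // 2)
        seq = _fetch(fasta, chrom, ws, we)
        for call in scan_window(seq, model, min_percent):
            distances.append(ws + call.midpoint - peak.maximum)
    return distances


def write_site_calls(calls_by_peak: Mapping, path: str | Path) -> None:
    """BED6+ export of genomic site calls: spacer and score_percent appended."""
    with open(path, "w") as fh:
        for peak, calls in calls_by_peak.items():
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\tsite\t{c.score_percent:.3f}\t"
                    f"{c.strand}\t{c.spacer}\t{c.score_percent:.3f}\n"
                )
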