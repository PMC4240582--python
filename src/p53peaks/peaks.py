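"""Coverage maps and high-confidence peak calling against an Input control.

Mapped tags (5' positions of 36-mers) are extended to the average chromatin
fragment size to build a nucleotide-resolution fragment-coverage track.
Candidate peaks are maximal runs above a threshold (fixed, or set from the
Poisson upper tail of the mean coverage).  A candidate becomes high-confidence
only if it passes, at the 99% level, two independent tests against the Input
track — a library-scaled binomial enrichment test and an empirical
background-percentile test — and is not matched by a symmetric Input peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, GenomicInterval, ValidationError, ParseError

TAG_COLUMNS = ["chrom", "pos", "strand"]
DEFAULT_TAG_LEN = 36
DEFAULT_FRAGMENT_SIZE = 700


@dataclass(frozen=True)
class TagAlignment:
    """A uniquely-mapped sequencing tag; ``pos`` is the leftmost base."""

    chrom: str
    pos: int
    strand: str
    tag_len: int = DEFAULT_TAG_LEN


def tags_to_frame(tags: Iterable[TagAlignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.chrom, t.pos, t.strand) for t in tags], columns=TAG_COLUMNS
    )


def read_tags(path: str | Path) -> pd.DataFrame:
    """Read tags from BED6 (pos = BED start) or 3-column chrom/pos/strand TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 6:
        out = df.iloc[:, [0, 1, 5]].copy()
    elif df.shape[1] == 3:
        out = df.copy()
    else:
        raise ParseError(f"{path}: expected 3 or >=6 columns, got {df.shape[1]}")
    out.columns = TAG_COLUMNS
    bad = ~out["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(f"{path}: invalid strand at row {int(np.flatnonzero(bad)[0])}")
    return out.reset_index(drop=True)


def write_tags(tags: pd.DataFrame, path: str | Path) -> None:
    tags[TAG_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def dedup_tags(tags: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop duplicate (chrom, pos, strand) tags; returns (distinct, n_removed)."""
    distinct = tags.drop_duplicates(subset=TAG_COLUMNS).reset_index(drop=True)
    return distinct, len(tags) - len(distinct)


@dataclass
class CoverageTrack:
    """Per-chromosome fragment coverage at nucleotide resolution."""

    assembly: GenomeAssembly
    coverage: dict[str, np.ndarray]
    fragment_size: int
    library_size: int
    n_rejected: int = 0

    def chrom_coverage(self, chrom: str) -> np.ndarray:
        return self.coverage[chrom]

    def total_coverage(self) -> int:
        return int(sum(int(c.sum()) for c in self.coverage.values()))


def build_coverage(
    tags: pd.DataFrame | Iterable[TagAlignment],
    assembly: GenomeAssembly,
    fragment_size: int = DEFAULT_FRAGMENT_SIZE,
    tag_len: int = DEFAULT_TAG_LEN,
) -> CoverageTrack:
    """Extend each tag to ``fragment_size`` and accumulate coverage.

    A + tag at ``pos`` covers ``[pos, pos+fragment_size)``; a − tag covers
    ``[pos+tag_len−fragment_size, pos+tag_len)``, both truncated at chromosome
    ends.  Tags whose 36-mer body falls outside the chromosome are rejected
    and counted.
    """
    if fragment_size < tag_len:
        raise ValidationError("fragment_size must be >= tag_len")
    if not isinstance(tags, pd.DataFrame):
        tags = tags_to_frame(tags)
    coverage: dict[str, np.ndarray] = {}
    n_rejected = 0
    n_accepted = 0
    for chrom, length in assembly.chrom_sizes.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        sub = tags[tags["chrom"] == chrom]
        if len(sub):
            pos = sub["pos"].to_numpy(dtype=np.int64)
            plus = (sub["strand"] == "+").to_numpy()
            ok = (pos >= 0) & (pos + tag_len <= length)
            n_rejected += int((~ok).sum())
            pos, plus = pos[ok], plus[ok]
            n_accepted += len(pos)
            starts = np.where(plus, pos, pos + tag_len - fragment_size)
            ends = starts + fragment_size
            np.add.at(diff, np.clip(starts, 0, length), 1)
            np.add.at(diff, np.clip(ends, 0, length), -1)
        coverage[chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    unknown = tags[~tags["chrom"].isin(assembly.chrom_sizes)]
    n_rejected += len(unknown)
    return CoverageTrack(assembly, coverage, fragment_size, n_accepted, n_rejected)


@dataclass(eq=False)  # identity semantics: peaks key per-peak result maps
class Peak:
    """A called enrichment site anchored at its coverage maximum."""

    region: GenomicInterval
    maximum: int
    height: float
    conf_enrichment: float | None = None
    conf_background: float | None = None
    input_symmetric_overlap: bool = False
    high_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.region.contains(self.maximum):
            raise ValidationError("peak maximum outside region")


@dataclass
class PeakSet:
    """Sorted, non-overlapping peaks on one assembly."""

    label: str
    assembly: GenomeAssembly
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.region.chrom, p.region.start)
        )
        prev = None
        for p in self.peaks:
            if (
                prev is not None
                and prev.region.chrom == p.region.chrom
                and p.region.start < prev.region.end
            ):
                raise ValidationError("overlapping peaks in set")
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def maxima(self, chrom: str) -> np.ndarray:
        return np.array(
            [p.maximum for p in self.peaks if p.region.chrom == chrom], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                p.region.chrom,
                p.region.start,
                p.region.end,
                p.maximum,
                p.height,
                p.conf_enrichment if p.conf_enrichment is not None else np.nan,
                p.conf_background if p.conf_background is not None else np.nan,
                int(p.input_symmetric_overlap),
                int(p.high_confidence),
            )
            for p in self.peaks
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "start",
                "end",
                "maximum",
                "height",
                "conf_enrichment",
                "conf_background",
                "input_symmetric_overlap",
                "high_confidence",
            ],
        )

    def write_bed(self, path: str | Path) -> None:
        """BED6+ export: name=maximum, score=height, then the two confidence
        scores and the flags."""
        df = self.to_frame()
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\tmax={row.maximum}\t"
                    f"{row.height:g}\t.\t{row.conf_enrichment:.6g}\t"
                    f"{row.conf_background:.6g}\t{row.input_symmetric_overlap}\t"
                    f"{row.high_confidence}\n"
                )


def read_peak_bed(path: str | Path, assembly: GenomeAssembly, label: str) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"{path}:{lineno}: expected 10 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            maximum = int(parts[3].removeprefix("max="))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    maximum,
                    float(parts[4]),
                    float(parts[6]),
                    float(parts[7]),
                    bool(int(parts[8])),
                    bool(int(parts[9])),
                )
            )
    return PeakSet(label, assembly, peaks)


# ---------------------------------------------------------------------------
# Threshold rules and candidate calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedThreshold:
    height: int

    def threshold(self, coverage: np.ndarray) -> int:
        return self.height


@dataclass(frozen=True)
class PoissonThreshold:
    """Smallest height h with upper-tail Poisson(mean coverage) P(X>=h) < q."""

    q: float = 1e-4

    def threshold(self, coverage: np.ndarray) -> int:
        lam = float(coverage.mean())
        if lam == 0.0:
            return 1
        h = max(1, int(stats.poisson.ppf(1.0 - self.q, lam)))
        while stats.poisson.sf(h - 1, lam) >= self.q:
            h += 1
        while h > 1 and stats.poisson.sf(h - 2, lam) < self.q:
            h -= 1
        return h


def call_candidate_peaks(
    track: CoverageTrack,
    rule: FixedThreshold | PoissonThreshold,
    merge_gap: int = 200,
    label: str = "candidates",
) -> PeakSet:
    """Threshold the coverage track into candidate peaks.

    Maximal runs with coverage >= threshold become candidates; runs separated
    by < ``merge_gap`` bp are merged; the maximum is the leftmost position
    attaining the run's highest coverage.
    """
    peaks = []
    for chrom, cov in track.coverage.items():
        t = rule.threshold(cov)
        above = cov >= t
        if not above.any():
            continue
        padded = np.concatenate(([0], above.view(np.int8), [0]))
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        merged: list[list[int]] = []
        for s, e in zip(run_starts, run_ends):
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            window = cov[s:e]
            argmax = int(np.argmax(window))  # leftmost by argmax semantics
            peaks.append(
                Peak(
                    GenomicInterval(chrom, s, e),
                    s + argmax,
                    float(window[argmax]),
                )
            )
    return PeakSet(label, track.assembly, peaks)


# ---------------------------------------------------------------------------
# Confidence tests
# ---------------------------------------------------------------------------


def region_fragment_count(track: CoverageTrack, region: GenomicInterval) -> float:
    """Effective fragment count in a region: coverage mass / fragment size."""
    if len(region) == 0:
        raise ValidationError("zero-width region")
    cov = track.coverage[region.chrom]
    return float(cov[region.start : region.end].sum()) / track.fragment_size


def confidence_test_enrichment(
    peak: Peak, chip: CoverageTrack, input_track: CoverageTrack
) -> float:
    """Library-scaled binomial enrichment confidence against the Input track.

    With k ChIP fragments and k' = (Input fragments + 1 pseudo-count) in the
    peak region, returns 1 − P(X >= k) for X ~ Binomial(k + k', p) where
    p = N_chip / (N_chip + N_input) corrects for library size.
    """
    if input_track.library_size <= 0:
        raise ValidationError("input library size must be positive")
    k_chip = int(round(region_fragment_count(chip, peak.region)))
    k_input = int(round(region_fragment_count(input_track, peak.region))) + 1
    n = k_chip + k_input
    p = chip.library_size / (chip.library_size + input_track.library_size)
    if k_chip == 0:
        return 0.0
    return float(1.0 - stats.binom.sf(k_chip - 1, n, p))


def confidence_test_background(
    peak: Peak,
    input_track: CoverageTrack,
    n_samples: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical percentile of the peak's ChIP height among maxima of random
    equal-width Input windows (genome-wide, chromosome chosen by length)."""
    if n_samples < 100:
        raise ValidationError("n_samples must be >= 100")
    width = len(peak.region)
    chroms = list(input_track.assembly.chrom_sizes)
    avail = np.array(
        [input_track.assembly.chrom_sizes[c] - width + 1 for c in chroms],
        dtype=np.float64,
    )
    if (avail <= 0).all():
        raise ValidationError("peak wider than every chromosome")
    avail = np.clip(avail, 0, None)
    if rng is None:
        rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(chroms), size=n_samples, p=avail / avail.sum())
    below = 0
    offsets = np.arange(width)
    for ci in np.unique(chrom_idx):
        n_c = int((chrom_idx == ci).sum())
        starts = rng.integers(0, int(avail[ci]), size=n_c)
        cov = input_track.coverage[chroms[ci]]
        maxima = cov[starts[:, None] + offsets[None, :]].max(axis=1)
        below += int((maxima < peak.height).sum())
    return below / n_samples


def score_peaks(
    peakset: PeakSet,
    chip: CoverageTrack,
    input_track: CoverageTrack,
    n_samples: int = 1000,
    seed: int = 0,
) -> PeakSet:
    """Populate both confidence scores for every peak (one seeded stream)."""
    rng = np.random.default_rng(seed)
    scored = []
    for p in peakset:
        scored.append(
            replace(
                p,
                conf_enrichment=confidence_test_enrichment(p, chip, input_track),
                conf_background=confidence_test_background(
                    p, input_track, n_samples=n_samples, rng=rng
                ),
            )
        )
    return PeakSet(peakset.label, peakset.assembly, scored)


def flag_symmetric_input_overlap(
    chip_peaks: PeakSet,
    input_peaks: PeakSet,
    max_offset: int = 100,
    max_height_ratio: float = 2.0,
    chip_library_size: int | None = None,
    input_library_size: int | None = None,
) -> PeakSet:
    """Flag ChIP peaks matched by a highly symmetric Input peak.

    A ChIP peak is flagged if some Input peak has |Δmaximum| <= ``max_offset``
    and a library-scaled ChIP/Input height ratio <= ``max_height_ratio``.
    """
    scale = 1.0
    if chip_library_size and input_library_size:
        scale = input_library_size / chip_library_size
    by_chrom: dict[str, list[Peak]] = {}
    for ip in input_peaks:
        by_chrom.setdefault(ip.region.chrom, []).append(ip)
    flagged = []
    for p in chip_peaks:
        hit = False
        for ip in by_chrom.get(p.region.chrom, []):
            if abs(ip.maximum - p.maximum) <= max_offset:
                if ip.height > 0 and (p.height * scale) / ip.height <= max_height_ratio:
                    hit = True
                    break
        flagged.append(replace(p, input_symmetric_overlap=hit))
    return PeakSet(chip_peaks.label, chip_peaks.assembly, flagged)


def filter_high_confidence(peakset: PeakSet, min_conf: float = 0.99) -> PeakSet:
    """Retain peaks passing both confidence tests at ``min_conf`` and lacking
    a symmetric Input peak."""
    kept = []
    for p in peakset:
        if p.conf_enrichment is None or p.conf_background is None:
            raise ValidationError("confidence scores not populated")
        if (
            p.conf_enrichment >= min_conf
            and p.conf_background >= min_conf
            and not p.input_symmetric_overlap
        ):
            kept.append(replace(p, high_confidence=True))
    return PeakSet(peakset.label + "_HC", peakset.assembly, kept)


def call_high_confidence(
    chip_tags: pd.DataFrame,
    input_tags: pd.DataFrame,
    assembly: GenomeAssembly,
    fragment_size: int = DEFAULT_FRAGMENT_SIZE,
    tag_len: int = DEFAULT_TAG_LEN,
    rule: FixedThreshold | PoissonThreshold | None = None,
    merge_gap: int = 200,
    n_samples: int = 1000,
    min_conf: float = 0.99,
    max_offset: int = 100,
    max_height_ratio: float = 2.0,
    seed: int = 0,
    label: str = "chip",
) -> dict:
    """Full calling pipeline: dedup -> coverage -> candidates (ChIP and Input,
    identical rules) -> dual confidence tests -> symmetric-Input filter."""
    rule = rule or PoissonThreshold()
    chip_tags, chip_dups = dedup_tags(chip_tags)
    input_tags, input_dups = dedup_tags(input_tags)
    chip_track = build_coverage(chip_tags, assembly, fragment_size, tag_len)
    input_track = build_coverage(input_tags, assembly, fragment_size, tag_len)
    candidates = call_candidate_peaks(chip_track, rule, merge_gap, f"{label}_candidates")
    input_peaks = call_candidate_peaks(input_track, rule, merge_gap, f"{label}_input")
    scored = score_peaks(candidates, chip_track, input_track, n_samples, seed)
    flagged = flag_symmetric_input_overlap(
        scored,
        input_peaks,
        max_offset,
        max_height_ratio,
        chip_track.library_size,
        input_track.library_size,
    )
    hc = filter_high_confidence(flagged, min_conf)
    return {
        "chip_track": chip_track,
        "input_track": input_track,
        "candidates": flagged,
        "input_peaks": input_peaks,
        "high_confidence": hc,
        "chip_duplicates": chip_dups,
        "input_duplicates": input_dups,
    }
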